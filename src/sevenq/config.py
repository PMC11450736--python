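"""Parameter containers for the simulation, segmentation and phenotyping stages.

All lengths are in nanometres, areas in nm^2 (background density excepted,
which is quoted per um^2 as is conventional for SMLM background rates), and
incubation volumes in microlitres. Probabilities are dimensionless in [0, 1].
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigError

#: Marker species used throughout: three mouse exosomal tetraspanins plus the
#: human CD81 tracer carried only by EVs from the Cre-activated cell type.
DEFAULT_SPECIES = ("MmCD9", "MmCD63", "MmCD81", "HsCD81")

#: Mean tetraspanin copies per vesicle, per species (Poisson means). Mouse
#: tetraspanins are set so that a three-species stain at the default labeling
#: efficiency yields ~17 detected proteins per EV; the HsCD81 tracer is sparse
#: (most tracer-positive vesicles carry fewer than four detectable copies).
DEFAULT_TSPAN_MEANS: Mapping[str, float] = {
    "MmCD9": 8.0,
    "MmCD63": 8.0,
    "MmCD81": 8.0,
    "HsCD81": 2.5,
}

MOUSE_TSPAN_PANEL = ("MmCD9", "MmCD63", "MmCD81")


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class PopulationConfig:
    """Ground-truth vesicle population of one biofluid sample.

    Diameters are lognormal; per-species tetraspanin copy numbers are Poisson.
    A fraction ``labeled_fraction`` of vesicles originates from the
    reporter-activated cell type and carries HsCD81 copies; all other vesicles
    carry none.
    """

    n_ev_per_roi_mean: float = 15.0  # expected captured EVs per ROI per uL incubated
    diameter_logmean: float = math.log(78.0)
    diameter_logsd: float = 0.25
    tspan_mean: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_TSPAN_MEANS)
    )
    species_list: Sequence[str] = DEFAULT_SPECIES
    labeled_fraction: float = 0.15
    labeled_source: str = "labeled"
    unlabeled_source: str = "other"

    def __post_init__(self) -> None:
        if self.n_ev_per_roi_mean < 0:
            raise ConfigError("n_ev_per_roi_mean must be >= 0")
        if self.diameter_logsd < 0:
            raise ConfigError("diameter_logsd must be >= 0")
        if not math.isfinite(self.diameter_logmean):
            raise ConfigError("diameter_logmean must be finite")
        _check_prob("labeled_fraction", self.labeled_fraction)
        if isinstance(self.tspan_mean, (int, float)):
            self.tspan_mean = {s: float(self.tspan_mean) for s in self.species_list}
        else:
            self.tspan_mean = {s: float(m) for s, m in self.tspan_mean.items()}
        for s in self.species_list:
            mean = self.tspan_mean.get(s, 0.0)
            if mean < 0:
                raise ConfigError(f"tspan_mean[{s}] must be >= 0")
            self.tspan_mean.setdefault(s, 0.0)

    def copy_mean(self, species: str) -> float:
        return self.tspan_mean.get(species, 0.0)


@dataclass
class AssayDesign:
    """One immunocapture + immunostain condition on one coverslip.

    ``capture_species`` selects which vesicles are retained on the coverslip;
    ``stain_panel`` lists the species whose copies can be bound by AF647
    antibodies (one dye per antibody). Each bound antibody emits on average
    ``loc_per_ab_mean`` localizations.
    """

    capture_species: str = "MmCD81"
    stain_panel: Sequence[str] = MOUSE_TSPAN_PANEL
    volume_ul: float = 1.0
    n_roi: int = 20
    roi_side_nm: float = 10_000.0
    capture_prob_per_epitope: float = 0.35
    labeling_efficiency: float = 0.7
    loc_per_ab_mean: float = 14.0
    sigma_loc_nm: float = 10.0
    bg_density_per_um2: float = 0.5

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise ConfigError("volume_ul must be > 0")
        if self.n_roi < 1:
            raise ConfigError("n_roi must be >= 1")
        if self.roi_side_nm <= 0:
            raise ConfigError("roi_side_nm must be > 0")
        if self.loc_per_ab_mean < 1:
            raise ConfigError("loc_per_ab_mean must be >= 1")
        if self.sigma_loc_nm < 0:
            raise ConfigError("sigma_loc_nm must be >= 0")
        if self.bg_density_per_um2 < 0:
            raise ConfigError("bg_density_per_um2 must be >= 0")
        _check_prob("capture_prob_per_epitope", self.capture_prob_per_epitope)
        _check_prob("labeling_efficiency", self.labeling_efficiency)
        self.stain_panel = tuple(self.stain_panel)

    @property
    def roi_area_nm2(self) -> float:
        return self.roi_side_nm ** 2


@dataclass
class SegmentationParams:
    """Voronoi density-segmentation parameters.

    A localization is "dense" when its cell density exceeds
    ``density_factor_alpha`` times the ROI-average density; edge-adjacent dense
    cells are merged and components below ``min_cluster_size`` are discarded.
    """

    min_cluster_size: int = 40
    density_factor_alpha: float = 2.0

    def __post_init__(self) -> None:
        if self.min_cluster_size < 1:
            raise ConfigError("min_cluster_size must be >= 1")
        if self.density_factor_alpha <= 0:
            raise ConfigError("density_factor_alpha must be > 0")


@dataclass
class PhenotypeParams:
    """Cluster-to-vesicle conversion parameters.

    ``loc_per_ab`` converts localization counts to detected-protein counts
    (average localizations per fluorescent antibody); vesicles need at least
    ``min_proteins`` detected proteins to be counted.
    """

    loc_per_ab: float = 14.0
    min_proteins: int = 3
    sigma_loc_nm: float = 10.0
    max_diameter_nm: float = 400.0
    rounding: str = "half_up"  # or "floor"
    include_boundary: bool = False

    def __post_init__(self) -> None:
        if self.loc_per_ab < 1:
            raise ConfigError("loc_per_ab must be >= 1")
        if self.min_proteins < 1:
            raise ConfigError("min_proteins must be >= 1")
        if self.rounding not in ("half_up", "floor"):
            raise ConfigError("rounding must be 'half_up' or 'floor'")
        if self.max_diameter_nm <= 0:
            raise ConfigError("max_diameter_nm must be > 0")
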