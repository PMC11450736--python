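"""Per-vesicle immunophenotyping: protein counts and diameters from clusters.

A detected cluster is converted to a vesicle call by (i) dividing its
localization count by the average localizations emitted per fluorescent
antibody (14) to estimate the number of detected tetraspanins, and (ii)
inverting the projection geometry of antibodies bound uniformly on a sphere
to estimate the diameter. A vesicle is only called when at least
``min_proteins`` (3) tetraspanins are detected, its cluster does not touch
the ROI boundary, and the diameter is exosome-plausible.

Diameter estimator: for antibodies uniform on a sphere of radius R,
orthographic projection gives E[r^2] = (2/3) R^2 about the center; each
localization adds 2 sigma^2 of planar noise variance. Hence
D = 2 * sqrt(1.5 * (mean_sq_radius - 2 sigma^2)), floored at a 1 nm^2
residual for sub-resolution clusters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .config import PhenotypeParams
from .tessellation import VoronoiCluster

EV_COLUMNS = ["roi_id", "cluster_id", "n_loc", "est_proteins", "est_diameter_nm"]

_FLOOR_NM2 = 1.0


@dataclass
class EVCall:
    """One detected vesicle."""

    roi_id: int
    cluster_id: int
    n_loc: int
    est_proteins: int
    est_diameter_nm: float


def estimate_protein_count(cluster: VoronoiCluster, params: PhenotypeParams) -> int:
    """Detected tetraspanins = localizations / (localizations per antibody)."""
    q = cluster.n_loc / params.loc_per_ab
    if params.rounding == "half_up":
        return int(math.floor(q + 0.5))
    return int(math.floor(q))


def estimate_diameter(cluster: VoronoiCluster, params: PhenotypeParams) -> float:
    """Second-moment spherical-shell diameter with precision deconvolution.

    Uses the cluster's mean localization precision when carried, falling back
    to ``params.sigma_loc_nm``.
    """
    sigma = (
        cluster.mean_precision_nm
        if cluster.mean_precision_nm is not None
        else params.sigma_loc_nm
    )
    resid = max(cluster.mean_sq_radius_nm2 - 2.0 * sigma**2, _FLOOR_NM2)
    return 2.0 * math.sqrt(1.5 * resid)


def call_evs(clusters: list[VoronoiCluster], params: PhenotypeParams) -> list[EVCall]:
    """Apply the detection gates and return vesicle calls.

    Excludes clusters below the minimum protein count, clusters touching the
    ROI boundary (truncated geometry, unless ``include_boundary``), and
    oversized clusters (aggregates/debris). Output ordered by ROI then
    cluster id.
    """
    calls = []
    for cl in clusters:
        if cl.touches_boundary and not params.include_boundary:
            continue
        proteins = estimate_protein_count(cl, params)
        if proteins < params.min_proteins:
            continue
        diameter = estimate_diameter(cl, params)
        if diameter > params.max_diameter_nm:
            continue
        calls.append(
            EVCall(
                roi_id=cl.roi_id,
                cluster_id=cl.cluster_id,
                n_loc=cl.n_loc,
                est_proteins=proteins,
                est_diameter_nm=diameter,
            )
        )
    calls.sort(key=lambda c: (c.roi_id, c.cluster_id))
    return calls


def evs_to_frame(calls: list[EVCall]) -> pd.DataFrame:
    """Vesicle calls as a table with the documented EV schema."""
    return pd.DataFrame(
        [(c.roi_id, c.cluster_id, c.n_loc, c.est_proteins, c.est_diameter_nm) for c in calls],
        columns=EV_COLUMNS,
    )
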