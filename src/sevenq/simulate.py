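"""Synthetic dSTORM data generator for immunocaptured extracellular vesicles.

The generator emulates the single-EV nanoscopy assay: ~70-80 nm vesicles
carrying Poisson numbers of tetraspanin copies are captured onto an
antibody-functionalized coverslip, stained with dye-conjugated antibodies
(one fluorophore per antibody), and imaged by SMLM. Each bound antibody sits
at a uniformly random point of the vesicle sphere, is orthographically
projected onto the coverslip plane, and emits a geometric number of
localizations (mean 14) that are jittered by the localization precision.
A homogeneous Poisson background is added per ROI.

Ground-truth populations are returned as DataFrames with columns
``roi_id, ev_id, x_nm, y_nm, diameter_nm, <one column per species>,
source_label``; localization tables have columns
``roi_id, x_nm, y_nm, frame, precision_nm``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AssayDesign, PopulationConfig
from .errors import ConfigError

LOC_COLUMNS = ["roi_id", "x_nm", "y_nm", "frame", "precision_nm"]


def _truth_columns(cfg: PopulationConfig) -> list[str]:
    return (
        ["roi_id", "ev_id", "x_nm", "y_nm", "diameter_nm"]
        + list(cfg.species_list)
        + ["source_label"]
    )


def sample_ev_population(
    cfg: PopulationConfig, assay: AssayDesign, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the ground-truth vesicle population for every ROI of one sample.

    Per ROI the vesicle count is Poisson(``n_ev_per_roi_mean`` x
    ``volume_ul``): the rate is quoted per microlitre of biofluid, so
    incubating a larger volume deposits proportionally more vesicles per
    field, as in the real assay. Positions are uniform in the ROI square,
    diameters lognormal, and per-species copy numbers Poisson. A
    Bernoulli(``labeled_fraction``) subset carries HsCD81 tracer copies; the
    remainder carries none.
    """
    n_per_roi = rng.poisson(cfg.n_ev_per_roi_mean * assay.volume_ul, size=assay.n_roi)
    total = int(n_per_roi.sum())
    roi_id = np.repeat(np.arange(assay.n_roi), n_per_roi)
    ev_id = np.concatenate([np.arange(n) for n in n_per_roi]) if total else np.array([], int)

    out = pd.DataFrame(
        {
            "roi_id": roi_id,
            "ev_id": ev_id,
            "x_nm": rng.uniform(0.0, assay.roi_side_nm, total),
            "y_nm": rng.uniform(0.0, assay.roi_side_nm, total),
            "diameter_nm": rng.lognormal(cfg.diameter_logmean, cfg.diameter_logsd, total),
        }
    )
    labeled = rng.random(total) < cfg.labeled_fraction
    for species in cfg.species_list:
        copies = rng.poisson(cfg.copy_mean(species), size=total)
        if species == "HsCD81":
            copies = np.where(labeled, copies, 0)
        out[species] = copies
    out["source_label"] = np.where(labeled, cfg.labeled_source, cfg.unlabeled_source)
    return out


def simulate_capture(
    evs: pd.DataFrame, assay: AssayDesign, rng: np.random.Generator
) -> pd.DataFrame:
    """Retain each vesicle with probability 1 - (1 - p)^k.

    ``k`` is the vesicle's copy number of the capture species and ``p`` the
    per-epitope engagement probability; a vesicle with no copies of the
    capture species is never retained.
    """
    if assay.capture_species not in evs.columns:
        raise ConfigError(
            f"capture species {assay.capture_species!r} not among simulated "
            f"species {[c for c in evs.columns if c.startswith(('Mm', 'Hs'))]}"
        )
    k = evs[assay.capture_species].to_numpy()
    p_keep = 1.0 - (1.0 - assay.capture_prob_per_epitope) ** k
    keep = rng.random(len(evs)) < p_keep
    return evs.loc[keep].reset_index(drop=True)


def _uniform_sphere_xy(diameters: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Orthographic (x, y) offsets of uniform points on spheres of given diameter."""
    v = rng.normal(size=(diameters.size, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v[:, :2] * (diameters[:, None] / 2.0)


def render_localizations(
    captured: pd.DataFrame, assay: AssayDesign, rng: np.random.Generator
) -> pd.DataFrame:
    """Render captured vesicles into a localization table.

    Each copy of each stained species independently becomes a bound antibody
    with probability ``labeling_efficiency``. Every antibody emits
    G ~ Geometric (support >= 1, mean ``loc_per_ab_mean``) localizations at its
    projected position plus isotropic Gaussian noise of ``sigma_loc_nm`` per
    axis, on consecutive frames. Background localizations are homogeneous
    Poisson at ``bg_density_per_um2``. Rows are sorted by ROI then frame.
    """
    stained = [s for s in assay.stain_panel if s in captured.columns]
    n_ev = len(captured)

    # antibodies per vesicle: binomial thinning of each stained species
    n_ab = np.zeros(n_ev, dtype=int)
    for species in stained:
        n_ab += rng.binomial(captured[species].to_numpy(), assay.labeling_efficiency)

    parent = np.repeat(np.arange(n_ev), n_ab)  # EV index per antibody
    diam = captured["diameter_nm"].to_numpy()[parent]
    centers = captured[["x_nm", "y_nm"]].to_numpy()[parent]
    ab_xy = centers + _uniform_sphere_xy(diam, rng)

    n_loc = rng.geometric(1.0 / assay.loc_per_ab_mean, size=parent.size)
    loc_parent_ab = np.repeat(np.arange(parent.size), n_loc)
    loc_roi = captured["roi_id"].to_numpy()[parent][loc_parent_ab] if parent.size else np.array([], int)
    loc_xy = ab_xy[loc_parent_ab] + rng.normal(0.0, assay.sigma_loc_nm, size=(loc_parent_ab.size, 2))
    # vesicles sit inside the ROI; localizations straying over the edge are
    # clipped to the field of view
    loc_xy = np.clip(loc_xy, 0.0, assay.roi_side_nm)

    # consecutive frames per antibody burst; frame counters restart per ROI
    # (rows are already in antibody order, antibodies in ROI order)
    roi_of_ab = captured["roi_id"].to_numpy()[parent]
    if loc_parent_ab.size:
        roi_of_loc = roi_of_ab[loc_parent_ab]
        sort_idx = np.argsort(roi_of_loc, kind="stable")
        inv = np.empty_like(sort_idx)
        inv[sort_idx] = np.arange(sort_idx.size)
        sorted_roi = roi_of_loc[sort_idx]
        start_of_roi = np.r_[0, np.flatnonzero(np.diff(sorted_roi)) + 1]
        within = np.arange(sort_idx.size) - np.repeat(
            start_of_roi, np.diff(np.r_[start_of_roi, sort_idx.size])
        )
        frames = within[inv]
    else:
        frames = np.array([], dtype=int)

    ev_part = pd.DataFrame(
        {
            "roi_id": loc_roi,
            "x_nm": loc_xy[:, 0] if loc_parent_ab.size else np.array([]),
            "y_nm": loc_xy[:, 1] if loc_parent_ab.size else np.array([]),
            "frame": frames,
            "precision_nm": np.full(loc_parent_ab.size, float(assay.sigma_loc_nm)),
        }
    )

    # homogeneous Poisson background, uniform positions and frames
    area_um2 = assay.roi_area_nm2 / 1e6
    n_bg = rng.poisson(assay.bg_density_per_um2 * area_um2, size=assay.n_roi)
    bg_roi = np.repeat(np.arange(assay.n_roi), n_bg)
    total_bg = int(n_bg.sum())
    max_frame = int(frames.max()) + 1 if frames.size else 1
    bg_part = pd.DataFrame(
        {
            "roi_id": bg_roi,
            "x_nm": rng.uniform(0.0, assay.roi_side_nm, total_bg),
            "y_nm": rng.uniform(0.0, assay.roi_side_nm, total_bg),
            "frame": rng.integers(0, max_frame, total_bg),
            "precision_nm": np.full(total_bg, float(assay.sigma_loc_nm)),
        }
    )

    out = pd.concat([ev_part, bg_part], ignore_index=True)
    out = out.sort_values(["roi_id", "frame"], kind="stable").reset_index(drop=True)
    return out[LOC_COLUMNS].astype(
        {"roi_id": int, "x_nm": float, "y_nm": float, "frame": int, "precision_nm": float}
    )


def simulate_condition(
    cfg: PopulationConfig, assay: AssayDesign, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Population -> capture -> localization table for one assay condition.

    Returns ``(locs, captured, truth)``.
    """
    truth = sample_ev_population(cfg, assay, rng)
    captured = simulate_capture(truth, assay, rng)
    locs = render_localizations(captured, assay, rng)
    return locs, captured, truth


def render_shell_cluster(
    diameter_nm: float,
    n_antibodies: int,
    assay: AssayDesign,
    rng: np.random.Generator,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Localizations of a single vesicle with a fixed number of bound antibodies.

    Bypasses Poisson copy numbers and binomial labeling; used to probe the
    diameter estimator against the projection geometry it assumes.
    """
    d = np.full(n_antibodies, float(diameter_nm))
    ab_xy = np.asarray(center, float) + _uniform_sphere_xy(d, rng)
    n_loc = rng.geometric(1.0 / assay.loc_per_ab_mean, size=n_antibodies)
    xy = ab_xy[np.repeat(np.arange(n_antibodies), n_loc)]
    return xy + rng.normal(0.0, assay.sigma_loc_nm, size=xy.shape)
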