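"""Reusable study drivers: simulated recovery experiments and published ratios.

These functions assemble the pipeline stages into the experiment designs the
package exists to analyse: a two-capture biofluid experiment whose
tracer-specific/total concentration ratio estimates the labeled cell type's
contribution, a spherical-shell study probing the diameter estimator, and
the contribution arithmetic applied to the published concentration tables.
"""
from __future__ import annotations

import numpy as np

from .config import AssayDesign, PhenotypeParams, PopulationConfig, SegmentationParams
from .phenotype import estimate_diameter
from .pipeline import process_localizations
from .quantify import (
    ConcentrationEstimate,
    concentration,
    contribution_fraction,
)
from .reference_data import HEPATOCYTE_PLASMA, IN_TEXT, NEURON_CSF, NEURON_PLASMA
from .simulate import render_shell_cluster, simulate_condition
from .tessellation import VoronoiCluster

MOUSE_PANEL = ("MmCD9", "MmCD63", "MmCD81")


def _condition_concentration(
    pop: PopulationConfig,
    assay: AssayDesign,
    rng: np.random.Generator,
    seg: SegmentationParams,
    phen: PhenotypeParams,
) -> ConcentrationEstimate:
    locs, _, _ = simulate_condition(pop, assay, rng)
    _, evs = process_localizations(locs, assay.roi_side_nm, seg, phen)
    return concentration(evs, assay.n_roi, assay.volume_ul)


def recovery_experiment(
    rng: np.random.Generator,
    labeled_fraction: float = 0.15,
    n_roi: int = 20,
    n_ev_per_roi_mean: float = 15.0,
    hs_copy_mean: float = 8.0,
    capture_prob: float = 0.35,
    include_stain_based: bool = False,
    n_boot: int = 10_000,
) -> dict:
    """One simulated two-capture experiment on a common vesicle population.

    The "total" condition captures on the mouse CD81 antibody, the
    "specific" condition on the human CD81 antibody; both are stained with
    the mouse tetraspanin panel, so the specific/total concentration ratio
    estimates ``labeled_fraction``. With ``hs_copy_mean`` equal to the mouse
    per-species copy mean the capture efficiencies are symmetric and the
    ratio is unbiased; a low ``hs_copy_mean`` (sparse tracer) reproduces the
    capture-vs-stain sensitivity asymmetry.

    With ``include_stain_based`` a third condition (mouse capture, human
    CD81 stain) estimates the same fraction through immunostaining, which
    requires at least three detected tracer proteins per vesicle and is
    therefore less sensitive than capture, which a single engaged epitope
    can trigger.

    Returns a dict with the capture-based ``fraction``, its ``ci95``, the
    per-condition concentrations and, optionally, ``stain_fraction``.
    """
    tspan = {"MmCD9": 8.0, "MmCD63": 8.0, "MmCD81": 8.0, "HsCD81": hs_copy_mean}
    pop = PopulationConfig(
        n_ev_per_roi_mean=n_ev_per_roi_mean,
        tspan_mean=tspan,
        labeled_fraction=labeled_fraction,
    )
    seg, phen = SegmentationParams(), PhenotypeParams()
    common = dict(
        stain_panel=MOUSE_PANEL,
        volume_ul=1.0,
        n_roi=n_roi,
        capture_prob_per_epitope=capture_prob,
    )
    total = _condition_concentration(
        pop, AssayDesign(capture_species="MmCD81", **common), rng, seg, phen
    )
    specific = _condition_concentration(
        pop, AssayDesign(capture_species="HsCD81", **common), rng, seg, phen
    )
    contrib = contribution_fraction(specific, total, n_boot=n_boot, rng=rng)
    out = {
        "fraction": contrib.fraction,
        "ci95": contrib.ci95,
        "specific": specific,
        "total": total,
    }
    if include_stain_based:
        stain_assay = AssayDesign(
            capture_species="MmCD81",
            stain_panel=("HsCD81",),
            volume_ul=1.0,
            n_roi=n_roi,
            capture_prob_per_epitope=capture_prob,
        )
        stained = _condition_concentration(pop, stain_assay, rng, seg, phen)
        out["stain_fraction"] = stained.mean / total.mean if total.mean > 0 else 0.0
        out["stain_specific"] = stained
    return out


def shell_diameter_study(
    rng: np.random.Generator,
    n_vesicles: int = 500,
    diameter_nm: float = 80.0,
    n_antibodies: int = 30,
    sigma_loc_nm: float = 10.0,
) -> dict:
    """Diameter-estimator recovery on simulated spherical shells.

    Renders ``n_vesicles`` isolated vesicles of known diameter with a fixed
    number of bound antibodies, computes each cluster's second moment, and
    applies the estimator. Returns the mean estimate and its relative error.
    """
    assay = AssayDesign(sigma_loc_nm=sigma_loc_nm, bg_density_per_um2=0.0)
    phen = PhenotypeParams(sigma_loc_nm=sigma_loc_nm)
    estimates = np.empty(n_vesicles)
    for i in range(n_vesicles):
        xy = render_shell_cluster(diameter_nm, n_antibodies, assay, rng)
        c = xy.mean(axis=0)
        msr = float(np.mean(np.sum((xy - c) ** 2, axis=1)))
        cluster = VoronoiCluster(
            roi_id=0,
            cluster_id=i,
            member_indices=np.arange(len(xy)),
            n_loc=len(xy),
            centroid_xy_nm=(float(c[0]), float(c[1])),
            mean_sq_radius_nm2=msr,
            touches_boundary=False,
            mean_precision_nm=sigma_loc_nm,
        )
        estimates[i] = estimate_diameter(cluster, phen)
    mean_est = float(estimates.mean())
    return {
        "mean_diameter_nm": mean_est,
        "relative_error": abs(mean_est - diameter_nm) / diameter_nm,
        "estimates": estimates,
    }


def published_contributions() -> dict:
    """Headline contribution percentages from the published concentration tables.

    Ratios of tracer-specific to total mean concentrations (EV/ROI/uL) for
    the hepatocyte (plasma) and neuron (plasma and CSF) experiments, plus
    the capture-vs-stain sensitivity fold for the doubly-human condition.
    Uses the in-text rounded concentrations where the running text's
    arithmetic was based on them.
    """
    hep_stain = contribution_fraction(
        ConcentrationEstimate.from_mean(HEPATOCYTE_PLASMA["cre_mm_capture_hs_stain"]["mean"]),
        ConcentrationEstimate.from_mean(HEPATOCYTE_PLASMA["cre_mm_capture_mm_stain"]["mean"]),
        control_specific=ConcentrationEstimate.from_mean(
            HEPATOCYTE_PLASMA["ctrl_mm_capture_hs_stain"]["mean"]
        ),
        control_total=ConcentrationEstimate.from_mean(
            HEPATOCYTE_PLASMA["ctrl_mm_capture_mm_stain"]["mean"]
        ),
    )
    hep_capture = contribution_fraction(
        ConcentrationEstimate.from_mean(IN_TEXT["hepatocyte_hs_capture_mm_stain"]),
        ConcentrationEstimate.from_mean(HEPATOCYTE_PLASMA["cre_mm_capture_mm_stain"]["mean"]),
    )
    neuron_plasma = contribution_fraction(
        ConcentrationEstimate.from_mean(NEURON_PLASMA["cre_hs_capture"]["mean"]),
        ConcentrationEstimate.from_mean(NEURON_PLASMA["cre_mm_capture"]["mean"]),
        control_specific=ConcentrationEstimate.from_mean(NEURON_PLASMA["ctrl_hs_capture"]["mean"]),
        control_total=ConcentrationEstimate.from_mean(NEURON_PLASMA["ctrl_mm_capture"]["mean"]),
    )
    neuron_csf = contribution_fraction(
        ConcentrationEstimate.from_mean(NEURON_CSF["cre_hs_capture"]["mean"]),
        ConcentrationEstimate.from_mean(NEURON_CSF["cre_mm_capture"]["mean"]),
        control_specific=ConcentrationEstimate.from_mean(NEURON_CSF["ctrl_hs_capture"]["mean"]),
        control_total=ConcentrationEstimate.from_mean(NEURON_CSF["ctrl_mm_capture"]["mean"]),
    )
    capture_vs_stain_fold = (
        IN_TEXT["hepatocyte_hs_capture_mm_stain"] / IN_TEXT["hepatocyte_hs_capture_hs_stain"]
    )
    return {
        "hepatocyte_plasma_stain": hep_stain,
        "hepatocyte_plasma_capture": hep_capture,
        "neuron_plasma": neuron_plasma,
        "neuron_csf": neuron_csf,
        "capture_vs_stain_fold": capture_vs_stain_fold,
    }
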