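"""End-to-end orchestration: simulate -> cluster -> phenotype -> quantify.

A pipeline configuration (YAML or dict) declares one vesicle population, the
segmentation and phenotyping parameters, a set of assay conditions (capture
antibody, stain panel, volume, ROI count) and the contribution contrasts
between them. All randomness flows through one seeded generator; the seed
and every stage's parameters are echoed into the report for provenance.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AssayDesign, PhenotypeParams, PopulationConfig, SegmentationParams
from .errors import ConfigError, DegenerateGeometryError
from .io import clusters_to_frame, write_localizations, write_truth
from .phenotype import call_evs, evs_to_frame
from .quantify import concentration, contribution_fraction, summary_report
from .simulate import simulate_condition
from .tessellation import segment_clusters, tessellate

logger = logging.getLogger("sevenq")


def process_localizations(
    locs: pd.DataFrame,
    roi_side_nm: float,
    seg_params: SegmentationParams | None = None,
    phen_params: PhenotypeParams | None = None,
) -> tuple[list, pd.DataFrame]:
    """Segment and phenotype a localization table, ROI by ROI.

    Returns ``(clusters, ev_table)``. ROIs with too few or degenerate
    localizations yield no clusters (logged), not an error: an almost-empty
    field of view is a valid observation.
    """
    seg_params = seg_params or SegmentationParams()
    phen_params = phen_params or PhenotypeParams()
    bounds = (0.0, 0.0, roi_side_nm, roi_side_nm)
    all_clusters = []
    for roi_id, grp in locs.groupby("roi_id", sort=True):
        pts = grp[["x_nm", "y_nm"]].to_numpy()
        try:
            tess = tessellate(pts, bounds, roi_id=int(roi_id))
        except DegenerateGeometryError as exc:
            logger.info("skipping segmentation: %s", exc)
            continue
        clusters = segment_clusters(
            tess,
            seg_params,
            roi_id=int(roi_id),
            precisions=grp["precision_nm"].to_numpy(),
        )
        logger.debug(
            "ROI %s: %d localizations -> %d clusters", roi_id, len(grp), len(clusters)
        )
        all_clusters.extend(clusters)
    calls = call_evs(all_clusters, phen_params)
    logger.debug("%d clusters -> %d EV calls", len(all_clusters), len(calls))
    return all_clusters, evs_to_frame(calls)


def _build_configs(config: dict):
    pop = PopulationConfig(**config.get("population", {}))
    seg = SegmentationParams(**config.get("segmentation", {}))
    phen = PhenotypeParams(**config.get("phenotype", {}))
    conditions = config.get("conditions")
    if not conditions:
        raise ConfigError("pipeline config must declare at least one condition")
    assays = {name: AssayDesign(**block) for name, block in conditions.items()}
    contrasts = config.get("contrasts", {})
    for name, block in contrasts.items():
        for role in ("specific", "total"):
            if role not in block:
                raise ConfigError(f"contrast {name!r} is missing its {role!r} condition")
            if block[role] not in assays:
                raise ConfigError(
                    f"contrast {name!r} references unknown condition {block[role]!r}"
                )
        for role in ("control_specific", "control_total"):
            if role in block and block[role] not in assays:
                raise ConfigError(
                    f"contrast {name!r} references unknown condition {block[role]!r}"
                )
    return pop, seg, phen, assays, contrasts


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> Path:
    """Run the full simulated experiment described by ``config``.

    Writes per-condition localization, ground-truth, cluster and EV tables
    plus ``report.json`` under ``out_dir`` and returns the report path.
    """
    pop, seg, phen, assays, contrasts = _build_configs(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    estimates = {}
    for name, assay in assays.items():
        locs, captured, truth = simulate_condition(pop, assay, rng)
        clusters, evs = process_localizations(locs, assay.roi_side_nm, seg, phen)
        write_localizations(locs, out_dir / f"{name}_localizations.csv")
        write_truth(truth, out_dir / f"{name}_truth.csv")
        clusters_to_frame(clusters).to_csv(out_dir / f"{name}_clusters.csv", index=False)
        evs.to_csv(out_dir / f"{name}_evs.csv", index=False)
        estimates[name] = concentration(evs, assay.n_roi, assay.volume_ul)
        logger.info(
            "condition %s: %d localizations, %d clusters, %d EV calls, "
            "%.2f EV/ROI/uL",
            name, len(locs), len(clusters), len(evs), estimates[name].mean,
        )

    contribs = {}
    for name, block in contrasts.items():
        contribs[name] = contribution_fraction(
            estimates[block["specific"]],
            estimates[block["total"]],
            control_specific=estimates.get(block.get("control_specific")),
            control_total=estimates.get(block.get("control_total")),
            rng=rng,
        )

    report = summary_report(
        estimates,
        contribs,
        params={
            "seed": seed,
            "population": dataclasses.asdict(pop),
            "segmentation": dataclasses.asdict(seg),
            "phenotype": dataclasses.asdict(phen),
            "conditions": {n: dataclasses.asdict(a) for n, a in assays.items()},
        },
    )
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=_jsonable))
    return report_path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
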