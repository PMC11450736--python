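"""Delimited-text table formats and YAML configuration.

All tables are comma-separated UTF-8 text with a mandatory header and ``.``
decimals, matching common SMLM localization-table exports. Coordinates are
in nm with the origin at the ROI's lower-left corner, y increasing upward.

Schemas
-------
localizations : ``roi_id,x_nm,y_nm,frame,precision_nm``
ground truth  : ``roi_id,ev_id,x_nm,y_nm,diameter_nm,<species...>,source_label``
clusters      : ``roi_id,cluster_id,n_loc,centroid_x_nm,centroid_y_nm,
                 mean_sq_radius_nm2,touches_boundary,mean_precision_nm``
EV calls      : ``roi_id,cluster_id,n_loc,est_proteins,est_diameter_nm``
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .phenotype import EV_COLUMNS
from .simulate import LOC_COLUMNS

logger = logging.getLogger("sevenq")

CLUSTER_COLUMNS = [
    "roi_id",
    "cluster_id",
    "n_loc",
    "centroid_x_nm",
    "centroid_y_nm",
    "mean_sq_radius_nm2",
    "touches_boundary",
    "mean_precision_nm",
]


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a localization table, dropping malformed rows with a logged count.

    Raises :class:`FormatError` when the header does not carry the expected
    columns; an empty file yields an empty table with a warning.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty localization file", path)
        return pd.DataFrame(columns=LOC_COLUMNS)
    missing = [c for c in LOC_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(
            f"{path}: missing columns {missing}; expected header "
            f"{','.join(LOC_COLUMNS)}"
        )
    raw = raw[LOC_COLUMNS]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    ok = np.isfinite(numeric[["x_nm", "y_nm", "precision_nm"]]).all(axis=1)
    ok &= numeric["roi_id"].notna() & numeric["frame"].notna()
    ok &= numeric["precision_nm"] >= 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: rejected %d malformed row(s) of %d", path, n_bad, len(raw))
    out = numeric.loc[ok].reset_index(drop=True)
    return out.astype(
        {"roi_id": int, "x_nm": float, "y_nm": float, "frame": int, "precision_nm": float}
    )


def write_localizations(locs: pd.DataFrame, path: str | Path) -> None:
    locs[LOC_COLUMNS].to_csv(path, index=False)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def clusters_to_frame(clusters) -> pd.DataFrame:
    """Cluster collection -> table (member indices are not serialized)."""
    rows = [
        (
            cl.roi_id,
            cl.cluster_id,
            cl.n_loc,
            cl.centroid_xy_nm[0],
            cl.centroid_xy_nm[1],
            cl.mean_sq_radius_nm2,
            cl.touches_boundary,
            cl.mean_precision_nm if cl.mean_precision_nm is not None else np.nan,
        )
        for cl in clusters
    ]
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def read_clusters(path: str | Path):
    """Read a cluster table back into :class:`VoronoiCluster` records."""
    from .tessellation import VoronoiCluster

    df = pd.read_csv(path)
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        prec = getattr(row, "mean_precision_nm")
        out.append(
            VoronoiCluster(
                roi_id=int(row.roi_id),
                cluster_id=int(row.cluster_id),
                member_indices=np.array([], int),
                n_loc=int(row.n_loc),
                centroid_xy_nm=(float(row.centroid_x_nm), float(row.centroid_y_nm)),
                mean_sq_radius_nm2=float(row.mean_sq_radius_nm2),
                touches_boundary=bool(row.touches_boundary),
                mean_precision_nm=None if pd.isna(prec) else float(prec),
            )
        )
    return out


def read_evs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}
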