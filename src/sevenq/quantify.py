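"""Concentrations, contribution fractions, and log-scale group comparisons.

Vesicle counts are summarized per ROI (the technical replicate unit) and
normalized to 1 uL of biofluid, giving EV/ROI/uL values whose mean, median,
SEM and CV match the layout of published single-EV nanoscopy concentration
tables. The contribution of a labeled cell type to a biofluid's exosome
population is the ratio of the tracer-specific concentration to the total
concentration, reported with a bootstrap interval and alongside (never
silently minus) the background ratio measured on a tracer-free control.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError


@dataclass
class ConcentrationEstimate:
    """Per-ROI EV concentrations (EV/ROI/uL) and their summary statistics."""

    per_roi_values: np.ndarray
    volume_ul: float
    mean: float = field(init=False)
    median: float = field(init=False)
    sem: float = field(init=False)
    cv: float = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.per_roi_values, float)
        self.per_roi_values = v
        self.mean = float(v.mean()) if v.size else 0.0
        self.median = float(np.median(v)) if v.size else 0.0
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        self.sem = sd / np.sqrt(v.size) if v.size > 1 else 0.0
        self.cv = sd / self.mean if self.mean > 0 else 0.0

    @property
    def n_roi(self) -> int:
        return int(self.per_roi_values.size)

    @classmethod
    def from_mean(cls, mean: float, volume_ul: float = 1.0) -> "ConcentrationEstimate":
        """Summary-only estimate (e.g. a published table value); no ROI spread."""
        return cls(np.array([float(mean)]), volume_ul)


@dataclass
class ContributionEstimate:
    """Fraction of a biofluid's exosomes attributed to the labeled cell type."""

    fraction: float
    fraction_pct_rounded: int
    ci95: tuple[float, float] | None = None
    background_fraction: float | None = None

    @property
    def fraction_pct(self) -> float:
        return 100.0 * self.fraction


def concentration(
    evs: pd.DataFrame, n_roi: int, volume_ul: float
) -> ConcentrationEstimate:
    """Per-ROI concentrations from a table of vesicle calls.

    ROIs 0..n_roi-1 absent from the call table contribute explicit zeros,
    which matters for the SEM and CV of weak conditions.
    """
    if n_roi < 1:
        raise ConfigError("n_roi must be >= 1")
    if volume_ul <= 0:
        raise ConfigError("volume_ul must be > 0")
    counts = np.zeros(n_roi)
    if len(evs):
        got = evs.groupby("roi_id").size()
        idx = got.index.to_numpy(int)
        if (idx < 0).any() or (idx >= n_roi).any():
            raise ConfigError("EV call roi_id outside 0..n_roi-1")
        counts[idx] = got.to_numpy()
    return ConcentrationEstimate(counts / volume_ul, volume_ul)


def concentration_from_counts(counts, volume_ul: float) -> ConcentrationEstimate:
    """Per-ROI concentrations from raw per-ROI vesicle counts."""
    if volume_ul <= 0:
        raise ConfigError("volume_ul must be > 0")
    return ConcentrationEstimate(np.asarray(counts, float) / volume_ul, volume_ul)


def _bootstrap_ratio(
    specific: np.ndarray, total: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Percentile bootstrap CI of mean(specific)/mean(total) over ROIs.

    ROIs are resampled jointly when the two conditions have the same number
    of ROIs (paired technical replicates), independently otherwise.
    """
    ns, nt = specific.size, total.size
    if ns == nt:
        idx = rng.integers(0, ns, size=(n_boot, ns))
        s = specific[idx].mean(axis=1)
        t = total[idx].mean(axis=1)
    else:
        s = specific[rng.integers(0, ns, size=(n_boot, ns))].mean(axis=1)
        t = total[rng.integers(0, nt, size=(n_boot, nt))].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(t > 0, s / t, np.nan)
    lo, hi = np.nanpercentile(r, [2.5, 97.5])
    return float(lo), float(hi)


def contribution_fraction(
    specific: ConcentrationEstimate,
    total: ConcentrationEstimate,
    control_specific: ConcentrationEstimate | None = None,
    control_total: ConcentrationEstimate | None = None,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> ContributionEstimate:
    """Specific / total concentration ratio of per-ROI means.

    The bootstrap interval is computed when both estimates carry more than
    one ROI. A control-sample background ratio is attached when control
    estimates are supplied; it is reported, not subtracted.
    """
    if total.mean <= 0:
        raise ConfigError("total concentration mean is zero; ratio undefined")
    fraction = specific.mean / total.mean
    if fraction > 1:
        warnings.warn(
            f"specific exceeds total concentration (fraction {fraction:.3g})",
            stacklevel=2,
        )
    ci95 = None
    if specific.n_roi > 1 and total.n_roi > 1:
        rng = rng if rng is not None else np.random.default_rng(0)
        ci95 = _bootstrap_ratio(
            specific.per_roi_values, total.per_roi_values, n_boot, rng
        )
    background = None
    if control_specific is not None and control_total is not None:
        if control_total.mean > 0:
            background = control_specific.mean / control_total.mean
    return ContributionEstimate(
        fraction=float(fraction),
        fraction_pct_rounded=int(np.floor(100.0 * fraction + 0.5)),
        ci95=ci95,
        background_fraction=background,
    )


def compare_log(*groups) -> tuple[float, list[float]]:
    """Two-sided test on log-transformed values; geometric means per group.

    Skewed per-vesicle quantities (diameters, proteins per vesicle) are
    compared after natural-log transformation: Student's t-test for two
    groups, one-way ANOVA for more. Returns ``(p_value, geometric_means)``.
    """
    if len(groups) < 2:
        raise ConfigError("need at least two groups")
    logs = []
    for g in groups:
        arr = np.asarray(g, float)
        if arr.size < 2:
            raise ConfigError("each group needs >= 2 values")
        if (arr <= 0).any():
            raise ConfigError(
                "non-positive values cannot be log-transformed; exclude them upstream"
            )
        logs.append(np.log(arr))
    gmeans = [float(np.exp(l.mean())) for l in logs]
    variances = [l.var(ddof=1) for l in logs]
    if max(variances) == 0.0:
        # degenerate: no within-group spread
        means = [l.mean() for l in logs]
        p = 1.0 if np.ptp(means) == 0.0 else 0.0
        if p == 0.0:
            warnings.warn("zero within-group variance with distinct means", stacklevel=2)
        return p, gmeans
    if len(logs) == 2:
        res = stats.ttest_ind(logs[0], logs[1])
    else:
        res = stats.f_oneway(*logs)
    return float(res.pvalue), gmeans


def summary_report(
    conditions: dict[str, ConcentrationEstimate],
    contrasts: dict[str, ContributionEstimate] | None = None,
    params: dict | None = None,
) -> dict:
    """Machine-readable summary mirroring a published concentration table.

    One block per capture/stain condition (mean, median, SEM, CV, n_roi,
    volume) plus one block per contribution contrast. ROI-count mismatches
    between conditions are recorded as warnings in the report, not raised.
    """
    report: dict = {"conditions": {}, "contrasts": {}, "warnings": []}
    n_rois = {name: est.n_roi for name, est in conditions.items()}
    if len(set(n_rois.values())) > 1:
        report["warnings"].append(f"ROI counts differ between conditions: {n_rois}")
    for name, est in conditions.items():
        report["conditions"][name] = {
            "mean": est.mean,
            "median": est.median,
            "sem": est.sem,
            "cv": est.cv,
            "n_roi": est.n_roi,
            "volume_ul": est.volume_ul,
        }
    for name, contrib in (contrasts or {}).items():
        report["contrasts"][name] = {
            "fraction": contrib.fraction,
            "fraction_pct": contrib.fraction_pct,
            "fraction_pct_rounded": contrib.fraction_pct_rounded,
            "ci95": list(contrib.ci95) if contrib.ci95 is not None else None,
            "background_fraction": contrib.background_fraction,
        }
    if params:
        report["params"] = params
    return report
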