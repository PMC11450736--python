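"""Concentration summaries, contribution fractions, log-scale comparisons."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sevenq import (
    ConcentrationEstimate,
    ConfigError,
    compare_log,
    concentration,
    concentration_from_counts,
    contribution_fraction,
    summary_report,
)


def _evs(counts):
    """EV-call table with the given number of calls in ROIs 0..len-1."""
    rows = [(roi, i, 140, 10, 80.0) for roi, n in enumerate(counts) for i in range(n)]
    return pd.DataFrame(
        rows, columns=["roi_id", "cluster_id", "n_loc", "est_proteins", "est_diameter_nm"]
    )


def test_constant_counts_have_zero_spread():
    est = concentration(_evs([5, 5, 5, 5]), n_roi=4, volume_ul=1.0)
    assert (est.mean, est.median, est.sem, est.cv) == (5.0, 5.0, 0.0, 0.0)


def test_volume_normalization():
    est = concentration(_evs([25] * 6), n_roi=6, volume_ul=5.0)
    assert est.mean == 5.0


def test_missing_rois_count_as_zero():
    est = concentration(_evs([4, 4]), n_roi=4, volume_ul=1.0)
    assert est.n_roi == 4
    assert est.mean == 2.0 and est.median == 2.0
    assert est.sem > 0


def test_csf_normalization_inverts_to_raw_counts():
    """0.4 EV/ROI/uL at 6 uL over 10 ROIs corresponds to 2.4 raw calls/ROI."""
    est = concentration_from_counts([2.4] * 10, volume_ul=6.0)
    assert np.isclose(est.mean, 0.4)


def test_empty_call_table():
    est = concentration(_evs([]), n_roi=10, volume_ul=1.0)
    assert est.mean == 0.0 and est.cv == 0.0 and est.sem == 0.0


def test_invalid_volume_rejected():
    with pytest.raises(ConfigError):
        concentration(_evs([1]), n_roi=1, volume_ul=0.0)


def test_contribution_fraction_published_arithmetic():
    out = contribution_fraction(
        ConcentrationEstimate.from_mean(23.0), ConcentrationEstimate.from_mean(202.0)
    )
    assert np.isclose(out.fraction, 23.0 / 202.0)
    assert out.fraction_pct_rounded == 11
    out2 = contribution_fraction(
        ConcentrationEstimate.from_mean(3.3), ConcentrationEstimate.from_mean(259.0)
    )
    assert out2.fraction_pct_rounded == 1


def test_zero_specific_signal_gives_zero_fraction():
    out = contribution_fraction(
        ConcentrationEstimate.from_mean(0.0), ConcentrationEstimate.from_mean(100.0)
    )
    assert out.fraction == 0.0


def test_zero_total_is_an_error():
    with pytest.raises(ConfigError):
        contribution_fraction(
            ConcentrationEstimate.from_mean(1.0), ConcentrationEstimate.from_mean(0.0)
        )


def test_fraction_above_one_warns():
    with pytest.warns(UserWarning, match="exceeds total"):
        contribution_fraction(
            ConcentrationEstimate.from_mean(5.0), ConcentrationEstimate.from_mean(2.0)
        )


def test_bootstrap_interval_brackets_the_estimate(rng):
    spec = concentration_from_counts(rng.poisson(3.0, 20), 1.0)
    tot = concentration_from_counts(rng.poisson(20.0, 20), 1.0)
    out = contribution_fraction(spec, tot, rng=rng)
    lo, hi = out.ci95
    assert lo <= out.fraction <= hi
    assert 0 <= lo < hi


def test_background_is_reported_not_subtracted():
    out = contribution_fraction(
        ConcentrationEstimate.from_mean(3.3),
        ConcentrationEstimate.from_mean(259.0),
        control_specific=ConcentrationEstimate.from_mean(1.7),
        control_total=ConcentrationEstimate.from_mean(648.0),
    )
    assert np.isclose(out.background_fraction, 1.7 / 648.0)
    assert np.isclose(out.fraction, 3.3 / 259.0)  # unchanged by the control


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.floats(min_value=0.01, max_value=100.0))
def test_fraction_invariant_to_volume_rescaling(c):
    """Scaling both incubation volumes by c leaves the fraction unchanged."""
    counts_s, counts_t = [2, 3, 1, 4], [20, 25, 18, 22]
    base = contribution_fraction(
        concentration_from_counts(counts_s, 1.0),
        concentration_from_counts(counts_t, 1.0),
    )
    scaled = contribution_fraction(
        concentration_from_counts(counts_s, c),
        concentration_from_counts(counts_t, c),
    )
    assert np.isclose(base.fraction, scaled.fraction)


def test_identical_groups_are_not_distinguishable():
    p, gmeans = compare_log([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
    assert p > 0.99
    assert np.isclose(gmeans[0], gmeans[1])


def test_separated_lognormal_groups_detected(rng):
    a = rng.lognormal(0.0, 0.3, 100)
    b = rng.lognormal(1.0, 0.3, 100)
    p, gmeans = compare_log(a, b)
    assert p < 1e-6
    assert gmeans[0] < gmeans[1]


def test_three_groups_use_anova(rng):
    groups = [rng.lognormal(m, 0.3, 50) for m in (0.0, 0.0, 1.0)]
    p, _ = compare_log(*groups)
    assert p < 1e-6


def test_degenerate_variance_handled():
    import math
    with pytest.warns(UserWarning, match="zero within-group variance"):
        p, _ = compare_log([1.0, 1.0], [math.e, math.e])
    assert p == 0.0
    p_same, _ = compare_log([1.0, 1.0], [1.0, 1.0])
    assert p_same == 1.0


def test_nonpositive_values_rejected():
    with pytest.raises(ConfigError, match="upstream"):
        compare_log([1.0, 2.0], [0.0, 3.0])


def test_summary_report_is_internally_consistent(rng):
    counts = rng.poisson(10, 20)
    est = concentration_from_counts(counts, 1.0)
    report = summary_report({"total": est}, params={"seed": 0})
    block = report["conditions"]["total"]
    v = est.per_roi_values
    assert np.isclose(block["cv"], v.std(ddof=1) / v.mean(), atol=1e-12)
    assert np.isclose(block["sem"], v.std(ddof=1) / np.sqrt(v.size), atol=1e-12)
    assert block["n_roi"] == 20
    assert report["params"]["seed"] == 0


def test_summary_report_echoes_published_means():
    conditions = {
        "cre_mm_capture_mm_stain": ConcentrationEstimate.from_mean(202.0),
        "ctrl_mm_capture_mm_stain": ConcentrationEstimate.from_mean(517.0),
        "cre_mm_capture_hs_stain": ConcentrationEstimate.from_mean(23.0),
        "cre_hs_capture_mm_stain": ConcentrationEstimate.from_mean(35.4),
    }
    report = summary_report(conditions)
    got = {k: v["mean"] for k, v in report["conditions"].items()}
    assert got == {
        "cre_mm_capture_mm_stain": 202.0,
        "ctrl_mm_capture_mm_stain": 517.0,
        "cre_mm_capture_hs_stain": 23.0,
        "cre_hs_capture_mm_stain": 35.4,
    }


def test_summary_report_warns_on_roi_mismatch():
    report = summary_report(
        {
            "a": concentration_from_counts([1, 2, 3], 1.0),
            "b": concentration_from_counts([1, 2], 1.0),
        }
    )
    assert any("ROI counts differ" in w for w in report["warnings"])


def test_empty_ev_set_reports_zeros():
    report = summary_report({"empty": concentration(_evs([]), 5, 1.0)})
    block = report["conditions"]["empty"]
    assert block["mean"] == 0.0 and block["median"] == 0.0
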