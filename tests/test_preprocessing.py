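"""Baseline shifting, pooled-SD normalization and first-difference rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratenet import (
    PreprocessConfig,
    baseline_shift,
    estimate_rates,
    normalize,
    preprocess,
)
from ratenet.io_formats import POST_BASELINE_TIMEPOINTS

from conftest import build_cohort, schedule_frame

CFG_NO_NORM = PreprocessConfig(normalize_mode="none", min_intervals_per_metabolite=1)
CFG_SMALL = PreprocessConfig(min_intervals_per_metabolite=1)


def test_baseline_shift_arithmetic():
    cohort = build_cohort(
        {"p1": schedule_frame({"Lactate": lambda t: 2.0 if t == 0 else 3.5})}
    )
    shifted = baseline_shift(cohort)
    assert shifted.concentrations.loc["p1_BS", "Lactate"] == 0.0
    assert shifted.concentrations.loc["p1_S45", "Lactate"] == pytest.approx(1.5)


def test_baseline_shift_constant_trajectory_is_zero():
    cohort = build_cohort({"p1": schedule_frame({"Glucose": lambda t: 4.2})})
    shifted = baseline_shift(cohort)
    assert (shifted.concentrations["Glucose"] == 0).all()


def test_baseline_shift_missing_bs_excludes_animal(caplog):
    frames = {
        "p1": schedule_frame({"Lactate": lambda t: 1 + t}),
        "p2": schedule_frame({"Lactate": lambda t: 2 + t}, timepoints=["S45", "FR2"]),
        "p3": schedule_frame({"Lactate": lambda t: 3 + t}),
    }
    with caplog.at_level("WARNING"):
        shifted = baseline_shift(build_cohort(frames))
    assert shifted.animals == ["p1", "p3"]
    assert "p2" in caplog.text


def test_normalize_unit_pooled_sd():
    cohort = build_cohort(
        {"p1": schedule_frame({"Lactate": lambda t: 0.3 * t, "Glucose": lambda t: 5.0})}
    )
    shifted = baseline_shift(cohort)
    post = shifted.concentrations.loc[shifted.post_baseline_mask()]
    expected_scale = post["Lactate"].std(ddof=1)
    normalized = normalize(shifted)
    post_norm = normalized.concentrations.loc[normalized.post_baseline_mask()]
    assert post_norm["Lactate"].std(ddof=1) == pytest.approx(1.0)
    assert np.allclose(
        normalized.concentrations["Lactate"],
        shifted.concentrations["Lactate"] / expected_scale,
    )


def test_normalize_degenerate_column_flagged_unchanged():
    cohort = build_cohort(
        {"p1": schedule_frame({"Flat": lambda t: 1.0, "Moving": lambda t: t})}
    )
    shifted = baseline_shift(cohort)
    normalized = normalize(shifted)
    assert "Flat" in normalized.degenerate
    assert (normalized.concentrations["Flat"] == 0).all()  # shifted but unscaled


def test_normalize_requires_shift():
    cohort = build_cohort({"p1": schedule_frame({"Lactate": lambda t: 1 + t})})
    with pytest.raises(ValueError, match="shifted"):
        normalize(cohort)


def test_unit_rescale_invariance_of_normalized_values():
    """Changing a raw column's units leaves the normalized column unchanged."""
    frames = {
        f"p{k}": schedule_frame({"Lactate": lambda t, k=k: 1 + 0.1 * k * t})
        for k in range(1, 4)
    }
    cohort = build_cohort(frames)
    rescaled = build_cohort(
        {
            a: f.assign(Lactate=f["Lactate"] * 1000.0)
            for a, f in frames.items()
        }
    )
    a = normalize(baseline_shift(cohort))
    b = normalize(baseline_shift(rescaled))
    pd.testing.assert_frame_equal(a.concentrations, b.concentrations)


def test_rates_constant_series_zero():
    cohort = build_cohort({"p1": schedule_frame({"Glucose": lambda t: 3.0})})
    shifted = baseline_shift(cohort)
    panel = estimate_rates(
        normalize(shifted, CFG_NO_NORM), CFG_NO_NORM
    )
    assert np.allclose(panel.rates, 0.0)


def test_rates_linear_series_exact():
    cohort = build_cohort({"p1": schedule_frame({"Lactate": lambda t: 2.0 * t})})
    _, panel = (
        normalize(baseline_shift(cohort), CFG_NO_NORM),
        estimate_rates(normalize(baseline_shift(cohort), CFG_NO_NORM), CFG_NO_NORM),
    )
    assert np.allclose(panel.rates, 2.0, atol=1e-12)


def test_complete_animal_interval_schedule():
    cohort = build_cohort({"p1": schedule_frame({"Lactate": lambda t: t})})
    panel = estimate_rates(normalize(baseline_shift(cohort), CFG_NO_NORM), CFG_NO_NORM)
    got = list(zip(panel.intervals["t_start"], panel.intervals["t_end"]))
    assert got == [(0.75, 3.0), (3.0, 5.0), (5.0, 9.0), (9.0, 17.0), (17.0, 21.0)]


def test_interval_dropped_when_endpoint_missing():
    frames = {
        "p1": schedule_frame(
            {"Lactate": lambda t: t},
            timepoints=["BS", "S45", "FR2", "FR4", "FR16", "FR20"],  # FR8 missing
        )
    }
    panel = estimate_rates(
        normalize(baseline_shift(build_cohort(frames)), CFG_NO_NORM), CFG_NO_NORM
    )
    got = set(zip(panel.intervals["t_start"], panel.intervals["t_end"]))
    assert got == {(0.75, 3.0), (3.0, 5.0), (17.0, 21.0)}


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    a=st.floats(-5, 5),
    b=st.floats(-2, 2),
)
def test_affine_trajectories_give_exact_rates(a, b):
    cohort = build_cohort(
        {
            "p1": schedule_frame({"Lactate": lambda t: 50 + a + b * t}),
            "p2": schedule_frame({"Lactate": lambda t: 49 + a + b * t}),
        }
    )
    panel = estimate_rates(normalize(baseline_shift(cohort), CFG_NO_NORM), CFG_NO_NORM)
    assert np.allclose(panel.rates, b, atol=1e-12)


def test_rates_invariant_to_animal_ordering():
    frames = {
        "p2": schedule_frame({"Lactate": lambda t: 1 + 0.3 * t}),
        "p1": schedule_frame({"Lactate": lambda t: 20 - 0.1 * t}),
    }
    reordered = {k: frames[k] for k in sorted(frames)}
    p_a = estimate_rates(normalize(baseline_shift(build_cohort(frames)), CFG_SMALL), CFG_SMALL)
    p_b = estimate_rates(
        normalize(baseline_shift(build_cohort(reordered)), CFG_SMALL), CFG_SMALL
    )
    pd.testing.assert_frame_equal(p_a.intervals, p_b.intervals)
    # pooled-SD summation order shifts the scale by one ulp between orderings
    assert np.allclose(p_a.rates, p_b.rates, rtol=1e-12, atol=0, equal_nan=True)


def test_midpoint_alignment_averages_endpoints():
    cfg = PreprocessConfig(
        normalize_mode="none", regressor_alignment="midpoint", min_intervals_per_metabolite=1
    )
    cohort = build_cohort({"p1": schedule_frame({"Lactate": lambda t: t})})
    panel = estimate_rates(normalize(baseline_shift(cohort), cfg), cfg)
    # first interval: shifted values at 0.75 and 3 are 0.75 and 3
    assert panel.regressors[0, 0] == pytest.approx((0.75 + 3.0) / 2)


def test_min_intervals_eligibility_flag():
    cohort = build_cohort({"p1": schedule_frame({"Lactate": lambda t: 1 + t})})
    cfg = PreprocessConfig(normalize_mode="none", min_intervals_per_metabolite=6)
    panel = estimate_rates(normalize(baseline_shift(cohort), cfg), cfg)
    assert "Lactate" not in panel.eligible  # only 5 intervals exist
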