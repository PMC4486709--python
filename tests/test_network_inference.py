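"""Sparse-path fitting, the acceptance criterion and the best-subset oracle."""

import numpy as np
import pytest

from ratenet import (
    InferenceConfig,
    best_subset_oracle,
    edge_sign,
    fit_sparse_predictor,
    identify_controlled_nodes,
)
from ratenet.network_inference import _path_supports

from conftest import panel_from_arrays

NAMES10 = (
    "alanine", "citrate", "glucose", "glycine", "lactate",
    "pyruvate", "serine", "succinate", "valine", "urea",
)


def _two_driver_panel(beta_succ=0.8, beta_lact=-0.6, noise=0.0, seed=0, n=160):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 10))
    rates = np.zeros((n, 10))
    y = beta_succ * X[:, NAMES10.index("succinate")] + beta_lact * X[:, NAMES10.index("lactate")]
    rates[:, NAMES10.index("glucose")] = y + noise * rng.standard_normal(n)
    return panel_from_arrays(X, rates, NAMES10)


def test_noiseless_two_driver_recovery_matches_oracle():
    """Both balanced drivers are required, found, and signed correctly."""
    panel = _two_driver_panel()
    fit = fit_sparse_predictor(panel, "glucose")
    assert fit.accepted
    assert fit.support == ("lactate", "succinate")
    assert edge_sign(fit, "succinate", panel) == "+"
    assert edge_sign(fit, "lactate", panel) == "-"
    oracle = best_subset_oracle(panel, "glucose", max_support=3)
    assert oracle.support == frozenset(fit.support)
    assert oracle.accepted


def test_dominant_driver_satisfies_criterion_alone():
    """A weak second driver is legitimately dropped by the sparsity rule.

    With coefficients 0.8 and -0.3 the single-driver predictor already has a
    mean error below half the mean rate magnitude, so both the path selection
    and the exhaustive oracle return the lone dominant driver.
    """
    panel = _two_driver_panel(beta_succ=0.8, beta_lact=-0.3)
    fit = fit_sparse_predictor(panel, "glucose")
    oracle = best_subset_oracle(panel, "glucose", max_support=3)
    assert fit.accepted
    assert fit.support == ("succinate",)
    assert oracle.support == frozenset(fit.support)


def test_all_zero_rates_no_signal():
    X = np.random.default_rng(1).standard_normal((40, 10))
    panel = panel_from_arrays(X, np.zeros((40, 10)), NAMES10)
    fit = fit_sparse_predictor(panel, "glucose")
    assert not fit.accepted
    assert fit.reason == "no-signal"
    assert fit.support == ()


def test_pure_noise_rejected():
    rng = np.random.default_rng(42)
    X = rng.standard_normal((160, 10))
    rates = rng.standard_normal((160, 10))
    panel = panel_from_arrays(X, rates, NAMES10)
    rejected = 0
    for name in NAMES10:
        fit = fit_sparse_predictor(panel, name)
        rejected += not fit.accepted
        assert fit.error_ratio > 0.5 or not fit.accepted
    assert rejected == 10


def test_acceptance_flag_reproducible_from_stored_errors():
    cfg = InferenceConfig()
    for seed, noise in ((0, 0.0), (1, 0.3), (2, 2.0)):
        panel = _two_driver_panel(noise=noise, seed=seed)
        for name in ("glucose", "alanine"):
            fit = fit_sparse_predictor(panel, name, cfg)
            expected = (
                fit.mean_abs_rate > cfg.rate_tolerance
                and fit.mean_abs_error < cfg.error_ratio_threshold * fit.mean_abs_rate
            )
            assert fit.accepted == expected


def test_support_size_monotone_along_path():
    panel = _two_driver_panel(noise=0.2)
    j = panel.index_of("glucose")
    X, y = panel.regressors, panel.rates[:, j]
    supports = _path_supports(X, y, InferenceConfig())
    ordered = sorted(supports.items(), key=lambda kv: -kv[1])
    sizes = [len(s) for s, _ in ordered]
    assert sizes == sorted(sizes)


def test_max_support_respected():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((200, 10))
    beta = rng.uniform(0.5, 1.0, 10) * rng.choice([-1, 1], 10)
    rates = np.zeros((200, 10))
    rates[:, 0] = X @ beta  # needs all 10 regressors
    panel = panel_from_arrays(X, rates, NAMES10)
    fit = fit_sparse_predictor(panel, NAMES10[0], InferenceConfig(max_support=4))
    assert len(fit.support) <= 4


def test_self_edge_flag():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((160, 10))
    rates = np.zeros((160, 10))
    j = NAMES10.index("glucose")
    rates[:, j] = -0.9 * X[:, j]
    panel = panel_from_arrays(X, rates, NAMES10)
    with_self = fit_sparse_predictor(panel, "glucose", InferenceConfig(allow_self_edge=True))
    assert with_self.accepted and with_self.support == ("glucose",)
    without = fit_sparse_predictor(panel, "glucose", InferenceConfig(allow_self_edge=False))
    assert "glucose" not in without.support
    assert not without.accepted


def test_edge_sign_requires_support_membership():
    panel = _two_driver_panel()
    fit = fit_sparse_predictor(panel, "glucose")
    with pytest.raises(ValueError, match="not in the support"):
        edge_sign(fit, "urea", panel)


def test_best_subset_oracle_refuses_wide_panels():
    rng = np.random.default_rng(0)
    names = tuple(f"m{i}" for i in range(13))
    X = rng.standard_normal((50, 13))
    rates = rng.standard_normal((50, 13))
    panel = panel_from_arrays(X, rates, names)
    with pytest.raises(ValueError, match="12"):
        best_subset_oracle(panel, "m0", max_support=3)


def test_best_subset_single_perfect_regressor():
    rng = np.random.default_rng(9)
    names = tuple(f"m{i}" for i in range(6))
    X = rng.standard_normal((80, 6))
    rates = np.zeros((80, 6))
    rates[:, 0] = 1.3 * X[:, 4]
    panel = panel_from_arrays(X, rates, names)
    oracle = best_subset_oracle(panel, "m0", max_support=3)
    assert oracle.support == frozenset({"m4"})
    assert oracle.accepted


def test_best_subset_pure_noise_empty_unaccepted():
    rng = np.random.default_rng(10)
    names = tuple(f"m{i}" for i in range(6))
    X = rng.standard_normal((120, 6))
    rates = rng.standard_normal((120, 6))
    panel = panel_from_arrays(X, rates, names)
    oracle = best_subset_oracle(panel, "m0", max_support=2)
    assert oracle.support == frozenset()
    assert not oracle.accepted


def test_identify_controlled_nodes_only_eligible():
    panel = _two_driver_panel()
    fits = identify_controlled_nodes(panel)
    assert [f.target for f in fits] == list(NAMES10)
    accepted = [f.target for f in fits if f.accepted]
    assert accepted == ["glucose"]


def test_missing_rate_rows_are_dropped():
    panel = _two_driver_panel()
    panel.rates[:20, panel.index_of("glucose")] = np.nan
    fit = fit_sparse_predictor(panel, "glucose")
    assert fit.n_intervals == 140
    assert fit.accepted
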