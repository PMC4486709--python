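"""Recovery, null-calibration and oracle-agreement experiments.

These harnesses validate the inference machinery against synthetic ground
truth: signed-edge precision/recall/F1 on sparse regression truths, the
fraction of pure-noise metabolites falsely accepted as controlled, the
agreement of the lasso-path selection with the exhaustive best-subset
oracle, and end-to-end controlled-set recovery through the full
simulate -> preprocess -> infer pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_inference import (
    InferenceConfig,
    best_subset_oracle,
    fit_sparse_predictor,
    identify_controlled_nodes,
)
from .preprocessing import PreprocessConfig, preprocess
from .synthetic_cohort import (
    SimConfig,
    make_rate_panel,
    make_regression_truth,
    make_truth,
    simulate_cohort,
)


def child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible independent seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def precision_recall_f1(true_set: frozenset, pred_set: frozenset) -> tuple:
    tp = len(true_set & pred_set)
    precision = tp / len(pred_set) if pred_set else (1.0 if not true_set else 0.0)
    recall = tp / len(true_set) if true_set else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def fits_edge_set(fits, panel) -> frozenset:
    """Signed (controlled, controlling, sign) triples from accepted fits."""
    out = set()
    for fit in fits:
        if not fit.accepted:
            continue
        for name in fit.support:
            w = fit.coefficient_of(name, panel)
            out.add((fit.target, name, "+" if w > 0 else "-"))
    return frozenset(out)


@dataclass(frozen=True)
class RecoveryResult:
    edge_precision: float
    edge_recall: float
    edge_f1: float
    node_sensitivity: float
    node_fdr: float


def panel_recovery_trial(
    seed: int,
    m: int = 48,
    n_controlled: int = 6,
    max_drivers: int = 3,
    n_animals: int = 32,
    intervals_per_animal: int = 5,
    noise_sd: float = 0.2,
    cfg: InferenceConfig | None = None,
) -> RecoveryResult:
    """One signed-edge recovery experiment on a sparse regression truth."""
    truth_seed, panel_seed = child_seeds(seed, 2)
    truth = make_regression_truth(
        m=m, n_controlled=n_controlled, max_drivers=max_drivers, seed=truth_seed
    )
    panel = make_rate_panel(
        truth,
        n_animals=n_animals,
        intervals_per_animal=intervals_per_animal,
        noise_sd=noise_sd,
        seed=panel_seed,
    )
    fits = identify_controlled_nodes(panel, cfg or InferenceConfig())
    pred_edges = fits_edge_set(fits, panel)
    edge_p, edge_r, edge_f1 = precision_recall_f1(truth.edge_set(), pred_edges)

    accepted = frozenset(f.target for f in fits if f.accepted)
    true_nodes = truth.controlled_names
    tp = len(accepted & true_nodes)
    sensitivity = tp / len(true_nodes) if true_nodes else 1.0
    fdr = (len(accepted) - tp) / len(accepted) if accepted else 0.0
    return RecoveryResult(edge_p, edge_r, edge_f1, sensitivity, fdr)


def null_acceptance_trial(
    seed: int,
    m: int = 48,
    n_animals: int = 32,
    intervals_per_animal: int = 5,
    cfg: InferenceConfig | None = None,
) -> float:
    """Fraction of pure-noise metabolites accepted as controlled (one cohort)."""
    truth = make_regression_truth(m=m, n_controlled=0, seed=seed)
    panel = make_rate_panel(
        truth,
        n_animals=n_animals,
        intervals_per_animal=intervals_per_animal,
        noise_sd=1.0,
        seed=seed,
    )
    fits = identify_controlled_nodes(panel, cfg or InferenceConfig())
    return sum(f.accepted for f in fits) / len(fits)


def oracle_agreement_trial(
    seed: int,
    m: int = 10,
    max_drivers: int = 3,
    n_intervals: int = 160,
    cfg: InferenceConfig | None = None,
) -> bool:
    """Does path selection match exhaustive best-subset on a noiseless target?"""
    truth_seed, panel_seed = child_seeds(seed, 2)
    truth = make_regression_truth(
        m=m, n_controlled=1, max_drivers=max_drivers, seed=truth_seed
    )
    panel = make_rate_panel(
        truth,
        n_animals=n_intervals,
        intervals_per_animal=1,
        noise_sd=0.0,
        seed=panel_seed,
    )
    target = next(iter(truth.controlled_names))
    fit = fit_sparse_predictor(panel, target, cfg or InferenceConfig())
    oracle = best_subset_oracle(panel, target, max_support=max_drivers)
    return frozenset(fit.support) == oracle.support and fit.accepted == oracle.accepted


def endtoend_recovery_trial(
    seed: int,
    m: int = 48,
    n_controlled: int = 6,
    max_density: int = 3,
    sim_cfg: SimConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
    inf_cfg: InferenceConfig | None = None,
) -> RecoveryResult:
    """Controlled-set recovery through the full simulate -> infer pipeline."""
    truth_seed, sim_seed = child_seeds(seed, 2)
    truth = make_truth(m=m, n_controlled=n_controlled, max_density=max_density, seed=truth_seed)
    cfg = sim_cfg or SimConfig(seed=sim_seed)
    cohort, _ = simulate_cohort(truth, cfg)
    _, panel = preprocess(cohort, pre_cfg or PreprocessConfig())
    fits = identify_controlled_nodes(panel, inf_cfg or InferenceConfig())
    accepted = frozenset(f.target for f in fits if f.accepted)
    true_nodes = truth.controlled_names
    tp = len(accepted & true_nodes)
    sensitivity = tp / len(true_nodes) if true_nodes else 1.0
    fdr = (len(accepted) - tp) / len(accepted) if accepted else 0.0
    pred_edges = fits_edge_set(fits, panel)
    edge_p, edge_r, edge_f1 = precision_recall_f1(truth.edge_set(), pred_edges)
    return RecoveryResult(edge_p, edge_r, edge_f1, sensitivity, fdr)
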