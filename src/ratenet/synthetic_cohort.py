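"""Synthetic cohorts with known sparse signed dynamics.

The study design this emulates: two arms of 32 pigs, 48 serum metabolites
quantified at a pre-hemorrhage baseline and six post-hemorrhage timepoints
(0.75, 3, 5, 9, 17, 21 h), with high inter-animal variation and mortality
dropout.  The generative model matches what the inference assumes: the
rate of change of each *controlled* metabolite is a sparse signed linear
function of the (baseline-deviation) concentrations, all other metabolites
are flat apart from noise, and the hemorrhage appears as a randomized
deviation from baseline at 45 min.

Two ground-truth flavours exist.  :func:`make_truth` builds a dynamically
stable adjacency (each controlled row gets a dominating negative
self-coefficient, so all eigenvalues have non-positive real part) for the
ODE simulator.  :func:`make_regression_truth` builds an off-diagonal-only
coefficient matrix used by :func:`make_rate_panel`, which emits the
regression problem directly (unit-SD regressors, additive rate noise) for
controlled recovery experiments on the selection rule itself.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (
    POST_BASELINE_TIMEPOINTS,
    TIMEPOINT_HOURS,
    CohortTimeSeries,
)
from .preprocessing import RatePanel

logger = logging.getLogger(__name__)

DEFAULT_SCHEDULE = (0.0, 0.75, 3.0, 5.0, 9.0, 17.0, 21.0)

_HOURS_TO_LABEL = {v: k for k, v in TIMEPOINT_HOURS.items()}

#: Post-hemorrhage schedule-consecutive interval endpoints (hours).
POST_INTERVALS = tuple(
    (TIMEPOINT_HOURS[a], TIMEPOINT_HOURS[b])
    for a, b in zip(POST_BASELINE_TIMEPOINTS[:-1], POST_BASELINE_TIMEPOINTS[1:])
)


def default_metabolite_names(m: int) -> tuple:
    return tuple(f"met{i + 1:02d}" for i in range(m))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth signed adjacency plus generation parameters.

    ``adjacency[j, k]`` is the effect (per hour) of metabolite k on the
    rate of metabolite j; rows outside ``controlled_idx`` are all zero.
    ``stable`` records whether the matrix was built for ODE integration
    (all eigenvalue real parts <= 0).
    """

    metabolite_names: tuple
    adjacency: np.ndarray
    controlled_idx: frozenset
    correlated_blocks: tuple = ()  # (leader idx, follower idx tuple, gain tuple)
    seed: int = 0
    stable: bool = True

    @property
    def controlled_names(self) -> frozenset:
        return frozenset(self.metabolite_names[i] for i in self.controlled_idx)

    def edge_set(self, include_self: bool = True) -> frozenset:
        """Signed (controlled, controlling, sign) triples of non-zero entries."""
        out = set()
        for j in sorted(self.controlled_idx):
            row = self.adjacency[j]
            for k in np.where(row != 0)[0]:
                if not include_self and k == j:
                    continue
                out.add(
                    (
                        self.metabolite_names[j],
                        self.metabolite_names[int(k)],
                        "+" if row[k] > 0 else "-",
                    )
                )
        return frozenset(out)

    def to_json(self, path) -> None:
        payload = {
            "metabolite_names": list(self.metabolite_names),
            "adjacency": self.adjacency.tolist(),
            "controlled_idx": sorted(self.controlled_idx),
            "correlated_blocks": [
                [leader, list(followers), list(gains)]
                for leader, followers, gains in self.correlated_blocks
            ],
            "seed": self.seed,
            "stable": self.stable,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            metabolite_names=tuple(payload["metabolite_names"]),
            adjacency=np.asarray(payload["adjacency"], dtype=float),
            controlled_idx=frozenset(payload["controlled_idx"]),
            correlated_blocks=tuple(
                (leader, tuple(followers), tuple(gains))
                for leader, followers, gains in payload["correlated_blocks"]
            ),
            seed=payload["seed"],
            stable=payload["stable"],
        )


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation settings (units: hours, mM).

    ``rate_scale`` uniformly rescales the adjacency inside the integrator,
    setting metabolic relaxation times; the default 0.12/h puts them at
    roughly 4-10 h, comparable to the sampling gaps.  ``shock_frac`` is the
    SD of the randomized post-hemorrhage deviation as a fraction of each
    metabolite's baseline.  The default mortality hazard of 0.0156/h gives
    about 28 % cumulative mortality over the 21-h window.
    """

    n_animals: int = 32
    group: str = "FS"
    schedule: tuple = DEFAULT_SCHEDULE
    baseline_mean: float = 1.0  # mM; lognormal median
    baseline_sigma: float = 0.5
    shock_frac: float = 0.5
    process_noise_sd: float = 0.02  # mM per sqrt(hour)
    measurement_noise_sd: float = 0.02  # mM
    mortality_hazard: float = 0.0156  # per hour
    euler_step: float = 0.05  # hours
    rate_scale: float = 0.12
    seed: int = 0

    def __post_init__(self):
        gaps = np.diff(self.schedule)
        if np.any(gaps <= 0):
            raise ValueError("schedule must be strictly increasing")
        if self.euler_step > gaps.min() / 10:
            raise ValueError("euler_step must be at most one tenth of the smallest gap")


def make_truth(
    m: int = 48,
    n_controlled: int = 6,
    max_density: int = 3,
    seed: int = 0,
    coef_range: tuple = (0.5, 1.0),
    names: tuple | None = None,
    max_retries: int = 20,
) -> SyntheticTruth:
    """Random sparse signed *stable* adjacency for the ODE simulator.

    Each controlled row holds 1..max_density non-zeros: a negative
    self-coefficient dominating the row (Gershgorin then bounds every
    eigenvalue's real part by zero) plus up to max_density-1 signed
    drivers with magnitudes drawn from ``coef_range``.
    """
    if n_controlled > m:
        raise ValueError("n_controlled cannot exceed m")
    if not 1 <= max_density <= 5:
        raise ValueError("max_density must lie in 1..5")
    names = tuple(names) if names is not None else default_metabolite_names(m)
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        A = np.zeros((m, m))
        controlled = rng.choice(m, size=n_controlled, replace=False)
        for j in controlled:
            density = int(rng.integers(1, max_density + 1))
            others = [k for k in range(m) if k != j]
            drivers = rng.choice(others, size=density - 1, replace=False)
            mags = rng.uniform(*coef_range, size=density - 1)
            signs = rng.choice([-1.0, 1.0], size=density - 1)
            A[j, drivers] = signs * mags
            # stability margin drawn from coef_range so the self-coefficient
            # honors the same magnitude floor as the drivers
            A[j, j] = -(np.abs(A[j, drivers]).sum() + rng.uniform(*coef_range))
        if np.max(np.linalg.eigvals(A).real) <= 1e-9:
            return SyntheticTruth(
                metabolite_names=names,
                adjacency=A,
                controlled_idx=frozenset(int(j) for j in controlled),
                seed=seed,
                stable=True,
            )
    raise RuntimeError("could not construct a stable adjacency")


def make_regression_truth(
    m: int = 48,
    n_controlled: int = 6,
    max_drivers: int = 3,
    seed: int = 0,
    coef_range: tuple = (0.5, 1.0),
    names: tuple | None = None,
) -> SyntheticTruth:
    """Off-diagonal sparse signed coefficient matrix for rate-panel studies.

    Each controlled row receives 1..max_drivers signed drivers (never
    itself) with magnitudes from ``coef_range``; no stabilizing diagonal is
    added because this truth parameterizes a regression, not an ODE.
    """
    if n_controlled > m:
        raise ValueError("n_controlled cannot exceed m")
    names = tuple(names) if names is not None else default_metabolite_names(m)
    rng = np.random.default_rng(seed)
    A = np.zeros((m, m))
    controlled = rng.choice(m, size=n_controlled, replace=False) if n_controlled else []
    for j in controlled:
        density = int(rng.integers(1, max_drivers + 1))
        others = [k for k in range(m) if k != j]
        drivers = rng.choice(others, size=density, replace=False)
        A[j, drivers] = rng.choice([-1.0, 1.0], size=density) * rng.uniform(
            *coef_range, size=density
        )
    return SyntheticTruth(
        metabolite_names=names,
        adjacency=A,
        controlled_idx=frozenset(int(j) for j in controlled),
        seed=seed,
        stable=False,
    )


def truth_from_edges(
    edges, metabolite_names: tuple, magnitude: float = 0.8
) -> SyntheticTruth:
    """Regression truth transcribing a printed signed edge list.

    ``edges`` holds (controlled, controlling, sign) triples; every
    coefficient gets the same magnitude with the printed sign.
    """
    names = tuple(metabolite_names)
    index = {n: i for i, n in enumerate(names)}
    m = len(names)
    A = np.zeros((m, m))
    controlled = set()
    for controlled_name, controlling_name, sign in edges:
        j, k = index[controlled_name], index[controlling_name]
        A[j, k] = magnitude if sign == "+" else -magnitude
        controlled.add(j)
    return SyntheticTruth(
        metabolite_names=names,
        adjacency=A,
        controlled_idx=frozenset(controlled),
        seed=0,
        stable=False,
    )


def simulate_cohort(
    truth: SyntheticTruth, cfg: SimConfig | None = None
) -> tuple[CohortTimeSeries, pd.DataFrame]:
    """Integrate the cohort and sample it on the schedule.

    Per animal: draw a lognormal baseline vector; at 45 min apply a
    randomized deviation (the hemorrhage); integrate
    d(dev)/dt = rate_scale * A @ dev + process noise by explicit
    Euler-Maruyama; sample the latent state at the schedule, add
    measurement noise, clip negatives at zero (counted), and truncate
    animals that die under the exponential mortality hazard.

    Returns the cohort plus the latent (measurement-noise-free)
    first-difference rates per surviving interval, for oracle checks.
    """
    cfg = cfg or SimConfig()
    if truth.stable and np.max(np.linalg.eigvals(truth.adjacency).real) > 1e-6:
        raise ValueError("truth adjacency is not stable")
    rng = np.random.default_rng(cfg.seed)
    names = truth.metabolite_names
    m = len(names)
    A = cfg.rate_scale * truth.adjacency
    schedule = list(cfg.schedule)
    labels = [_HOURS_TO_LABEL[t] for t in schedule]

    sample_rows, conc_rows, latent_records = [], [], []
    n_clipped = 0
    for i in range(cfg.n_animals):
        animal = f"{cfg.group}{i + 1:02d}"
        baseline = rng.lognormal(math.log(cfg.baseline_mean), cfg.baseline_sigma, m)
        death_time = (
            rng.exponential(1.0 / cfg.mortality_hazard)
            if cfg.mortality_hazard > 0
            else math.inf
        )
        survived = death_time > schedule[-1]

        # latent deviations from baseline at each scheduled time
        latent = {schedule[0]: np.zeros(m)}
        dev = baseline * cfg.shock_frac * rng.standard_normal(m)
        latent[schedule[1]] = dev.copy()
        for t0, t1 in zip(schedule[1:-1], schedule[2:]):
            n_steps = max(1, round((t1 - t0) / cfg.euler_step))
            dt = (t1 - t0) / n_steps
            for _ in range(n_steps):
                dev = (
                    dev
                    + dt * (A @ dev)
                    + math.sqrt(dt) * cfg.process_noise_sd * rng.standard_normal(m)
                )
            latent[t1] = dev.copy()

        observed_times = [t for t in schedule if t <= death_time]
        if not observed_times:
            observed_times = [schedule[0]]
        for t in observed_times:
            label = _HOURS_TO_LABEL[t]
            measured = (
                baseline
                + latent[t]
                + cfg.measurement_noise_sd * rng.standard_normal(m)
            )
            n_clipped += int((measured < 0).sum())
            measured = np.clip(measured, 0.0, None)
            sample_rows.append(
                {
                    "sample_id": f"{animal}_{label}",
                    "animal_id": animal,
                    "group": cfg.group,
                    "timepoint": label,
                    "hours": t,
                    "survived": survived,
                }
            )
            conc_rows.append(measured)

        post_observed = [t for t in observed_times if t > 0]
        for t0, t1 in zip(post_observed[:-1], post_observed[1:]):
            rate = (baseline + latent[t1] - (baseline + latent[t0])) / (t1 - t0)
            latent_records.append(
                {"animal_id": animal, "t_start": t0, "t_end": t1}
                | dict(zip(names, rate))
            )

    if n_clipped:
        logger.info("clipped %d negative simulated concentrations at 0", n_clipped)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    conc = pd.DataFrame(conc_rows, index=samples.index, columns=list(names))
    cohort = CohortTimeSeries(samples=samples, concentrations=conc)
    cohort.validate()
    latent_rates = pd.DataFrame(
        latent_records, columns=["animal_id", "t_start", "t_end", *names]
    )
    return cohort, latent_rates


def inject_correlated_block(
    cohort: CohortTimeSeries,
    truth: SyntheticTruth,
    noise_frac: float = 0.05,
    seed: int | None = None,
) -> CohortTimeSeries:
    """Overwrite follower columns as gain x leader plus small noise.

    The noise SD is ``noise_frac`` of the leader column's SD, keeping the
    pooled squared correlation with the leader above 0.9; columns are then
    shifted up if needed so concentrations stay non-negative.
    """
    if not truth.correlated_blocks:
        return cohort
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    conc = cohort.concentrations.copy()
    for leader, followers, gains in truth.correlated_blocks:
        leader_col = conc.iloc[:, leader].to_numpy()
        sd = float(np.std(leader_col))
        for follower, gain in zip(followers, gains):
            col = gain * leader_col + noise_frac * sd * abs(gain) * rng.standard_normal(
                len(leader_col)
            )
            if col.min() < 0:
                col = col - col.min()
            conc.iloc[:, follower] = col
    out = CohortTimeSeries(samples=cohort.samples.copy(), concentrations=conc)
    out.validate()
    return out


def make_rate_panel(
    truth: SyntheticTruth,
    n_animals: int = 32,
    intervals_per_animal: int = 5,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> RatePanel:
    """Emit the regression problem directly: unit-SD regressors, noisy rates.

    Regressor rows are i.i.d. standard normal (the pooled, normalized
    concentration deviations the pipeline would produce); rates are
    ``regressors @ A.T`` plus Gaussian noise of SD ``noise_sd``.  Interval
    labels cycle through the post-hemorrhage schedule so the panel is
    shaped exactly like a preprocessed cohort of ``n_animals`` animals.
    """
    rng = np.random.default_rng(seed)
    names = truth.metabolite_names
    n = n_animals * intervals_per_animal
    X = rng.standard_normal((n, len(names)))
    rates = X @ truth.adjacency.T + noise_sd * rng.standard_normal((n, len(names)))
    records = []
    for i in range(n_animals):
        animal = f"SIM{i + 1:02d}"
        for k in range(intervals_per_animal):
            t0, t1 = POST_INTERVALS[k % len(POST_INTERVALS)]
            records.append((animal, t0, t1))
    intervals = pd.DataFrame(records, columns=["animal_id", "t_start", "t_end"])
    return RatePanel(
        metabolite_names=names,
        intervals=intervals,
        rates=rates,
        regressors=X,
        eligible=frozenset(names),
    )
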