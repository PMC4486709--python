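"""Baseline shifting, pooled-SD normalization and first-difference rates.

Each animal's post-hemorrhage trajectory is expressed as a deviation from
its own pre-hemorrhage baseline, every metabolite is scaled to unit pooled
standard deviation within the experimental group, and rates of change are
estimated by first differences over the consecutive post-hemorrhage
sampling intervals (0.75-3, 3-5, 5-9, 9-17, 17-21 h).  The baseline-to-45-min
interval is excluded: the hemorrhage itself lies inside it, so that
difference reflects the intervention rather than network dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import POST_BASELINE_TIMEPOINTS, TIMEPOINT_HOURS, CohortTimeSeries

logger = logging.getLogger(__name__)

#: Pooled SDs below this are treated as degenerate (column left unscaled).
DEGENERATE_SD_TOL = 1e-12


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing knobs.

    normalize_mode
        ``"pooled_sd"`` divides each shifted metabolite column by its SD
        pooled over all animals and post-baseline timepoints; ``"none"``
        skips scaling.
    regressor_alignment
        ``"left_endpoint"`` pairs each interval's rate with the
        concentrations at the interval start (explicit-Euler reading of
        dx/dt = f(x)); ``"midpoint"`` averages the two endpoints.
    min_intervals_per_metabolite
        Metabolites with fewer usable intervals are flagged ineligible as
        controlled-node candidates.
    """

    normalize_mode: str = "pooled_sd"
    regressor_alignment: str = "left_endpoint"
    min_intervals_per_metabolite: int = 10

    def __post_init__(self):
        if self.normalize_mode not in ("pooled_sd", "none"):
            raise ValueError(f"unknown normalize_mode {self.normalize_mode!r}")
        if self.regressor_alignment not in ("left_endpoint", "midpoint"):
            raise ValueError(f"unknown regressor_alignment {self.regressor_alignment!r}")
        if self.min_intervals_per_metabolite < 1:
            raise ValueError("min_intervals_per_metabolite must be positive")


@dataclass
class RatePanel:
    """Pooled per-interval rate estimates with aligned regressor rows.

    ``rates[i, j]`` is the first-difference rate of metabolite j over
    interval i (normalized units per hour); ``regressors[i, :]`` holds the
    normalized concentrations the predictor may use for that interval.
    NaN marks intervals unusable for a given metabolite.
    """

    metabolite_names: tuple
    intervals: pd.DataFrame  # columns: animal_id, t_start, t_end
    rates: np.ndarray
    regressors: np.ndarray
    eligible: frozenset = field(default_factory=frozenset)

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def index_of(self, name: str) -> int:
        key = name.strip().casefold()
        for j, canonical in enumerate(self.metabolite_names):
            if canonical.strip().casefold() == key:
                return j
        raise KeyError(f"unknown metabolite {name!r}")

    def n_usable(self, name: str) -> int:
        return int(np.isfinite(self.rates[:, self.index_of(name)]).sum())


def baseline_shift(cohort: CohortTimeSeries) -> CohortTimeSeries:
    """Subtract each animal's baseline (BS) concentration per metabolite.

    BS rows are retained with value 0; shifted values may be negative.
    Animals with no BS sample are excluded with a logged warning.
    """
    samples, conc = cohort.samples, cohort.concentrations
    keep_rows = []
    shifted = conc.copy()
    for animal, sub in samples.groupby("animal_id", sort=False):
        bs = sub.index[sub["timepoint"] == "BS"]
        if len(bs) == 0:
            logger.warning("animal %s has no baseline (BS) sample; excluded", animal)
            continue
        baseline = conc.loc[bs[0]]
        shifted.loc[sub.index] = conc.loc[sub.index].sub(baseline, axis=1)
        keep_rows.extend(sub.index)
    keep_rows = [i for i in samples.index if i in set(keep_rows)]
    return replace(
        cohort,
        samples=samples.loc[keep_rows].copy(),
        concentrations=shifted.loc[keep_rows],
        is_shifted=True,
    )


def normalize(cohort: CohortTimeSeries, cfg: PreprocessConfig | None = None) -> CohortTimeSeries:
    """Scale each metabolite to unit pooled SD of its shifted values.

    The SD pools all animals and all post-baseline timepoints of the cohort
    (call after :func:`subset_group` when two groups are present, so each
    group is scaled on its own).  Columns with pooled SD below
    ``DEGENERATE_SD_TOL`` are flagged degenerate and left unscaled.
    """
    cfg = cfg or PreprocessConfig()
    if not cohort.is_shifted:
        raise ValueError("normalize expects a baseline-shifted cohort")
    if cfg.normalize_mode == "none":
        return replace(cohort, is_normalized=True)

    post = cohort.concentrations.loc[cohort.post_baseline_mask()]
    sds = post.std(ddof=1, skipna=True)
    degenerate = frozenset(sds.index[(sds < DEGENERATE_SD_TOL) | sds.isna()])
    scale = sds.where(~sds.index.isin(degenerate), 1.0)
    return replace(
        cohort,
        concentrations=cohort.concentrations.div(scale, axis=1),
        is_normalized=True,
        degenerate=degenerate,
    )


def estimate_rates(cohort: CohortTimeSeries, cfg: PreprocessConfig | None = None) -> RatePanel:
    """Pool per-animal first-difference rates over the sampling schedule.

    For each animal and each schedule-consecutive post-baseline pair
    (t_k, t_{k+1}) with both samples present, the rate is
    (x(t_{k+1}) - x(t_k)) / (t_{k+1} - t_k); the regressor row holds the
    concentrations at t_k (or the endpoint average under midpoint
    alignment).  Intervals are pooled across all animals of the cohort.
    """
    cfg = cfg or PreprocessConfig()
    if not (cohort.is_shifted and cohort.is_normalized):
        raise ValueError("estimate_rates expects a shifted and normalized cohort")

    samples, conc = cohort.samples, cohort.concentrations
    names = tuple(conc.columns)
    schedule = [(tp, TIMEPOINT_HOURS[tp]) for tp in POST_BASELINE_TIMEPOINTS]

    records, rate_rows, reg_rows = [], [], []
    for animal in sorted(samples["animal_id"].unique()):
        sub = samples[samples["animal_id"] == animal]
        by_tp = {row["timepoint"]: idx for idx, row in sub.iterrows()}
        for (tp0, t0), (tp1, t1) in zip(schedule[:-1], schedule[1:]):
            if tp0 not in by_tp or tp1 not in by_tp:
                continue
            x0 = conc.loc[by_tp[tp0]].to_numpy(dtype=float)
            x1 = conc.loc[by_tp[tp1]].to_numpy(dtype=float)
            records.append((animal, t0, t1))
            rate_rows.append((x1 - x0) / (t1 - t0))
            if cfg.regressor_alignment == "left_endpoint":
                reg_rows.append(x0)
            else:
                reg_rows.append(0.5 * (x0 + x1))

    intervals = pd.DataFrame(records, columns=["animal_id", "t_start", "t_end"])
    rates = np.asarray(rate_rows, dtype=float).reshape(len(records), len(names))
    regressors = np.asarray(reg_rows, dtype=float).reshape(len(records), len(names))

    usable = np.isfinite(rates).sum(axis=0)
    eligible = frozenset(
        name
        for j, name in enumerate(names)
        if usable[j] >= cfg.min_intervals_per_metabolite and name not in cohort.degenerate
    )
    return RatePanel(
        metabolite_names=names,
        intervals=intervals,
        rates=rates,
        regressors=regressors,
        eligible=eligible,
    )


def preprocess(
    cohort: CohortTimeSeries, cfg: PreprocessConfig | None = None
) -> tuple[CohortTimeSeries, RatePanel]:
    """Convenience: shift, normalize and build the rate panel in one call."""
    cfg = cfg or PreprocessConfig()
    shifted = normalize(baseline_shift(cohort), cfg)
    return shifted, estimate_rates(shifted, cfg)
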