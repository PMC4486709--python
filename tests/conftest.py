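"""Shared fixtures: tiny hand-built cohorts and rate panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ratenet import CohortTimeSeries, RatePanel
from ratenet.io_formats import TIMEPOINT_HOURS


def build_cohort(
    trajectories: dict,
    group: str = "FS",
    survived: dict | None = None,
    is_shifted: bool = False,
    is_normalized: bool = False,
) -> CohortTimeSeries:
    """Cohort from {animal -> DataFrame(index=timepoint labels, columns=metabolites)}."""
    sample_rows, conc_rows = [], []
    metabolites = None
    for animal, frame in trajectories.items():
        metabolites = list(frame.columns) if metabolites is None else metabolites
        for tp, row in frame.iterrows():
            sample_rows.append(
                {
                    "sample_id": f"{animal}_{tp}",
                    "animal_id": animal,
                    "group": group,
                    "timepoint": tp,
                    "hours": TIMEPOINT_HOURS[tp],
                    "survived": True if survived is None else survived[animal],
                }
            )
            conc_rows.append(row.to_numpy(dtype=float))
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    conc = pd.DataFrame(conc_rows, index=samples.index, columns=metabolites)
    cohort = CohortTimeSeries(
        samples=samples,
        concentrations=conc,
        is_shifted=is_shifted,
        is_normalized=is_normalized,
    )
    cohort.validate()
    return cohort


def schedule_frame(metabolites: dict, timepoints=None) -> pd.DataFrame:
    """DataFrame of trajectories from {metabolite -> f(hours)} callables."""
    timepoints = timepoints or list(TIMEPOINT_HOURS)
    return pd.DataFrame(
        {
            name: [fn(TIMEPOINT_HOURS[tp]) for tp in timepoints]
            for name, fn in metabolites.items()
        },
        index=timepoints,
    )


def panel_from_arrays(X: np.ndarray, rates: np.ndarray, names) -> RatePanel:
    """RatePanel wrapper around explicit regressor/rate matrices."""
    n = X.shape[0]
    intervals = pd.DataFrame(
        {
            "animal_id": [f"a{i // 5:02d}" for i in range(n)],
            "t_start": 0.75,
            "t_end": 3.0,
        }
    )
    return RatePanel(
        metabolite_names=tuple(names),
        intervals=intervals,
        rates=rates,
        regressors=X,
        eligible=frozenset(names),
    )


@pytest.fixture
def two_animal_cohort() -> CohortTimeSeries:
    """2 animals x 7 timepoints x 3 metabolites, simple smooth values."""
    frames = {}
    for k, animal in enumerate(("p01", "p02")):
        frames[animal] = schedule_frame(
            {
                "Lactate": lambda t, k=k: 2.0 + 0.1 * t + 0.2 * k,
                "Glucose": lambda t, k=k: 5.0 - 0.05 * t + 0.1 * k,
                "Alanine": lambda t, k=k: 1.0 + 0.02 * t * t + 0.05 * k,
            }
        )
    return build_cohort(frames)
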