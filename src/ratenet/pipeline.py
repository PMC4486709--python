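"""End-to-end orchestration: load -> preprocess -> infer -> assemble -> report.

One :class:`PipelineConfig` document (YAML or JSON) drives the whole run;
every artifact (edge TSV, GraphML, report tables, cohort summary, run log
with config echo and input hashes) lands in the output directory.  Runs
are deterministic: the same config and inputs produce byte-identical edge
lists and reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .io_formats import GROUPS, CohortTimeSeries, read_cohort, write_network
from .network_assembly import RegulatoryNetwork, assemble, render_tables, surrogate_map
from .network_inference import InferenceConfig, identify_controlled_nodes
from .preprocessing import PreprocessConfig, estimate_rates, preprocess

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-labeled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline settings; round-trips losslessly through YAML/JSON."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    r2_threshold: float = 0.8
    group: str = "both"
    seed: int = 0
    output_dir: str = "ratenet_out"

    def to_dict(self) -> dict:
        return {
            "preprocess": asdict(self.preprocess),
            "inference": asdict(self.inference),
            "r2_threshold": self.r2_threshold,
            "group": self.group,
            "seed": self.seed,
            "output_dir": str(self.output_dir),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        return cls(
            preprocess=PreprocessConfig(**payload.get("preprocess", {})),
            inference=InferenceConfig(**payload.get("inference", {})),
            r2_threshold=payload.get("r2_threshold", 0.8),
            group=payload.get("group", "both"),
            seed=payload.get("seed", 0),
            output_dir=payload.get("output_dir", "ratenet_out"),
        )

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _display_pct(x: float) -> int:
    """Round half-up to an integer percent for display."""
    return int(math.floor(x + 0.5))


def summarize_cohort(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-group cohort summary: animals, samples, deaths, mortality percent.

    Mortality percent is 100 x deaths / animals; ``mortality_pct`` keeps
    full precision while ``mortality_display`` carries the half-up rounded
    integer used in text.
    """
    rows = []
    for group, sub in samples.groupby("group", sort=True):
        animals = sub.groupby("animal_id")["survived"].agg(lambda s: bool(s.iloc[0]))
        n_animals = len(animals)
        if n_animals == 0:  # pragma: no cover - groupby never yields empty groups
            logger.warning("group %s has no animals; omitted from summary", group)
            continue
        deaths = int((~animals).sum())
        pct = 100.0 * deaths / n_animals
        rows.append(
            {
                "group": group,
                "n_animals": n_animals,
                "n_samples": len(sub),
                "n_deaths": deaths,
                "mortality_pct": pct,
                "mortality_display": _display_pct(pct),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(
    cfg: PipelineConfig, concentration_path, metadata_path, sep: str = ","
) -> dict:
    """Run the full inference for every requested group.

    Returns {group: RegulatoryNetwork} and writes, per group, the edge TSV,
    the GraphML graph and the rendered report tables, plus a cohort summary
    and a JSON run log (config echo, SHA-256 of both inputs, and one
    accept/reject decision line per candidate metabolite).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("read"):
        cohort = read_cohort(concentration_path, metadata_path, sep=sep)
        if cohort.n_samples == 0:
            raise ValueError("cohort is empty after the join")

    with _stage("summarize"):
        summary = summarize_cohort(cohort.samples)
        summary.to_csv(out / "cohort_summary.tsv", sep="\t")

    groups = list(GROUPS) if cfg.group == "both" else [cfg.group]
    groups = [g for g in groups if g in set(cohort.samples["group"])]
    if not groups:
        raise PipelineError("groups", f"no samples for requested group {cfg.group!r}")

    log = {
        "config": cfg.to_dict(),
        "inputs": {
            str(concentration_path): _sha256(concentration_path),
            str(metadata_path): _sha256(metadata_path),
        },
        "groups": {},
    }
    networks: dict[str, RegulatoryNetwork] = {}
    for group in groups:
        with _stage(f"preprocess:{group}"):
            shifted, panel = preprocess(cohort.subset_group(group), cfg.preprocess)
        with _stage(f"infer:{group}"):
            fits = identify_controlled_nodes(panel, cfg.inference)
        with _stage(f"assemble:{group}"):
            controlling = {
                name for fit in fits if fit.accepted for name in fit.support
            }
            surrogates = surrogate_map(shifted, controlling, cfg.r2_threshold)
            net = assemble(fits, panel, surrogates, group=group)
        with _stage(f"write:{group}"):
            write_network(net, out / f"edges_{group}.tsv", out / f"network_{group}.graphml")
            (out / f"report_{group}.tsv").write_text(render_tables(net))
        networks[group] = net
        log["groups"][group] = {
            "n_candidates": len(fits),
            "n_controlled": sum(f.accepted for f in fits),
            "decisions": [
                {
                    "target": f.target,
                    "accepted": f.accepted,
                    "error_ratio": None if not math.isfinite(f.error_ratio) else round(f.error_ratio, 6),
                    "support": list(f.support),
                    "reason": f.reason,
                }
                for f in fits
            ],
        }

    with _stage("log"):
        (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return networks
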