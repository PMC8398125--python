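"""End-to-end experiments: ablation grids and parameter sweeps.

`run_experiment` drives the full pipeline (parse/clean/segment/attach
context -> class selection -> repeated balanced stratified CV) for every
point of an architecture grid and returns one result row per point.  Grid
points share the same balanced sample draws (they receive the same
evaluation seed), so ablation differences are paired rather than confounded
by sampling.  Failures are isolated per grid point.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import pandas as pd

from .casas_io import parse_event_log, segment_activities
from .evaluation import cross_validate
from .features import build_vocabulary
from .model import ModelSpec
from .preprocessing import CLASS_ORDER, Dataset, attach_context, clean_events, select_classes
from .synthetic_data import SimConfig, simulate_log

__all__ = ["ExperimentConfig", "GridPoint", "reference_grid", "run_experiment", "sweep"]

_MACRO_COLS = ["precision", "recall", "specificity", "f1", "accuracy", "error"]


@dataclass(frozen=True)
class GridPoint:
    """One architecture variant of the ablation grid."""

    bidirectional: bool = True
    nodes: int = 60
    use_prev: bool = True
    use_ts: bool = True

    def apply(self, spec: ModelSpec) -> ModelSpec:
        return replace(
            spec,
            bidirectional=self.bidirectional,
            recurrent_nodes=self.nodes,
            use_prev=self.use_prev,
            use_ts=self.use_ts,
        )


def reference_grid() -> List[GridPoint]:
    """The standard 8-variant comparison: uni/bi LSTM, node counts, and the
    four external-feature combinations around the bidirectional-60 model."""
    return [
        GridPoint(bidirectional=False, nodes=60, use_prev=True, use_ts=True),
        GridPoint(bidirectional=False, nodes=60, use_prev=False, use_ts=False),
        GridPoint(bidirectional=True, nodes=60, use_prev=True, use_ts=True),
        GridPoint(bidirectional=True, nodes=50, use_prev=True, use_ts=True),
        GridPoint(bidirectional=True, nodes=20, use_prev=True, use_ts=True),
        GridPoint(bidirectional=True, nodes=60, use_prev=False, use_ts=True),
        GridPoint(bidirectional=True, nodes=60, use_prev=True, use_ts=False),
        GridPoint(bidirectional=True, nodes=60, use_prev=False, use_ts=False),
    ]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce an experiment.

    ``source`` is either a log path or a :class:`SimConfig`; preprocessing
    keeps ``classes`` and balances to ``n_per_class``; each grid point runs
    ``repeats`` x ``k``-fold CV with the shared ``seed``.
    """

    source: Union[str, SimConfig]
    grid: Sequence[GridPoint] = field(default_factory=lambda: [GridPoint()])
    classes: Sequence[str] = CLASS_ORDER
    n_per_class: Optional[int] = 60
    k: int = 10
    repeats: int = 5
    seed: int = 0
    base_spec: ModelSpec = field(default_factory=ModelSpec)

    def config_hash(self) -> str:
        payload = {
            "source": self.source if isinstance(self.source, str) else "simulated",
            "sim_seed": self.source.seed if isinstance(self.source, SimConfig) else None,
            "grid": [vars(g) for g in self.grid],
            "classes": list(self.classes),
            "n_per_class": self.n_per_class,
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _load_pool(config: ExperimentConfig):
    if isinstance(config.source, SimConfig):
        events = simulate_log(config.source)
    else:
        events = parse_event_log(config.source)
    events = clean_events(events)
    instances = attach_context(segment_activities(events))
    pool = select_classes(Dataset(instances, config.classes), config.classes)
    vocab = build_vocabulary(events)
    return pool, vocab


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run every grid point; one result row per point.

    Rows carry the grid-point settings, the macro metric suite, and
    provenance (seed, config hash).  A failing grid point yields a row with
    an ``error`` message instead of aborting the rest of the grid.
    """
    pool, vocab = _load_pool(config)
    rows = []
    for point in config.grid:
        row = {
            "bidirectional": point.bidirectional,
            "nodes": point.nodes,
            "use_prev": point.use_prev,
            "use_ts": point.use_ts,
            "k": config.k,
            "repeats": config.repeats,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        }
        try:
            spec = point.apply(config.base_spec)
            result = cross_validate(
                pool, spec, vocab,
                n_per_class=config.n_per_class,
                k=config.k, repeats=config.repeats, seed=config.seed,
            )
            for col in _MACRO_COLS:
                row[f"macro_{col}"] = result.report.macro[col]
        except Exception as exc:  # isolate the failing point
            warnings.warn(f"grid point {point} failed: {exc}", stacklevel=2)
            row["run_error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def sweep(
    config: ExperimentConfig,
    parameter: str,
    values: Sequence,
) -> pd.DataFrame:
    """Metric-versus-value series for one architecture parameter.

    ``parameter`` is ``"nodes"`` or ``"sequence_length"``; everything else
    stays fixed at the first grid point of ``config``.
    """
    if parameter not in ("nodes", "sequence_length"):
        raise ValueError(f"unsupported sweep parameter {parameter!r}")
    if not values:
        raise ValueError("values must be non-empty")
    pool, vocab = _load_pool(config)
    point = config.grid[0]
    rows = []
    for value in values:
        spec = point.apply(config.base_spec)
        if parameter == "nodes":
            spec = replace(spec, recurrent_nodes=int(value))
        else:
            spec = replace(spec, sequence_length=int(value))
        result = cross_validate(
            pool, spec, vocab,
            n_per_class=config.n_per_class,
            k=config.k, repeats=config.repeats, seed=config.seed,
        )
        row = {parameter: value, "seed": config.seed}
        for col in _MACRO_COLS:
            row[f"macro_{col}"] = result.report.macro[col]
        rows.append(row)
    return pd.DataFrame(rows)
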