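"""Synthetic smart-home event-log generator.

Emulates a single-resident testbed instrumented with binary motion (``M``)
and door (``D``) sensors: an activity chain drawn from a first-order
previous->current transition matrix, hour-of-day-dependent activity starts,
per-activity sensor emission distributions and variable event-sequence
lengths.  Output is a chronological annotated log in the exact CASAS dialect
of :mod:`adlseq.casas_io`, fully determined by one seed.

The default configuration reproduces the structural regularities real
single-resident data shows: Enter_Home is always preceded by Leave_Home,
Bed_to_Toilet always by Sleeping, Sleeping and Bed_to_Toilet start at night,
and Meal_Preparation / Wash_Dishes fire overlapping kitchen sensors (the
classic hardest confusion, since both happen in the same location).  Two
additional presets bracket the difficulty range: ``separable`` gives every
class a disjoint sensor set, ``transition_only`` gives all classes identical
emissions so that only the temporal context is informative.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .casas_io import SensorEvent, segment_activities
from .preprocessing import CLASS_ORDER

__all__ = [
    "SimConfig",
    "default_sim_config",
    "separable_sim_config",
    "transition_only_sim_config",
    "simulate_log",
    "summarize_log",
    "load_sim_config",
    "save_sim_config",
]

_DEFAULT_SENSORS = tuple(f"M{i:03d}" for i in range(1, 32)) + tuple(
    f"D{i:03d}" for i in range(1, 5)
)


def _hours(peaks: Dict[int, float], base: float = 0.02) -> np.ndarray:
    w = np.full(24, base)
    for h, v in peaks.items():
        w[h % 24] += v
    return w


@dataclass
class SimConfig:
    """Generative parameters of the simulator.

    ``transition`` is row-stochastic over previous->current activity;
    ``begin_hour_weights`` gives per-class propensities over hours 0-23
    (normalized at sampling time); ``emission`` is a per-class categorical
    over sensors; ``length_pair_mean`` parametrizes the per-class Poisson
    number of ON/OFF sensor activations (support clipped to 1-100 pairs, so
    2-200 events).  Gap times are exponential with the given means (seconds).
    """

    classes: Sequence[str] = CLASS_ORDER
    sensors: Sequence[str] = _DEFAULT_SENSORS
    transition: np.ndarray = None  # (9, 9) row-stochastic, prev -> current
    begin_hour_weights: Dict[str, np.ndarray] = None
    emission: Dict[str, np.ndarray] = None  # per-class categorical over sensors
    length_pair_mean: Dict[str, float] = None
    inter_event_gap_mean: float = 20.0
    inter_activity_gap_mean: float = 600.0
    n_days: int = 7
    start_date: dt.date = dt.date(2010, 11, 4)
    seed: int = 0

    def validate(self) -> None:
        n = len(self.classes)
        T = np.asarray(self.transition, dtype=float)
        if T.shape != (n, n):
            raise ValueError(f"transition must be {n}x{n}")
        if (T < 0).any() or not np.allclose(T.sum(axis=1), 1.0):
            raise ValueError("transition rows must be non-negative and sum to 1")
        for cls in self.classes:
            w = np.asarray(self.begin_hour_weights[cls], dtype=float)
            if w.shape != (24,) or (w < 0).any() or w.sum() <= 0:
                raise ValueError(f"bad begin-hour weights for {cls!r}")
            e = np.asarray(self.emission[cls], dtype=float)
            if e.shape != (len(self.sensors),) or (e < 0).any() or e.sum() <= 0:
                raise ValueError(f"bad emission distribution for {cls!r}")
            if self.length_pair_mean[cls] <= 0:
                raise ValueError(f"bad length mean for {cls!r}")

    def transition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.transition, index=self.classes, columns=self.classes)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "sensors": list(self.sensors),
            "transition": np.asarray(self.transition, dtype=float).tolist(),
            "begin_hour_weights": {
                c: np.asarray(w, dtype=float).tolist()
                for c, w in self.begin_hour_weights.items()
            },
            "emission": {
                c: np.asarray(e, dtype=float).tolist()
                for c, e in self.emission.items()
            },
            "length_pair_mean": dict(self.length_pair_mean),
            "inter_event_gap_mean": self.inter_event_gap_mean,
            "inter_activity_gap_mean": self.inter_activity_gap_mean,
            "n_days": self.n_days,
            "start_date": self.start_date.isoformat(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        cfg = cls(
            classes=tuple(d["classes"]),
            sensors=tuple(d["sensors"]),
            transition=np.asarray(d["transition"], dtype=float),
            begin_hour_weights={
                c: np.asarray(w, dtype=float) for c, w in d["begin_hour_weights"].items()
            },
            emission={c: np.asarray(e, dtype=float) for c, e in d["emission"].items()},
            length_pair_mean=dict(d["length_pair_mean"]),
            inter_event_gap_mean=float(d.get("inter_event_gap_mean", 20.0)),
            inter_activity_gap_mean=float(d.get("inter_activity_gap_mean", 600.0)),
            n_days=int(d.get("n_days", 7)),
            start_date=dt.date.fromisoformat(d.get("start_date", "2010-11-04")),
            seed=int(d.get("seed", 0)),
        )
        cfg.validate()
        return cfg


def _default_transition(classes: Sequence[str]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    rows = {
        # prev -> {current: prob}; structural constraints baked in:
        # only Sleeping may lead to Bed_to_Toilet, only Leave_Home to
        # Enter_Home, and Leave_Home leads to Enter_Home with certainty.
        "Work": {"Relax": 0.50, "Meal_Preparation": 0.20, "Leave_Home": 0.15,
                 "Eating": 0.05, "Work": 0.05, "Sleeping": 0.05},
        "Wash_Dishes": {"Relax": 0.50, "Meal_Preparation": 0.15, "Leave_Home": 0.10,
                        "Sleeping": 0.10, "Work": 0.05, "Eating": 0.05,
                        "Wash_Dishes": 0.05},
        "Sleeping": {"Bed_to_Toilet": 0.30, "Meal_Preparation": 0.30,
                     "Relax": 0.25, "Sleeping": 0.05, "Work": 0.05,
                     "Leave_Home": 0.05},
        "Relax": {"Meal_Preparation": 0.25, "Sleeping": 0.20, "Work": 0.15,
                  "Leave_Home": 0.15, "Relax": 0.10, "Wash_Dishes": 0.10,
                  "Eating": 0.05},
        "Meal_Preparation": {"Eating": 0.55, "Relax": 0.20, "Meal_Preparation": 0.10,
                             "Wash_Dishes": 0.05, "Work": 0.05, "Leave_Home": 0.05},
        "Eating": {"Wash_Dishes": 0.40, "Relax": 0.30, "Work": 0.10,
                   "Meal_Preparation": 0.10, "Eating": 0.05, "Leave_Home": 0.05},
        "Bed_to_Toilet": {"Sleeping": 0.95, "Relax": 0.05},
        "Enter_Home": {"Relax": 0.35, "Meal_Preparation": 0.25, "Work": 0.20,
                       "Sleeping": 0.10, "Eating": 0.05, "Wash_Dishes": 0.05},
        "Leave_Home": {"Enter_Home": 1.0},
    }
    T = np.zeros((len(classes), len(classes)))
    for prev, probs in rows.items():
        for cur, p in probs.items():
            T[idx[prev], idx[cur]] = p
    return T


def _default_hours() -> Dict[str, np.ndarray]:
    return {
        "Work": _hours({9: 1.0, 10: 1.0, 11: 0.6, 14: 0.8, 15: 0.6, 16: 0.4}),
        "Wash_Dishes": _hours({8: 0.6, 13: 0.8, 19: 1.0, 20: 0.6}),
        "Sleeping": _hours({21: 0.6, 22: 1.0, 23: 1.0, 0: 0.6, 1: 0.3}, base=0.005),
        "Relax": _hours({h: 0.5 for h in range(8, 22)}),
        "Meal_Preparation": _hours({7: 1.0, 8: 0.6, 12: 1.0, 13: 0.5, 18: 1.0, 19: 0.5}),
        "Eating": _hours({7: 0.6, 8: 1.0, 12: 0.8, 13: 1.0, 18: 0.6, 19: 1.0}),
        "Bed_to_Toilet": _hours({0: 0.6, 1: 0.8, 2: 1.0, 3: 1.0, 4: 0.8, 5: 0.4},
                                base=0.002),
        "Enter_Home": _hours({h: 0.5 for h in range(8, 21)}),
        "Leave_Home": _hours({h: 0.5 for h in range(8, 20)}),
    }


def _emission_over(sensors: Sequence[str], support: Sequence[str]) -> np.ndarray:
    e = np.zeros(len(sensors))
    for s in support:
        e[list(sensors).index(s)] = 1.0
    return e / e.sum()


def _default_emissions(sensors: Sequence[str]) -> Dict[str, np.ndarray]:
    M = [s for s in sensors if s.startswith("M")]
    D = [s for s in sensors if s.startswith("D")]
    kitchen = M[13:19]          # shared by Meal_Preparation and Wash_Dishes
    return {
        "Work": _emission_over(sensors, M[25:29]),
        "Wash_Dishes": _emission_over(sensors, kitchen[:4]),
        "Sleeping": _emission_over(sensors, M[0:4]),
        "Relax": _emission_over(sensors, M[8:13]),
        "Meal_Preparation": _emission_over(sensors, kitchen),
        "Eating": _emission_over(sensors, M[19:23]),
        "Bed_to_Toilet": _emission_over(sensors, M[3:7]),
        "Enter_Home": _emission_over(sensors, D[:2] + M[29:31]),
        "Leave_Home": _emission_over(sensors, D[:2] + M[29:31]),
    }


_DEFAULT_LENGTH_MEANS = {
    "Work": 12.0, "Wash_Dishes": 8.0, "Sleeping": 10.0, "Relax": 9.0,
    "Meal_Preparation": 14.0, "Eating": 7.0, "Bed_to_Toilet": 4.0,
    "Enter_Home": 3.0, "Leave_Home": 3.0,
}


def default_sim_config(n_days: int = 7, seed: int = 0) -> SimConfig:
    """Reference configuration with realistic structure (see module notes)."""
    cfg = SimConfig(
        transition=_default_transition(CLASS_ORDER),
        begin_hour_weights=_default_hours(),
        emission=_default_emissions(_DEFAULT_SENSORS),
        length_pair_mean=dict(_DEFAULT_LENGTH_MEANS),
        n_days=n_days,
        seed=seed,
    )
    cfg.validate()
    return cfg


def separable_sim_config(n_days: int = 7, seed: int = 0) -> SimConfig:
    """Every class emits from its own disjoint sensor set — classes are
    identifiable from the event sequence alone (learnability preset)."""
    cfg = default_sim_config(n_days=n_days, seed=seed)
    sensors = list(cfg.sensors)
    emission = {}
    for j, cls in enumerate(cfg.classes):
        emission[cls] = _emission_over(sensors, sensors[3 * j : 3 * j + 3])
    cfg = replace(cfg, emission=emission)
    cfg.validate()
    return cfg


def transition_only_sim_config(n_days: int = 7, seed: int = 0) -> SimConfig:
    """All classes share one uniform emission distribution — the event
    sequence carries no class signal, only the temporal context does
    (ablation preset for the previous-activity feature)."""
    cfg = default_sim_config(n_days=n_days, seed=seed)
    uniform = np.full(len(cfg.sensors), 1.0 / len(cfg.sensors))
    cfg = replace(cfg, emission={cls: uniform.copy() for cls in cfg.classes})
    cfg.validate()
    return cfg


def simulate_log(config: SimConfig) -> List[SensorEvent]:
    """Generate a chronological annotated event log.

    A schedule loop walks through ``n_days``: the next activity comes from
    the transition row of the previous one; its begin hour is drawn from the
    class's hour weights restricted to the remaining hours of the current
    day (rolling over to the next day when no mass remains, which is how
    night-time classes land at night).  Each activity emits k ~ Poisson
    ON/OFF sensor pairs (k clipped to 1-100) with exponential gaps; the
    first event carries the ``begin`` annotation and the last the ``end``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = list(config.classes)
    sensors = list(config.sensors)
    T = np.asarray(config.transition, dtype=float)

    start = dt.datetime.combine(config.start_date, dt.time(0, 0))
    horizon = start + dt.timedelta(days=config.n_days)
    clock = start
    events: List[SensorEvent] = []
    label = "Sleeping"  # the night-time start state of the schedule
    while True:
        # pick a begin time: class hour propensities, not earlier than clock
        w = np.asarray(config.begin_hour_weights[label], dtype=float).copy()
        hour_now = clock.hour
        w_today = w.copy()
        w_today[:hour_now] = 0.0
        if w_today.sum() > 0:
            hour = int(rng.choice(24, p=w_today / w_today.sum()))
            day = clock.date()
        else:  # no remaining mass today -> start tomorrow
            hour = int(rng.choice(24, p=w / w.sum()))
            day = clock.date() + dt.timedelta(days=1)
        begin = dt.datetime.combine(day, dt.time(hour)) + dt.timedelta(
            minutes=float(rng.uniform(0, 60))
        )
        if begin <= clock:
            begin = clock + dt.timedelta(
                seconds=float(rng.exponential(config.inter_activity_gap_mean))
            )
        if begin >= horizon:
            break

        n_pairs = int(np.clip(rng.poisson(config.length_pair_mean[label]), 1, 100))
        t = begin
        act_events: List[SensorEvent] = []
        for _ in range(n_pairs):
            sensor = sensors[int(rng.choice(len(sensors), p=config.emission[label]))]
            act_events.append(SensorEvent(t, sensor, "ON"))
            t += dt.timedelta(seconds=float(rng.exponential(config.inter_event_gap_mean)))
            act_events.append(SensorEvent(t, sensor, "OFF"))
            t += dt.timedelta(seconds=float(rng.exponential(config.inter_event_gap_mean)))
        act_events[0] = replace(act_events[0], activity=label, marker="begin")
        act_events[-1] = replace(act_events[-1], activity=label, marker="end")
        events.extend(act_events)

        clock = act_events[-1].timestamp + dt.timedelta(
            seconds=float(rng.exponential(config.inter_activity_gap_mean))
        )
        label = classes[int(rng.choice(len(classes), p=T[classes.index(label)]))]
    return events


def summarize_log(
    events: Sequence[SensorEvent], class_order: Sequence[str] = CLASS_ORDER
) -> Tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Descriptive statistics of an annotated log.

    Returns ``(transition_counts, begin_hour_hist, length_hist)`` where the
    transition table is indexed by current activity with previous-activity
    columns (the first instance, having no predecessor, is not counted),
    the hour histogram covers hours 0-23 and the length histogram counts
    events per instance.
    """
    instances = segment_activities(events)
    trans = pd.DataFrame(0, index=list(class_order), columns=list(class_order))
    hours = pd.Series(0, index=range(24))
    lengths: Dict[int, int] = {}
    prev: Optional[str] = None
    for inst in instances:
        if prev is not None and inst.label in trans.index and prev in trans.columns:
            trans.loc[inst.label, prev] += 1
        hours[inst.begin_hour] += 1
        lengths[len(inst)] = lengths.get(len(inst), 0) + 1
        prev = inst.label
    return trans, hours, pd.Series(lengths).sort_index()


def load_sim_config(path: str) -> SimConfig:
    """Read a :class:`SimConfig` from a YAML (or JSON) file."""
    import yaml

    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh))


def save_sim_config(config: SimConfig, path: str) -> None:
    """Write a :class:`SimConfig` as YAML."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
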