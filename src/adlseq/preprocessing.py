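"""Event cleaning, temporal-context attachment, class selection, balancing.

The cleaning rules mirror the standard CASAS Aruba preparation: temperature
readings are irrelevant to activity recognition and are removed; door states
``OPEN``/``CLOSE`` are folded onto the binary ``ON``/``OFF`` alphabet; and the
handful of corrupted ``OFF`` spellings found in real logs (``OF``, ``OFF5``,
...) are repaired.  After cleaning every surviving state is ``ON`` or ``OFF``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .casas_io import PREV_NONE, ActivityInstance, SensorEvent

__all__ = [
    "CLASS_ORDER",
    "Dataset",
    "clean_events",
    "attach_context",
    "select_classes",
    "balance_dataset",
]

#: Canonical 9-activity order used everywhere (vectors, confusion matrices,
#: report rows).  Index 6 is Bed_to_Toilet, index 8 Leave_Home.
CLASS_ORDER = (
    "Work",
    "Wash_Dishes",
    "Sleeping",
    "Relax",
    "Meal_Preparation",
    "Eating",
    "Bed_to_Toilet",
    "Enter_Home",
    "Leave_Home",
)


@dataclass
class Dataset:
    """A list of activity instances plus the fixed class order."""

    instances: list
    class_order: Sequence[str] = CLASS_ORDER

    def __len__(self) -> int:
        return len(self.instances)

    def labels(self) -> list:
        return [inst.label for inst in self.instances]

    def counts(self) -> dict:
        out = {c: 0 for c in self.class_order}
        for inst in self.instances:
            out[inst.label] = out.get(inst.label, 0) + 1
        return out


def _normalize_state(state: str) -> str:
    if state == "OPEN":
        return "ON"
    if state == "CLOSE":
        return "OFF"
    # malformed-OFF repair: any token starting "OF" that is not "ON"
    # (generalizes the observed corruptions "OF", "OFF5", ...)
    if state.startswith("OF"):
        return "OFF"
    return state


def clean_events(events: Iterable[SensorEvent]) -> list:
    """Drop temperature samples and normalize states to {ON, OFF}.

    Idempotent.  Raises ``ValueError`` listing the offending token if a
    surviving state cannot be normalized to the binary alphabet.
    """
    cleaned = []
    for ev in events:
        if ev.sensor_id.startswith("T"):
            continue
        state = _normalize_state(ev.state)
        if state not in ("ON", "OFF"):
            raise ValueError(
                f"unnormalizable sensor state {ev.state!r} on {ev.sensor_id} "
                f"at {ev.timestamp}"
            )
        cleaned.append(ev if state == ev.state else replace(ev, state=state))
    return cleaned


def attach_context(instances: Sequence[ActivityInstance]) -> list:
    """Set each instance's previous-activity label from its chronological
    predecessor (the first instance gets the no-predecessor sentinel).

    Must be called on the full chronological stream BEFORE class selection or
    balancing, so that the context records the true temporal predecessor.
    Returns the same list (mutated in place) for chaining.
    """
    prev = PREV_NONE
    for inst in instances:
        inst.prev_label = prev
        prev = inst.label
    return list(instances)


def select_classes(dataset: Dataset, keep: Sequence[str]) -> Dataset:
    """Restrict the dataset to ``keep`` labels.

    Rare classes (for Aruba: Housekeeping with 33 instances and Respirate
    with 6) are excluded this way before balancing.  ``prev_label`` values
    are deliberately NOT re-linked: the context keeps recording the true
    preceding activity even when that activity's class is dropped.
    """
    if not keep:
        raise ValueError("keep must name at least one class")
    kept = [inst for inst in dataset.instances if inst.label in keep]
    return Dataset(kept, class_order=tuple(keep))


def balance_dataset(dataset: Dataset, n_per_class: int, seed: int):
    """Sample ``n_per_class`` instances per class uniformly without
    replacement; return ``(balanced, remaining)``.

    The remaining split feeds the held-out evaluation on the imbalanced rest
    of the data.  Chronological order is preserved within both splits.
    Raises ``ValueError`` naming the first class with too few instances.
    """
    rng = np.random.default_rng(seed)
    by_class: dict = {c: [] for c in dataset.class_order}
    for idx, inst in enumerate(dataset.instances):
        by_class[inst.label].append(idx)
    chosen: set = set()
    for cls in dataset.class_order:
        idxs = by_class[cls]
        if len(idxs) < n_per_class:
            raise ValueError(
                f"class {cls!r} has {len(idxs)} instances, fewer than "
                f"n_per_class={n_per_class}"
            )
        chosen.update(rng.choice(idxs, size=n_per_class, replace=False).tolist())
    balanced = [inst for i, inst in enumerate(dataset.instances) if i in chosen]
    remaining = [inst for i, inst in enumerate(dataset.instances) if i not in chosen]
    return (
        Dataset(balanced, class_order=dataset.class_order),
        Dataset(remaining, class_order=dataset.class_order),
    )
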