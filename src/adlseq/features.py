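"""Encoding activity instances into model-ready samples.

Each sensor event becomes an integer token for its ``(sensor_id, state)``
pair; an instance's event sequence is aligned to a fixed length ``L`` (20 by
default) by zero-padding in front when shorter and keeping the last ``L``
events when longer.  The external context is a 9-element one-hot of the
previous activity (all-zero for "no predecessor") plus the begin hour scaled
to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence, Tuple, Union

import numpy as np

from .casas_io import PREV_NONE, ActivityInstance, SensorEvent
from .preprocessing import CLASS_ORDER, Dataset

__all__ = [
    "Vocabulary",
    "EncodedSample",
    "build_vocabulary",
    "encode_sequence",
    "encode_externals",
    "encode_instance",
    "encode_dataset",
]

PAD = 0  # reserved token index


@dataclass(frozen=True)
class Vocabulary:
    """Deterministic token table over observed ``(sensor_id, state)`` pairs.

    Index 0 is the padding token; real tokens start at 1 and are ordered
    lexicographically by sensor id then state, so two builds over the same
    events always agree.
    """

    tokens: tuple  # tuple[(sensor_id, state), ...], index i -> token i+1

    def __len__(self) -> int:  # including pad
        return len(self.tokens) + 1

    @property
    def index(self) -> dict:
        return {pair: i + 1 for i, pair in enumerate(self.tokens)}

    def token_of(self, event: SensorEvent, lenient: bool = False) -> int:
        tok = self.index.get((event.sensor_id, event.state))
        if tok is None:
            if lenient:
                return PAD
            raise KeyError(
                f"({event.sensor_id}, {event.state}) not in vocabulary; "
                "pass lenient=True to map unseen pairs to padding"
            )
        return tok

    def to_table(self, stream: Optional[IO[str]] = None) -> Optional[str]:
        """Two-column text serialization: token index, "sensor:state"."""
        lines = [f"{PAD}\t<pad>"] + [
            f"{i + 1}\t{sid}:{state}" for i, (sid, state) in enumerate(self.tokens)
        ]
        text = "".join(l + "\n" for l in lines)
        if stream is None:
            return text
        stream.write(text)
        return None

    @classmethod
    def from_table(cls, stream: Union[str, IO[str]]) -> "Vocabulary":
        if isinstance(stream, str):
            lines = stream.splitlines()
        else:
            lines = stream.read().splitlines()
        tokens = []
        for line in lines:
            if not line.strip():
                continue
            idx, name = line.split("\t")
            if int(idx) == PAD:
                continue
            sid, state = name.split(":")
            tokens.append((sid, state))
        return cls(tuple(tokens))


@dataclass
class EncodedSample:
    """Model-ready triple for one activity instance.

    ``i``   length-L integer token sequence (0 = pad);
    ``p``   9-element one-hot previous-activity vector (all-zero sentinel);
    ``t_s`` begin hour scaled to [0, 1];
    ``y``   class index 0-8.
    """

    i: np.ndarray
    p: np.ndarray
    t_s: float
    y: int

    @property
    def e(self) -> np.ndarray:
        """External vector [p^T, t_s]."""
        return np.concatenate([self.p, [self.t_s]])


def build_vocabulary(events: Iterable[SensorEvent]) -> Vocabulary:
    """Collect all observed (sensor, state) pairs into a stable vocabulary."""
    pairs = sorted({(ev.sensor_id, ev.state) for ev in events})
    if not pairs:
        raise ValueError("cannot build a vocabulary from zero events")
    return Vocabulary(tuple(pairs))


def encode_sequence(
    instance: ActivityInstance,
    vocab: Vocabulary,
    length: int = 20,
    lenient: bool = False,
) -> np.ndarray:
    """Fixed-length token encoding of an instance's event sequence.

    Shorter sequences are padded in front with the zero token; longer ones
    keep only their last ``length`` events, preserving order.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    tokens = [vocab.token_of(ev, lenient=lenient) for ev in instance.events]
    if len(tokens) >= length:
        tokens = tokens[-length:]
    else:
        tokens = [PAD] * (length - len(tokens)) + tokens
    return np.asarray(tokens, dtype=np.int64)


def encode_externals(
    instance: ActivityInstance, class_order: Sequence[str] = CLASS_ORDER
) -> Tuple[np.ndarray, float]:
    """One-hot previous activity and [0,1]-scaled begin hour.

    The no-predecessor sentinel maps to the all-zero vector so that a missing
    context injects no information.  Hours scale as hour/23 so both endpoints
    of the day land on 0 and 1.
    """
    p = np.zeros(len(class_order))
    if instance.prev_label != PREV_NONE:
        try:
            p[list(class_order).index(instance.prev_label)] = 1.0
        except ValueError:
            raise ValueError(
                f"previous label {instance.prev_label!r} not in class order"
            ) from None
    return p, instance.begin_hour / 23.0


def encode_instance(
    instance: ActivityInstance,
    vocab: Vocabulary,
    class_order: Sequence[str] = CLASS_ORDER,
    length: int = 20,
    lenient: bool = False,
) -> EncodedSample:
    p, t_s = encode_externals(instance, class_order)
    return EncodedSample(
        i=encode_sequence(instance, vocab, length, lenient),
        p=p,
        t_s=t_s,
        y=list(class_order).index(instance.label),
    )


def encode_dataset(
    dataset: Dataset,
    vocab: Vocabulary,
    length: int = 20,
    lenient: bool = False,
) -> list:
    """Encode every instance of a dataset (order preserved)."""
    return [
        encode_instance(inst, vocab, dataset.class_order, length, lenient)
        for inst in dataset.instances
    ]
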