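"""Session containers: ordered per-child interaction records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SessionRecord", "Session"]


@dataclass
class SessionRecord:
    """One timestamped interaction.

    ``intervention`` is None on steps where the engine chose not to
    intervene; ``confidence`` and ``intensity`` are filled only by the
    adaptive closed loop.
    """

    t: float
    x: np.ndarray
    intervention: object = None
    engagement: float | None = None
    confidence: float | None = None
    intensity: float | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)


@dataclass
class Session:
    """Ordered sequence of interaction records for one child."""

    child_id: str
    records: list = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        ts = [r.t for r in self.records]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("record times must be strictly increasing")
        ms = {r.x.shape[0] for r in self.records}
        if len(ms) > 1:
            raise ValueError("all records in a session must share the cue length M")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def engagements(self) -> np.ndarray:
        return np.array([r.engagement for r in self.records], dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.t for r in self.records], dtype=float)

    @property
    def cues(self) -> np.ndarray:
        return np.stack([r.x for r in self.records])

    def __eq__(self, other) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        if self.child_id != other.child_id or self.seed != other.seed:
            return False
        if len(self.records) != len(other.records):
            return False
        for a, b in zip(self.records, other.records):
            if (a.t != b.t or a.intervention != b.intervention
                    or not np.array_equal(a.x, b.x)):
                return False
            for f in ("engagement", "confidence", "intensity"):
                if getattr(a, f) != getattr(b, f):
                    return False
        return True
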