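"""Sampling grid of the germination time course.

The experiment samples a dormant-spore state followed by a dense series of
time points at 30-min spacing.  The dormant point has no defined clock time;
by convention it sits half an interval before the first germination sample,
so the default grid is uniform: t_k = 0.5 k hours for k = 0..12 with labels
TDorm, T0, T0.5, ..., T5.5.  Offsets of the origin are absorbed by the
kinetic model's parameters, and the grid is user-configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeGrid", "default_grid"]


@dataclass(frozen=True)
class TimeGrid:
    """Ordered time-point labels and the numeric time (hours) assigned to each."""

    labels: tuple[str, ...]
    hours: np.ndarray = field(repr=False)

    def __post_init__(self):
        hours = np.asarray(self.hours, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "hours", hours)
        if len(self.labels) != hours.size:
            raise ValueError("labels and hours must have equal length")
        if hours.size < 2 or np.any(np.diff(hours) <= 0):
            raise ValueError("hours must be strictly increasing with >= 2 points")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def default_grid(n_points: int = 13, spacing_h: float = 0.5) -> TimeGrid:
    """Default 13-point germination grid: TDorm then T0..T5.5 every 30 min."""
    labels = ["TDorm"] + [f"T{spacing_h * k:g}" for k in range(n_points - 1)]
    hours = spacing_h * np.arange(n_points, dtype=float)
    return TimeGrid(tuple(labels), hours)
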