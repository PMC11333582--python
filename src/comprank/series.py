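"""Daily scalar time series used across behavioral and neural analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LongSeries:
    """A per-day scalar series over an observation window.

    Days are integer indices on a common calendar (day 0 = intervention
    start for longitudinal experiments). Days must be strictly increasing
    and values must be finite after alignment.
    """

    label: str
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.ndim != 1 or self.values.ndim != 1:
            raise ValueError("days and values must be 1-D")
        if self.days.size != self.values.size:
            raise ValueError("days and values must have equal length")
        if self.days.size and np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")

    def __len__(self) -> int:
        return self.days.size

    def align(self, other: "LongSeries") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (common_days, self_values, other_values) on the shared grid."""
        common, ia, ib = np.intersect1d(self.days, other.days, return_indices=True)
        xa = self.values[ia]
        xb = other.values[ib]
        if common.size and (np.any(~np.isfinite(xa)) or np.any(~np.isfinite(xb))):
            raise ValueError("series contain non-finite values on the common day grid")
        return common, xa, xb
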