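"""Acceptance filter for miniature EPSC events.

Candidate events from a whole-cell recording are accepted only when the
amplitude exceeds 5 pA, the rise rate is at least 0.3 pA/ms, and the
decay time constant lies within 1-12 ms.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["filter_mepsc_events", "AMPLITUDE_MIN_PA", "RISE_RATE_MIN_PA_PER_MS", "DECAY_TAU_RANGE_MS"]

AMPLITUDE_MIN_PA = 5.0
RISE_RATE_MIN_PA_PER_MS = 0.3
DECAY_TAU_RANGE_MS = (1.0, 12.0)

REQUIRED = ("amplitude_pa", "rise_rate_pa_per_ms", "decay_tau_ms")


def filter_mepsc_events(events: pd.DataFrame) -> pd.DataFrame:
    """Return the accepted subset of candidate mEPSC events.

    Keep iff amplitude > 5 pA AND rise rate >= 0.3 pA/ms AND decay tau
    in [1, 12] ms. Missing measurements raise.
    """
    missing = [c for c in REQUIRED if c not in events.columns]
    if missing:
        raise ValueError(f"events lack required fields: {missing}")
    if events[list(REQUIRED)].isna().any().any():
        raise ValueError("events with missing measurements")
    lo, hi = DECAY_TAU_RANGE_MS
    keep = (
        (events["amplitude_pa"] > AMPLITUDE_MIN_PA)
        & (events["rise_rate_pa_per_ms"] >= RISE_RATE_MIN_PA_PER_MS)
        & (events["decay_tau_ms"] >= lo)
        & (events["decay_tau_ms"] <= hi)
    )
    return events[keep].reset_index(drop=True)
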