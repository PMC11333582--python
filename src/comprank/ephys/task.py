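"""Task-relatedness of units and population summaries.

Each unit's per-trial firing rate in a fixed window around reward-zone
entry is contrasted (i) between won and lost trials and (ii) between
trials against a dominant vs a subordinate opponent. A two-sided
Mann-Whitney U test (Welch t optional) at level alpha flags each
contrast; the two flags define the four mutually exclusive task
categories: competition-, rank-, both- and non-related. Units with too
few trials in any condition are marked unclassifiable and excluded from
the population denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from ..series import LongSeries

__all__ = [
    "trial_firing_rates",
    "classify_task_related",
    "PopulationSummary",
    "summarize_population",
    "delta_zscore_series",
]

CATEGORIES = ("competition", "rank", "both", "non")


def trial_firing_rates(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    anchor: str = "t_reach_rz_s",
    window_s: tuple[float, float] = (-2.0, 2.0),
) -> pd.DataFrame:
    """Per-unit, per-trial firing rate (Hz) in [anchor+a, anchor+b).

    ``spikes`` holds unit_id / spike_time_s; ``trials`` one row per
    trial of the recorded subject, carrying the anchor timestamp and the
    outcome annotations. Rates are computed for every unit against every
    trial row passed in (the caller restricts trials to the unit's
    session).
    """
    a, b = window_s
    if b <= a:
        raise ValueError("analysis window must have positive length")
    if anchor not in trials.columns:
        raise ValueError(f"trials lack anchor column {anchor!r}")
    if trials[anchor].isna().any():
        raise ValueError(f"trials with missing anchor event {anchor!r}")
    width = b - a
    t_anchor = trials[anchor].to_numpy(dtype=float)
    keep_cols = [
        c
        for c in (
            "group_id",
            "day",
            "pair_id",
            "trial_idx",
            "subject_id",
            "opponent_id",
            "pellet_winner_id",
            "opponent_relative_rank",
        )
        if c in trials.columns
    ]
    frames = []
    for unit_id, unit_spikes in spikes.groupby("unit_id", sort=False):
        t = np.sort(unit_spikes["spike_time_s"].to_numpy(dtype=float))
        lo = np.searchsorted(t, t_anchor + a, side="left")
        hi = np.searchsorted(t, t_anchor + b, side="left")  # half-open window
        block = trials[keep_cols].copy()
        block.insert(0, "unit_id", unit_id)
        block["rate_hz"] = (hi - lo) / width
        frames.append(block)
    if not frames:
        return pd.DataFrame(columns=["unit_id", *keep_cols, "rate_hz"])
    return pd.concat(frames, ignore_index=True)


def _contrast_pvalue(
    x: np.ndarray, y: np.ndarray, test: str
) -> tuple[float, float]:
    """Two-sided p-value and absolute mean-rate difference (Hz)."""
    effect = float(abs(x.mean() - y.mean()))
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0, effect  # identical constant rates: no evidence
    if test == "mannwhitney":
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    elif test == "welch":
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    else:
        raise ValueError("test must be 'mannwhitney' or 'welch'")
    return p, effect


def classify_task_related(
    rates: pd.DataFrame,
    alpha: float = 0.05,
    min_trials: int = 5,
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Sort units into competition-/rank-/both-/non-related categories.

    ``rates`` must carry unit_id, rate_hz, and the trial annotations
    subject_id + pellet_winner_id (win/loss contrast) and
    opponent_relative_rank (dominant/subordinate contrast). No
    multiple-testing correction is applied across units; each unit gets
    two per-contrast p-values at level ``alpha``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    rows = []
    for unit_id, block in rates.groupby("unit_id", sort=False):
        won = (block["pellet_winner_id"] == block["subject_id"]).to_numpy()
        dom = (block["opponent_relative_rank"] == "dominant").to_numpy()
        rate = block["rate_hz"].to_numpy(dtype=float)
        groups = [rate[won], rate[~won], rate[dom], rate[~dom]]
        if min(g.size for g in groups) < min_trials:
            rows.append(
                {
                    "unit_id": unit_id,
                    "category": "unclassifiable",
                    "p_competition": np.nan,
                    "p_rank": np.nan,
                    "effect_competition_hz": np.nan,
                    "effect_rank_hz": np.nan,
                }
            )
            continue
        p_comp, eff_comp = _contrast_pvalue(groups[0], groups[1], test)
        p_rank, eff_rank = _contrast_pvalue(groups[2], groups[3], test)
        sig_comp = p_comp < alpha
        sig_rank = p_rank < alpha
        if sig_comp and sig_rank:
            cat = "both"
        elif sig_comp:
            cat = "competition"
        elif sig_rank:
            cat = "rank"
        else:
            cat = "non"
        rows.append(
            {
                "unit_id": unit_id,
                "category": cat,
                "p_competition": p_comp,
                "p_rank": p_rank,
                "effect_competition_hz": eff_comp,
                "effect_rank_hz": eff_rank,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population summary


def _pct(count: int, total: int) -> float | None:
    """Percentage rounded half-away-from-zero to 1 decimal."""
    if total == 0:
        return None
    q = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass
class PopulationSummary:
    """Cross-tabulation of cell type x task category.

    ``counts`` maps (cell_type, category) -> count; ``percentages`` maps
    scope ("all", "excitatory", "inhibitory") -> category -> percentage
    of that scope's total (1-decimal, half away from zero), plus a
    "task_related" entry (competition + rank + both). ``totals`` holds
    the per-scope denominators.
    """

    counts: dict = field(default_factory=dict)
    percentages: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "counts": {f"{t}/{c}": v for (t, c), v in self.counts.items()},
            "percentages": self.percentages,
            "totals": self.totals,
        }


def summarize_population(
    cell_types: pd.DataFrame, task_categories: pd.DataFrame
) -> PopulationSummary:
    """Cross-tabulate unit types and task categories.

    Every classified unit must appear in both tables; units categorized
    as unclassifiable (insufficient trials) are dropped from numerators
    and denominators alike.
    """
    ct = cell_types[["unit_id", "cell_type"]]
    tc = task_categories[["unit_id", "category"]]
    only_ct = set(ct["unit_id"]) - set(tc["unit_id"])
    only_tc = set(tc["unit_id"]) - set(ct["unit_id"])
    if only_ct or only_tc:
        raise ValueError(
            f"units present in one table only: {sorted(only_ct | only_tc)[:5]}"
        )
    merged = ct.merge(tc, on="unit_id")
    merged = merged[merged["category"] != "unclassifiable"]

    counts = {
        (t, c): int(((merged["cell_type"] == t) & (merged["category"] == c)).sum())
        for t in ("excitatory", "inhibitory")
        for c in CATEGORIES
    }
    totals = {
        "all": int(len(merged)),
        "excitatory": int((merged["cell_type"] == "excitatory").sum()),
        "inhibitory": int((merged["cell_type"] == "inhibitory").sum()),
    }
    percentages: dict[str, dict[str, float | None]] = {}
    for scope in ("all", "excitatory", "inhibitory"):
        if scope == "all":
            sub = merged
        else:
            sub = merged[merged["cell_type"] == scope]
        total = len(sub)
        scope_pct = {
            c: _pct(int((sub["category"] == c).sum()), total) for c in CATEGORIES
        }
        task_related = int(sub["category"].isin(("competition", "rank", "both")).sum())
        scope_pct["task_related"] = _pct(task_related, total)
        percentages[scope] = scope_pct
    return PopulationSummary(counts=counts, percentages=percentages, totals=totals)


# ---------------------------------------------------------------------------
# longitudinal delta z-scores


def delta_zscore_series(
    rates: pd.DataFrame,
    baseline_day: int = 0,
    mode: str = "pooled",
) -> dict[str, LongSeries]:
    """Daily population firing-rate delta-z series per task category.

    For each category, the day-d z-score is
    ``(mean_d - mean_baseline) / SD_baseline`` where the baseline mean
    and SD come from the baseline day's per-trial rate distribution
    (pooled across the category's units; ``mode='per_unit'`` z-scores
    each unit separately and averages). The series is referenced to day
    0 so it starts at 0.
    """
    if mode not in ("pooled", "per_unit"):
        raise ValueError("mode must be 'pooled' or 'per_unit'")
    if "day" not in rates.columns or "rate_hz" not in rates.columns:
        raise ValueError("rates must have day and rate_hz columns")
    out: dict[str, LongSeries] = {}
    for category, block in rates.groupby("category", sort=True):
        days = np.sort(block["day"].unique())
        if baseline_day not in days:
            raise ValueError(f"baseline day {baseline_day} absent for {category!r}")

        def series_from(sub: pd.DataFrame) -> np.ndarray:
            base = sub.loc[sub["day"] == baseline_day, "rate_hz"]
            sd0 = float(base.std(ddof=1))
            if not np.isfinite(sd0) or sd0 == 0:
                raise ValueError("zero baseline SD")
            m0 = float(base.mean())
            means = sub.groupby("day")["rate_hz"].mean().reindex(days)
            return ((means - m0) / sd0).to_numpy()

        if mode == "pooled":
            z = series_from(block)
        else:
            per_unit = [series_from(u) for _, u in block.groupby("unit_id")]
            z = np.mean(per_unit, axis=0)
        if days[0] == 0:
            z = z - z[np.searchsorted(days, 0)]
        out[category] = LongSeries(f"delta_z_{category}", days, z)
    return out
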