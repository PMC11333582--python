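"""Synthetic cohort generator with known ground truth.

Everything downstream of spike sorting and video scoring is exercised
against tables produced here: per-unit averaged waveforms, spike-time
tables, food-competition trial tables, tube-test bout logs, warm-spot
occupancy logs, and 21-day longitudinal intervention series. The ground
truth (cell type, task category, latent dominance, configured onset lags)
is returned alongside, so every analysis stage has a closed-loop test.

Determinism contract: identical (seed, config) produces bit-identical
tables. Sub-streams are derived per (stage, group/unit) by stable hashing
of the stream name, so enlarging one part of the cohort does not perturb
the others.
"""

from __future__ import annotations

import itertools
import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CELL_TYPES, TASK_CATEGORIES, GeneratorConfig
from .series import LongSeries

__all__ = [
    "substream",
    "implanted_mouse",
    "generate_unit_population",
    "synth_waveform",
    "generate_waveform_table",
    "generate_competition_session",
    "generate_spike_trains",
    "homogeneous_train",
    "generate_tube_and_warmspot",
    "generate_longitudinal",
    "reference_cohort_config",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive an independent RNG stream from (seed, name).

    The name is hashed with CRC-32 so streams are stable across runs and
    insensitive to the order in which stages execute.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# unit population


def implanted_mouse(config: GeneratorConfig, group_id: str) -> str:
    """Id of the electrode-implanted mouse of a group.

    By convention the recorded animal is the ``recorded_index``-th mouse
    by descending latent competitiveness (1 = mid-ranked, as implanted
    cohorts typically choose a mid-ranked subject).
    """
    scores = config.group_competitiveness()
    order = np.argsort(scores)[::-1]
    k = int(order[min(config.recorded_index, len(order) - 1)])
    return f"{group_id}m{k}"


def _quota_counts(props: Mapping[str, float], total: int) -> dict[str, int]:
    """Largest-remainder apportionment of `total` over category fractions."""
    raw = {k: props[k] * total for k in TASK_CATEGORIES}
    counts = {k: int(np.floor(v + 1e-9)) for k, v in raw.items()}
    remainder = total - sum(counts.values())
    order = sorted(TASK_CATEGORIES, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def generate_unit_population(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the unit population and its ground-truth labels.

    Returns
    -------
    units : DataFrame with unit_id, group_id, waveform features
        (tp_latency_ms, half_width_ms, auc) and the per-unit doublet
        probability (bursty broad-spiking units only).
    truth : DataFrame with unit_id, cell_type, task_category.
    """
    rng = substream(config.seed, "unit_population")
    n = config.n_units

    if config.quota_mode:
        n_exc = int(round(n * config.prop_excitatory))
        types = ["excitatory"] * n_exc + ["inhibitory"] * (n - n_exc)
        categories: list[str] = []
        for cell_type in CELL_TYPES:
            n_type = types.count(cell_type)
            counts = _quota_counts(config.category_props[cell_type], n_type)
            for cat in TASK_CATEGORIES:
                categories.extend([cat] * counts[cat])
    else:
        types = list(
            rng.choice(
                CELL_TYPES,
                size=n,
                p=[config.prop_excitatory, 1 - config.prop_excitatory],
            )
        )
        types.sort()  # excitatory first, matching quota layout
        categories = []
        for cell_type in CELL_TYPES:
            n_type = types.count(cell_type)
            props = config.category_props[cell_type]
            categories.extend(
                rng.choice(
                    TASK_CATEGORIES, size=n_type, p=[props[c] for c in TASK_CATEGORIES]
                )
            )

    rows = []
    for i, (cell_type, category) in enumerate(zip(types, categories)):
        params = config.waveform_params[cell_type]
        feats = {}
        for name, (mean, sd) in params.items():
            v = rng.normal(mean, sd)
            while v <= 0:  # waveform features are strictly positive
                v = rng.normal(mean, sd)
            feats[name] = v
        rows.append(
            {
                "unit_id": f"u{i:04d}",
                "group_id": f"g{i % config.n_groups}",
                "cell_type": cell_type,
                "task_category": category,
                "doublet_prob": config.doublet_prob if cell_type == "excitatory" else 0.0,
                **feats,
            }
        )
    df = pd.DataFrame(rows)
    truth = df[["unit_id", "cell_type", "task_category"]].copy()
    units = df[
        [
            "unit_id",
            "group_id",
            "tp_latency_ms",
            "half_width_ms",
            "auc",
            "doublet_prob",
        ]
    ].copy()
    return units, truth


def synth_waveform(
    tp_latency_ms: float,
    half_width_ms: float,
    auc: float,
    sampling_rate_hz: float = 40000.0,
    duration_ms: float = 2.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Biphasic averaged-waveform template parameterized by its features.

    A negative Gaussian trough followed by a smaller positive Gaussian
    peak. The trough SD is set from the requested half-width (full width
    at half depth of a Gaussian = 2*sqrt(2 ln 2)*sigma), the peak is
    placed tp_latency after the trough, and the amplitude is scaled so
    the absolute-area integral matches the requested AUC (uV*ms).

    Returns (time_ms, amplitude_uv).
    """
    if min(tp_latency_ms, half_width_ms, auc) <= 0:
        raise ValueError("waveform features must be strictly positive")
    n = int(round(duration_ms * 1e-3 * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz * 1e3  # ms
    sigma1 = half_width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma2 = 1.6 * sigma1
    t_trough = 0.35 * duration_ms
    t_peak = t_trough + tp_latency_ms
    w = -np.exp(-0.5 * ((t - t_trough) / sigma1) ** 2)
    w += 0.45 * np.exp(-0.5 * ((t - t_peak) / sigma2) ** 2)
    # rescale so the realized absolute area matches the requested AUC
    # exactly (the opposite-sign lobes partially cancel where they overlap)
    w *= auc / np.trapezoid(np.abs(w), dx=1e3 / sampling_rate_hz)
    return t, w


def generate_waveform_table(config: GeneratorConfig, units: pd.DataFrame) -> pd.DataFrame:
    """Long-format averaged waveforms (unit_id, sample_idx, amplitude_uv)."""
    frames = []
    for row in units.itertuples(index=False):
        _, w = synth_waveform(
            row.tp_latency_ms,
            row.half_width_ms,
            row.auc,
            sampling_rate_hz=config.sampling_rate_hz,
            duration_ms=config.waveform_ms,
        )
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": row.unit_id,
                    "sample_idx": np.arange(w.size),
                    "amplitude_uv": w,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# food-competition sessions


def _win_probability(ci: float, cj: float, tau: float) -> float:
    return 1.0 / (1.0 + np.exp(-(ci - cj) / tau))


def generate_competition_session(
    config: GeneratorConfig,
    group_id: str,
    day: int = 0,
    competitiveness: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """One round-robin food-competition session for a group.

    Every unordered pair of cage mates runs ``trials_per_pair`` trials,
    starting alternately from the two starting areas. The pellet winner
    is drawn from a logistic (Bradley-Terry) win probability on the
    latent competitiveness difference; timestamps satisfy
    gate-open < SA-exit < RZ-entry, with the eventual winner tending to
    exit and reach the reward zone first.

    The table holds two rows per trial, one per mouse perspective
    (subject_id / opponent_id), sharing (pair_id, trial_idx).
    """
    mice = [f"{group_id}m{k}" for k in range(config.mice_per_group)]
    if competitiveness is None:
        scores = dict(zip(mice, config.group_competitiveness()))
    else:
        missing = [m for m in mice if m not in competitiveness]
        if missing:
            raise ValueError(f"missing competitiveness scores for {missing}")
        scores = {m: float(competitiveness[m]) for m in mice}

    rng = substream(config.seed, f"session:{group_id}:{day}")
    rows = []
    t_session = 0.0
    for pair_idx, (a, b) in enumerate(itertools.combinations(mice, 2)):
        pair_id = f"{a}-{b}"
        p_a = _win_probability(scores[a], scores[b], config.win_temperature)
        for trial_idx in range(config.trials_per_pair):
            start_area = "A" if trial_idx % 2 == 0 else "B"
            winner = a if rng.random() < p_a else b
            t_gate = t_session
            lat = {}
            for m in (a, b):
                handicap = 0.0 if m == winner else 0.25
                t_exit = t_gate + 0.4 + rng.exponential(0.3) + handicap
                t_rz = t_exit + 1.0 + rng.exponential(0.6) + 3.0 * handicap
                lat[m] = (t_exit, t_rz)
            for m, opp in ((a, b), (b, a)):
                dominant = scores[opp] > scores[m] or (
                    scores[opp] == scores[m] and opp < m
                )
                rows.append(
                    {
                        "group_id": group_id,
                        "day": day,
                        "session_id": f"{group_id}-d{day}",
                        "pair_id": pair_id,
                        "trial_idx": trial_idx,
                        "subject_id": m,
                        "opponent_id": opp,
                        "start_area": start_area,
                        "t_gate_open_s": t_gate,
                        "t_exit_sa_s": lat[m][0],
                        "t_reach_rz_s": lat[m][1],
                        "pellet_winner_id": winner,
                        "opponent_relative_rank": "dominant" if dominant else "subordinate",
                    }
                )
            t_session = t_gate + 40.0
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spike trains


def _inject_doublets(
    spikes: np.ndarray, doublet_prob: float, rng: np.random.Generator
) -> np.ndarray:
    if doublet_prob <= 0 or spikes.size == 0:
        return spikes
    mask = rng.random(spikes.size) < doublet_prob
    extras = spikes[mask] + rng.uniform(3e-3, 5e-3, size=int(mask.sum()))
    return np.sort(np.concatenate([spikes, extras]))


def _piecewise_poisson(
    segments: Sequence[tuple[float, float, float]], rng: np.random.Generator
) -> np.ndarray:
    times = []
    for t0, t1, rate in segments:
        if t1 <= t0 or rate <= 0:
            continue
        n = rng.poisson(rate * (t1 - t0))
        if n:
            times.append(rng.uniform(t0, t1, size=n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def homogeneous_train(
    rate_hz: float,
    duration_s: float,
    rng: np.random.Generator,
    doublet_prob: float = 0.0,
) -> np.ndarray:
    """Homogeneous Poisson spike train, optionally with 3-5 ms doublets."""
    base = _piecewise_poisson([(0.0, duration_s, rate_hz)], rng)
    return _inject_doublets(base, doublet_prob, rng)


def generate_spike_trains(
    config: GeneratorConfig,
    trials: pd.DataFrame,
    truth: pd.DataFrame,
    units: pd.DataFrame | None = None,
    window_s: tuple[float, float] = (-2.0, 2.0),
) -> pd.DataFrame:
    """Per-unit spike trains across the recorded mouse's trials.

    Each unit fires as an inhomogeneous Poisson process at base_rate_hz
    over [gate-2 s, RZ+4 s] of every trial of its group's implanted
    mouse. In the analysis window ``window_s`` around RZ entry the rate
    is multiplied by modulation_gain on win trials (competition-related
    units), dominant-opponent trials (rank-related units), or either
    (both-related). Bursty units receive doublets at 3-5 ms.
    """
    if trials.empty:
        raise ValueError("trial table is empty")
    merged = truth.copy()
    if units is not None:
        merged = merged.merge(
            units[["unit_id", "group_id", "doublet_prob"]], on="unit_id", how="left"
        )
    else:
        merged["group_id"] = [
            f"g{i % config.n_groups}" for i in range(len(merged))
        ]
        merged["doublet_prob"] = np.where(
            merged["cell_type"] == "excitatory", config.doublet_prob, 0.0
        )

    frames = []
    for group_id, unit_block in merged.groupby("group_id", sort=False):
        recorded = implanted_mouse(config, group_id)
        g_trials = trials[
            (trials["group_id"] == group_id) & (trials["subject_id"] == recorded)
        ]
        if g_trials.empty:
            continue
        won = (g_trials["pellet_winner_id"] == g_trials["subject_id"]).to_numpy()
        dom = (g_trials["opponent_relative_rank"] == "dominant").to_numpy()
        t_gate = g_trials["t_gate_open_s"].to_numpy()
        t_rz = g_trials["t_reach_rz_s"].to_numpy()
        zero = np.zeros(len(g_trials), dtype=int)
        for row in unit_block.itertuples(index=False):
            rng = substream(config.seed, f"spikes:{row.unit_id}")
            cat = row.task_category
            # multiplicative modulation per condition: both-related units
            # stack the win gain and the dominant-opponent gain
            exponent = {
                "competition": won.astype(int),
                "rank": dom.astype(int),
                "both": won.astype(int) + dom.astype(int),
                "non": zero,
            }[cat]
            all_times = []
            for k in range(len(g_trials)):
                w0 = t_rz[k] + window_s[0]
                w1 = t_rz[k] + window_s[1]
                gain = config.modulation_gain ** exponent[k]
                segs = [
                    (t_gate[k] - 2.0, w0, config.base_rate_hz),
                    (w0, w1, config.base_rate_hz * gain),
                    (w1, t_rz[k] + 4.0, config.base_rate_hz),
                ]
                all_times.append(_piecewise_poisson(segs, rng))
            spikes = np.concatenate(all_times) if all_times else np.empty(0)
            spikes = _inject_doublets(np.sort(spikes), row.doublet_prob, rng)
            frames.append(pd.DataFrame({"unit_id": row.unit_id, "spike_time_s": spikes}))
    if not frames:
        return pd.DataFrame(columns=["unit_id", "spike_time_s"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# tube test and warm spot


def generate_tube_and_warmspot(
    config: GeneratorConfig, group_id: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily round-robin tube bouts and warm-spot occupancy for n_days.

    Bout winners follow the latent dominance order with an upset
    probability that decays linearly to zero by tube_time_stable_day;
    bout durations are long before stabilization and short after
    (hierarchies settle into quick, low-conflict bouts). Warm-spot
    occupancy is monotone in latent dominance in expectation.
    """
    if config.n_days < 1:
        raise ValueError("n_days must be >= 1")
    mice = [f"{group_id}m{k}" for k in range(config.mice_per_group)]
    scores = dict(zip(mice, config.group_competitiveness()))
    rng = substream(config.seed, f"tube:{group_id}")

    stable = max(1, config.tube_time_stable_day)
    tube_rows = []
    ws_rows = []
    session_s = 1200.0
    for day in range(1, config.n_days + 1):
        if stable <= 1:
            noise = 0.0
        else:
            noise = max(0.0, 1.0 - (day - 1) / (stable - 1))
        for a, b in itertools.combinations(mice, 2):
            favorite = a if scores[a] >= scores[b] else b
            underdog = b if favorite == a else a
            p_upset = config.tube_noise * noise
            winner = underdog if rng.random() < p_upset else favorite
            if day < stable:
                duration = max(0.5, rng.normal(25.0, 5.0))
            else:
                duration = max(0.5, rng.normal(8.0, 2.0))
            tube_rows.append(
                {
                    "group_id": group_id,
                    "day": day,
                    "mouse_a": a,
                    "mouse_b": b,
                    "winner": winner,
                    "duration_s": duration,
                }
            )
        jitter = rng.normal(0.0, config.ws_noise, size=len(mice))
        logits = np.array([scores[m] for m in mice]) / 0.5 + jitter
        occ = session_s * np.exp(logits) / np.exp(logits).sum()
        for m, o in zip(mice, occ):
            ws_rows.append(
                {"group_id": group_id, "day": day, "mouse_id": m, "occupancy_s": o}
            )
    return pd.DataFrame(tube_rows), pd.DataFrame(ws_rows)


# ---------------------------------------------------------------------------
# longitudinal intervention series


def _onset_ramp(days: np.ndarray, onset_day: int, ramp_days: int) -> np.ndarray:
    """0 before onset_day, linear rise to 1 over ramp_days after it."""
    return np.clip((days - onset_day) / max(1, ramp_days), 0.0, 1.0)


def generate_longitudinal(config: GeneratorConfig) -> dict:
    """21-day intervention bundle with configured onset lags.

    The competition-related population rate gain and the winning
    proportion start changing at intervention_day + 1 with coupled
    (zero-lag) trajectories; the rank-related rate series follows the
    same trajectory delayed by rank_lag_days; the tube-test rank series
    changes after the competition change and tube-bout durations bulge
    during the re-establishment window (hysteresis).

    Returns a dict with:
      rates : DataFrame (day, trial_idx, category, rate_hz) of per-trial
          population rates for the competition- and rank-related pools
      winning : LongSeries of daily pellet-winning proportion
      tube_time : LongSeries of mean daily tube-bout duration
      tube_rank : LongSeries of daily tube rank of the treated mouse
    """
    if config.rank_lag_days >= config.n_days:
        raise ValueError("rank_lag_days must be smaller than n_days")
    rng = substream(config.seed, "longitudinal")
    days = np.arange(config.n_days)
    d0 = config.intervention_day
    eff = config.intervention_effect
    e_comp = eff * _onset_ramp(days, d0, config.ramp_days)
    e_rank = eff * _onset_ramp(days, d0 + config.rank_lag_days, config.ramp_days)

    window_s = 4.0  # analysis window length entering the rate estimate
    gain0 = config.modulation_gain
    tpd = config.trials_per_day
    frames = []
    for cat, e in (("competition", e_comp), ("rank", e_rank)):
        gain_t = gain0 - (gain0 - 1.0) * e  # modulation collapses toward 1
        lam = config.base_rate_hz * gain_t * window_s
        counts = rng.poisson(np.repeat(lam, tpd))
        frames.append(
            pd.DataFrame(
                {
                    "day": np.repeat(days, tpd),
                    "trial_idx": np.tile(np.arange(tpd), days.size),
                    "category": cat,
                    "rate_hz": counts / window_s,
                }
            )
        )
    rates = pd.concat(frames, ignore_index=True)

    # behavioral point data = cohort-mean winning proportion: one treated
    # mouse per group, (mice_per_group - 1) pairings x trials_per_pair
    # trials per day, averaged over all groups
    n_daily = config.trials_per_pair * (config.mice_per_group - 1) * config.n_groups
    p_win = 0.75 - 0.5 * e_comp
    wins = rng.binomial(n_daily, p_win)
    winning = LongSeries("winning_proportion", days, wins / n_daily)

    bump = e_comp - e_rank  # elevated only while rank lags behind competition
    tube_time = LongSeries(
        "tube_time_s",
        days,
        8.0 + 17.0 * bump + rng.normal(0.0, 0.5, size=days.size),
    )
    rank_vals = np.rint(2.0 + 2.0 * e_rank).astype(float)
    tube_rank = LongSeries("tube_rank", days, rank_vals)
    return {
        "rates": rates,
        "winning": winning,
        "tube_time": tube_time,
        "tube_rank": tube_rank,
    }


# ---------------------------------------------------------------------------
# study-condition presets


def reference_cohort_config(seed: int = 0) -> GeneratorConfig:
    """Configuration emulating the recorded cohort for unit typing and
    task categorization.

    The defaults already carry the reference cohort composition
    (379 units, 288/91 split, category quotas). For the categorization
    contrasts the session uses equal latent competitiveness, so the win
    outcome is a fair coin independent of the opponent's relative rank:
    with graded competitiveness a mouse wins more against subordinate
    opponents and competition modulation would leak into the rank
    contrast, blurring the configured ground truth.
    """
    return GeneratorConfig(seed=seed, competitiveness=[0.0, 0.0, 0.0, 0.0])
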