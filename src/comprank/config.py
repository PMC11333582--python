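"""Run configuration: generator settings, analysis settings, YAML loading.

The generator defaults emulate the recorded cohort the pipeline was built
around: groups of four co-housed male mice tested in round-robin food
competition (10 trials per pair, 5 starts from each starting area), a
379-unit prelimbic population with a 288/91 broad-/narrow-spiking split,
task-category quotas matching its cross-tabulation, and a 21-day
intervention window in which competition-related modulation changes
immediately while rank-related modulation follows with a 10-day lag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import yaml

TASK_CATEGORIES = ("competition", "rank", "both", "non")
CELL_TYPES = ("excitatory", "inhibitory")


def _default_category_props() -> dict[str, dict[str, float]]:
    # Reference cohort cross-tabulation: excitatory 86/22/14/166 of 288,
    # inhibitory 12/10/6/63 of 91.
    return {
        "excitatory": {
            "competition": 86 / 288,
            "rank": 22 / 288,
            "both": 14 / 288,
            "non": 166 / 288,
        },
        "inhibitory": {
            "competition": 12 / 91,
            "rank": 10 / 91,
            "both": 6 / 91,
            "non": 63 / 91,
        },
    }


def _default_waveform_params() -> dict[str, dict[str, tuple[float, float]]]:
    # (mean, sd) per feature; broad (excitatory) vs narrow (inhibitory)
    # spiking. Means separated by ~6 within-class SD on trough-to-peak
    # latency so waveform typing has an unambiguous ground truth.
    return {
        "excitatory": {
            "tp_latency_ms": (0.78, 0.08),
            "half_width_ms": (0.38, 0.04),
            "auc": (220.0, 25.0),
        },
        "inhibitory": {
            "tp_latency_ms": (0.30, 0.04),
            "half_width_ms": (0.16, 0.02),
            "auc": (110.0, 15.0),
        },
    }


@dataclass
class GeneratorConfig:
    """Ground-truth settings for the synthetic cohort.

    Parameters
    ----------
    seed : master seed; identical (seed, config) gives bit-identical tables.
    n_groups : number of 4-mouse cages.
    mice_per_group : mice per cage (round-robin pairs = C(n, 2)).
    trials_per_pair : food-competition trials per pair and session,
        half starting from each of the two starting areas.
    n_units : sorted units across the cohort.
    prop_excitatory : fraction of broad-spiking (putative excitatory) units.
    category_props : per cell type, fractions of task categories
        (competition / rank / both / non); each row sums to 1.
    quota_mode : if True category counts are exact largest-remainder
        quotas; if False they are sampled multinomially.
    base_rate_hz : baseline Poisson firing rate.
    modulation_gain : multiplicative rate gain in the analysis window on
        win trials (competition-modulated) or dominant-opponent trials
        (rank-modulated); 1.0 means no modulation.
    doublet_prob : probability that a spike of a bursty (excitatory) unit
        is followed by a 3-5 ms doublet spike.
    win_temperature : tau of the logistic (Bradley-Terry) win model
        p = 1 / (1 + exp(-(c_i - c_j) / tau)).
    competitiveness : latent per-mouse scores within a group (descending
        means more dominant); length mice_per_group.
    n_days : length of the longitudinal window (days).
    intervention_day : day index at which the intervention starts (day 0).
    rank_lag_days : onset delay of the rank-related firing change relative
        to the competition-related change.
    intervention_effect : 0..1 scale of the intervention effect
        (0 = null, all longitudinal series flat in expectation).
    ramp_days : days over which an onset ramps from 0 to full effect.
    tube_time_stable_day : day from which tube ranks are noise-free and
        bout durations drop to the stable (short) regime.
    tube_noise : pre-stabilization probability scale of upset outcomes.
    ws_noise : SD of latent-score jitter in warm-spot occupancy.
    trials_per_day : pooled per-trial rate samples per day entering the
        longitudinal tables (units x trials across the recorded cohort).
    recorded_index : index (by descending competitiveness) of the
        implanted mouse in each group; 1 = mid-ranked.
    sampling_rate_hz : waveform sampling rate.
    waveform_ms : length of the synthesized averaged waveform.
    """

    seed: int = 0
    n_groups: int = 6
    mice_per_group: int = 4
    trials_per_pair: int = 10
    n_units: int = 379
    prop_excitatory: float = 288 / 379
    category_props: dict = field(default_factory=_default_category_props)
    quota_mode: bool = True
    base_rate_hz: float = 5.0
    modulation_gain: float = 2.0
    waveform_params: dict = field(default_factory=_default_waveform_params)
    doublet_prob: float = 0.35
    win_temperature: float = 0.7
    competitiveness: Sequence[float] | None = None
    n_days: int = 21
    intervention_day: int = 0
    rank_lag_days: int = 10
    intervention_effect: float = 1.0
    ramp_days: int = 5
    tube_time_stable_day: int = 5
    tube_noise: float = 0.3
    ws_noise: float = 0.1
    trials_per_day: int = 2880
    recorded_index: int = 1
    sampling_rate_hz: float = 40000.0
    waveform_ms: float = 2.5

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")
        if self.n_groups <= 0 or self.mice_per_group < 2:
            raise ValueError("need at least one group of >= 2 mice")
        if not 0.0 <= self.prop_excitatory <= 1.0:
            raise ValueError("prop_excitatory must be in [0, 1]")
        if self.base_rate_hz <= 0:
            raise ValueError("base_rate_hz must be positive")
        if self.modulation_gain < 1.0:
            raise ValueError("modulation_gain must be >= 1")
        if not 0.0 <= self.doublet_prob <= 1.0:
            raise ValueError("doublet_prob must be in [0, 1]")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0 <= self.intervention_day < self.n_days:
            raise ValueError("intervention_day must lie in [0, n_days)")
        if self.rank_lag_days >= self.n_days:
            raise ValueError("rank_lag_days must be smaller than n_days")
        for cell_type, props in self.category_props.items():
            if cell_type not in CELL_TYPES:
                raise ValueError(f"unknown cell type {cell_type!r}")
            total = 0.0
            for cat in TASK_CATEGORIES:
                p = props[cat]
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{cell_type}/{cat} fraction outside [0, 1]")
                total += p
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"category_props[{cell_type!r}] must sum to 1")
        for cell_type, feats in self.waveform_params.items():
            for name, (mean, sd) in feats.items():
                if mean <= 0 or sd <= 0:
                    raise ValueError(
                        f"waveform_params[{cell_type!r}][{name!r}] must have "
                        "positive mean and SD"
                    )
        if self.competitiveness is not None:
            if len(self.competitiveness) != self.mice_per_group:
                raise ValueError(
                    "competitiveness must list one score per mouse in a group"
                )

    def group_competitiveness(self) -> list[float]:
        """Latent scores for one group, most dominant first."""
        if self.competitiveness is not None:
            return list(self.competitiveness)
        n = self.mice_per_group
        # evenly spaced, symmetric around zero
        return [((n - 1) / 2 - k) for k in range(n)]


@dataclass
class AnalysisConfig:
    """Settings for the unit-typing / categorization / lag analyses."""

    alpha: float = 0.05
    window_anchor: str = "t_reach_rz_s"
    window_start_s: float = -2.0
    window_end_s: float = 2.0
    bin_ms: float = 1.0
    max_lag_ms: float = 300.0
    min_trials: int = 5
    test: str = "mannwhitney"  # or "welch"
    kmeans_n_init: int = 50
    max_lag_days: int = 15
    n_perm: int = 1000
    stability_window: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.window_end_s <= self.window_start_s:
            raise ValueError("analysis window must have positive length")
        if self.test not in ("mannwhitney", "welch"):
            raise ValueError("test must be 'mannwhitney' or 'welch'")


@dataclass
class RunConfig:
    """Top-level pipeline configuration (YAML-loadable)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "comprank_out"

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {"generator", "analysis", "out_dir"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        gen = _build_section(GeneratorConfig, data.get("generator", {}))
        ana = _build_section(AnalysisConfig, data.get("analysis", {}))
        return cls(generator=gen, analysis=ana, out_dir=data.get("out_dir", "comprank_out"))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("run configuration must be a mapping")
        return cls.from_mapping(data)


def _build_section(cls, data: Mapping[str, Any]):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)
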