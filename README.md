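# comprank

Dominance-hierarchy scoring and prefrontal spike-train analysis for
social-competition experiments in group-housed mice.

In a typical experiment, four co-housed mice are ranked with daily
round-robin tube tests, their competitive ability is measured in a
pairwise food-competition race (two mice released together race from a
starting area to a reward zone holding one pellet; pellet consumption
defines the win) and a warm-spot territory assay, and single units are
recorded in the prelimbic cortex (PL) of an implanted animal during the
races. `comprank` implements the desk-scale analysis chain for such a
study:

- **behavior** — daily tube ranks with a linearity check, detection of
  the stable linear hierarchy (identical linear ranks on ≥ 3 consecutive
  days), the change point where mean tube-bout time settles, stage-wise
  winning proportions (exiting SA / reaching RZ / pellet), the C1..CN
  competitive order (pellet proportion, latency tie-break), training
  criterion (< 5 s mean latency on two consecutive days), warm-spot
  occupancy order, and the Spearman correlation between competitive
  order and tube rank.
- **ephys** — averaged-waveform features (trough-to-peak latency,
  trough half-width, AUC), excitatory/inhibitory typing by 2-means
  clustering in the standardized 3-D feature space (narrow-spiking
  cluster = putative inhibitory), an autocorrelogram **burst index**
  (mean count at 3–5 ms lags / mean count at 200–300 ms lags) with a
  bimodality validation, per-trial firing rates around reward-zone
  entry, task categorization (competition- / rank- / both- / non-related
  by two-sided Mann–Whitney contrasts on win–loss and
  dominant–subordinate-opponent trials), population summaries, daily
  Δz-score series, and the stated mEPSC accept/reject filter
  (amplitude > 5 pA, rise ≥ 0.3 pA/ms, decay τ 1–12 ms).
- **crosscorr** — lagged Pearson cross-correlation between day series
  (e.g. population Δz vs winning proportion) with a circular-shift
  permutation significance band; positive lag means the second series
  lags the first.
- **synthetic** — a cohort generator with known ground truth (logistic
  Bradley–Terry contests, quota-exact unit populations, inhomogeneous
  Poisson spike trains with doublet bursting, 21-day intervention series
  with a configurable rank-change lag) so every stage has a closed-loop
  test.

The statistic at the core of the longitudinal analysis is the
cross-correlogram

    r(ℓ) = corr(x_t, y_{t+ℓ}),   ℓ = −L..L  (days),

between the daily Δz-score of a neuronal population, z_d = (mean_d −
mean_0)/SD_0 referenced to the pre-intervention baseline day, and a
behavioral day series. Its peak lag estimates how long behavioral change
trails (or leads) the change in neuronal encoding — the operational
signature of the winner–loser effect, where continuing competitive
outcomes precede the re-establishment of social rank.

## Worked example

A cohort whose composition matches a recorded PL population (379 units;
288 broad-spiking / 91 narrow-spiking; task-category quotas per type):

```python
import pandas as pd
from comprank import synthetic as syn
from comprank.ephys import CellTypeClassifier, classify_task_related, trial_firing_rates

cfg = syn.reference_cohort_config(seed=1)
units, truth = syn.generate_unit_population(cfg)

clf = CellTypeClassifier(random_state=0).fit(units[["tp_latency_ms", "half_width_ms", "auc"]])
print(pd.Series(clf.cell_types_).value_counts().to_dict())
# {'excitatory': 288, 'inhibitory': 91}

trials = pd.concat(
    [syn.generate_competition_session(cfg, f"g{g}") for g in range(cfg.n_groups)],
    ignore_index=True,
)
spikes = syn.generate_spike_trains(cfg, trials, truth, units)
frames = []
for g in range(cfg.n_groups):
    gid = f"g{g}"
    uids = set(units.loc[units.group_id == gid, "unit_id"])
    subj = trials[(trials.group_id == gid) & (trials.subject_id == syn.implanted_mouse(cfg, gid))]
    frames.append(trial_firing_rates(spikes[spikes.unit_id.isin(uids)], subj))
cats = classify_task_related(pd.concat(frames, ignore_index=True), alpha=0.05)
print(cats["category"].value_counts().to_dict())
# {'non': 200, 'competition': 104, 'rank': 44, 'both': 31}
```

The classifier recovers the configured 288/91 split exactly; the
category counts recover the quotas (98 competition-modulated, 32
rank-modulated, 20 both) up to the α = 0.05 test noise — e.g. the 104
competition-only units are the 98 true ones minus a few falsely
rank-flagged, plus α(1−α) ≈ 4.8 % of the 229 unmodulated units.

The full pipeline (simulation → behavior → ephys → cross-correlation →
report) runs from a single seed:

```
comprank run --seed 1 --out out/
```

and prints `peak lags: {'competition_dz~winning': 0,
'competition_dz~rank_dz': 10}`: behavioral winning proportion moves
with the competition-related population Δz with **no lag**, while the
rank-related population follows **10 days** later (the generator's
configured rank lag). The report also contains per-group hierarchy
stabilization days (4–5 with default settings: early rank fluctuation
decays by day 5), the tube-time inflection day (5 per group), the
C1..C4 competitive orders with their Spearman correlation against the
final tube ranks (ρ = 1.0 per group at default noise), and the
burst-index bimodality validation of the waveform classification.

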