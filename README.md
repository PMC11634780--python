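# wmintermit

Single-trial analysis of working-memory coding in simultaneously recorded
neural populations: does mnemonic information persist in spiking through a
memory delay, or does it alternate between discrete On and Off coding
states — and when firing-rate coding is off, do cue-specific patterns of
functional connectivity carry the memorandum instead?

The package is aimed at systems neuroscientists analysing delayed-response
tasks with large populations (e.g. high-density probe recordings): spike
event tables in, per-session statistics out, with a synthetic-session
generator providing ground truth for every stage.

## What it computes

For a session of a delayed spatial task (8 cue locations at 45°, 50-ms cue,
1,400–1,600-ms delay):

1. **Decoder confidence.** For every trial and 10-ms timepoint, a
   leave-one-trial-out ridge-logistic classifier discriminates the trial's
   cue location from the opposite location; the posterior assigned to the
   correct label, c(t) ∈ (0, 1), is a time-resolved index of cue
   information in population spiking.
2. **On/Off state segmentation.** The classification is repeated 50× with
   shuffled training labels; confidence is z-scored against this null, and
   runs of z > 1.96 are kept as **On** states when their cluster mass
   exceeds the 95th percentile of the shuffle-derived null cluster masses;
   runs of ≥5 timepoints below the one-sided P > 0.20 point are **Off**
   states.
3. **One state or two.** Delay confidence is fit with a single beta
   density p(c) = Beta(c; α, β) versus a two-component mixture
   w·Beta(c; α, β) + (1−w)·Beta(c; α′, β′), compared by four-fold
   cross-validated bits per trial.
4. **State-conditioned rate coding.** Split-half tuning curves (one half
   of units labels states, the other half is read out), population rate in
   baseline SDs, and per-unit cue/state/interaction variance partitioning.
5. **Functional ensembles.** Jitter-corrected cross-correlograms
   CCG(τ) = Σᵢ Σₜ xⱼ(t−τ)xₖ(t) / √(Σxⱼ · Σxₖ) per cue condition
   (25-ms jitter windows; a pair is connected when the corrected peak at
   1 ≤ |τ| ≤ 10 ms exceeds the high-lag baseline by 7 SDs), binary graphs
   per condition, and the mean Manhattan distance between condition graphs
   z-scored against full-pipeline label-permutation reruns — also
   restricted to On-only or Off-only spikes, and to firing-rate-matched
   condition groups.
6. **Controls.** Microsaccade detection (10°/s velocity-peak rule),
   LFP-phase vs state-onset permutation tests, and robust noise-SD QC.

## Worked example

```python
import wmintermit as wm

cfg = wm.SimConfig(n_units=48, n_trials_per_condition=12, seed=7)
report = wm.pipeline.run_session(cfg, n_shuffles=50, n_perm=25)
print(f"delay accuracy      {report['delay_accuracy']:.3f}")
print(f"On per trial        {report['on_mean_per_trial']:.2f} "
      f"({report['on_mean_duration_ms']:.0f} ms)")
print(f"Off per trial       {report['off_mean_per_trial']:.2f} "
      f"({report['off_mean_duration_ms']:.0f} ms)")
print(f"state recovery (BA) {report['state_balanced_accuracy']:.2f}")
print(f"two-state dBits     {report['delta_bits_per_trial']:+.2f}")
print(f"manhattan z (full)  {report['manhattan_z_full']:.2f}")
```

prints, for this seed:

```
delay accuracy      0.866
On per trial        4.45 (177 ms)
Off per trial       2.47 (99 ms)
state recovery (BA) 0.82
two-state dBits     +0.54
manhattan z (full)  4.80
```

Reading: the session decodes the remembered location at 87% across the
delay, but single trials alternate between ~4 detected On episodes
(~177 ms) and ~2 detected Off episodes (~99 ms); detected state labels
agree with the generator's ground-truth states at balanced accuracy 0.82;
the two-state beta mixture beats the single-state description by +0.54
cross-validated bits per trial; and the condition-to-condition differences
among significant-CCG graphs exceed their label-permutation null by 4.8
SDs — the cue-specific-ensemble signature.

A thin CLI wraps the same calls:

```bash
wmintermit simulate --seed 1 --out session/          # spikes.csv, trials.csv, ground_truth.json
wmintermit run --seed 1 --out report.json --shuffles 50 --perms 25
```

## Layout

| module | role |
|---|---|
| `wmintermit.synthetic` | ground-truth session generator (spikes, eye traces, phases) |
| `wmintermit.preprocess` | boxcar rates, 1-ms rasters, unit filters, subtypes, noise SD |
| `wmintermit.decode` | LOO confidence, cross-temporal and state-restricted decoding |
| `wmintermit.states` | shuffle null, z-scoring, cluster-mass On/Off labeling |
| `wmintermit.betamix` | beta / beta-mixture fits, CV bits-per-trial comparison |
| `wmintermit.tuning` | split-half state tuning, population rates, variance partition |
| `wmintermit.ccg` | raw/jitter-corrected CCGs, 7-SD connection rule, state masking |
| `wmintermit.ensembles` | condition graphs, Manhattan permutation test, enrichment |
| `wmintermit.controls` | microsaccades, phase–state association |
| `wmintermit.pipeline` | session/cohort orchestration, JSON reports |

Methodological details, parameter defaults and their rationale, and known
limitations are documented in `docs/methods.md`.
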