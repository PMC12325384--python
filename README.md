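# lfpdecode

Layer- and band-specific decoding of tone frequency from
multielectrode-array local field potentials (LFP), built for studying how
a neuromodulatory perturbation (such as vagus nerve stimulation, VNS)
changes cortical information representation.

The package is aimed at systems/computational neuroscientists who record
sustained cortical activity with dense arrays under anesthesia and want a
tested, reproducible version of the full analysis chain:

1. **Burst screening** — under isoflurane the LFP alternates between
   high-amplitude bursts synchronized across the array and low-amplitude
   quiescence.  Epochs where the 100-ms standard deviation exceeds a
   per-site threshold at more than 24 of 96 recording sites for ≥ 150 ms
   are classified as bursting and excluded.
2. **Feature extraction** — from 1,000-ms non-burst windows (starting
   ≥ 1 s after tone onset), per band *b* ∈ {theta 4–8, alpha 8–14,
   beta 14–30, low-gamma 30–40, high-gamma 60–80 Hz}:
   band power (RMS of the band-passed signal per site) and the
   phase-locking value between every pair of sites,

   PLV(m, n) = (1/T) · | Σₜ exp( i(θₘ(t) − θₙ(t)) ) |,

   with θ the instantaneous angle from the Hilbert transform
   (C(96, 2) = 4,560 pairs on the canonical 10×10 array with offline
   corners).
3. **Decoding** — sparse multinomial logistic regression with automatic
   relevance determination decodes the tone frequency (five-choice over
   8/10/13/16/32 kHz, or two-choice stratified by frequency ratio) under
   periodic 7-fold or rolling-window cross-validation.
4. **Comparison** — per-animal post-minus-pre accuracy deltas are tested
   against zero with a two-sided *exact* Wilcoxon signed-rank test per
   (layer × band × feature-kind × task) cell.

Because raw recordings of this kind are rarely public, the package ships
a first-class **synthetic session generator** with tonotopic Gaussian
activation foci, controllable per-band phase coupling, pink-noise floor
and planted global bursts — every stage of the pipeline is validated by
recovering the generator's known ground truth.

## Worked example

```python
import lfpdecode as L
from lfpdecode.features import BANDS

grid = L.make_grid(5, 5, True)                      # 21 active sites
sched = L.TrialSchedule.make(repetitions=3, tone_duration_s=11.0,
                             gap_duration_s=2.0, seed=1)
sess = L.simulate_session(grid, sched, L.GeneratorParams(), seed=7)

mask = L.screen_session(sess)                        # burst intervals
windows = L.extract_analysis_windows(sess, mask, n_per_label=21)
table = L.build_feature_table(sess, windows, BANDS["high-gamma"], "plv")
res = L.run_task(table, L.five_choice_task(sched.tone_frequencies),
                 fit_kwargs={"max_iter": 50})

print(f"burst intervals: {len(mask.intervals)}")
print(f"feature table:   {table.X.shape[0]} windows x {table.X.shape[1]} PLV pairs")
print(f"five-choice accuracy from high-gamma PLV: {res.mean_accuracy:.1f}%")
```

prints

```
burst intervals: 7
feature table:   105 windows x 210 PLV pairs
five-choice accuracy from high-gamma PLV: 41.0%
```

meaning: seven global burst epochs were detected and excluded, 21
non-burst windows per tone frequency were converted into 210-pair PLV
patterns, and the decoder identifies the presented tone from a single
second of high-gamma phase coupling 41% of the time (chance: 20%).
Re-running after `L.apply_vns_effect(params,
L.VnsEffect(contrast_mult={"high-gamma": 0.5}))` — the ground-truth
analogue of a perturbation that degrades high-gamma tonotopy — drops
this accuracy toward chance, which is exactly the per-animal delta the
comparison stage feeds into the signed-rank test.

A full cohort run (simulate → screen → features → decode → compare,
grid written as TSV/JSON) is one call or one command:

```bash
lfpdecode run-all --config config.yaml --seed 42 --out results/
```

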