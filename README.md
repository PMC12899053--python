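# emgspecvar

Spectral-variability analysis of surface electromyography (sEMG) for
repeated isometric contractions, with a built-in synthetic-cohort
generator.

The package targets a common experimental design in neuromuscular
research: participants repeat a near-maximal isometric task (here, elbow
flexion recorded from biceps brachii, BB, and brachioradialis, BR) under
two forearm postures — supinated open hand (SP) and neutral grip (NT) —
and the question is how reproducible the *shape* of the sEMG power
spectrum is within a participant, and how much it differs between
participants.

## Method

For each two-channel recording (2 kHz, μV):

1. **Segmentation** — a reference trace is formed by summing the channels;
   contraction peaks are detected with a minimum prominence of 500 μV, a
   minimum spacing of 0.35 s, and a minimum RMS-envelope rise of 250 μV
   over the envelope minima toward neighbouring peaks; segment boundaries
   are placed at the RMS-envelope minimum between consecutive peaks.
2. **Spectra** — each segment is notch-filtered (50 Hz, Q = 35),
   zero-padded to the longest segment of its recording, Hann-tapered, and
   transformed: `P[f_m] = |X[m]|²` on `f_m = m·f_s/N`.  The raw spectrum is
   smoothed with a Moving Trend Filter (sliding third-order local
   least-squares polynomial fits over a 181-bin window, averaged), then
   normalized either by its peak (`max`) or by its bin sum (`energy`), and
   interpolated onto a common 0.5 Hz grid over 0–500 Hz.
3. **Variability** — per participant `s` and condition `c`, the repetition
   spectra are averaged into a reference `P̄_{s,c}[f_m]`.  Intra-subject
   variability is the Minkowski distance of each repetition from that
   reference, `d_{s,c}^{(i)} = (Σ_k |P̃^{(i)} − P̄|^l)^{1/l}` for
   l ∈ {1, 2, ∞}; inter-subject variability is the pairwise distance
   between participants' references.
4. **Inference** — SP vs NT distance samples are compared per muscle with
   the paired Wilcoxon signed-rank test (α = 0.05), and inter-subject
   distance distributions are fitted with Normal, Laplace and
   Maxwell–Boltzmann models by maximum likelihood, assessed with a
   chi-square goodness-of-fit test on equal-probability bins.

The synthetic generator emulates the acquisition protocol (10 × ~5 s
bursts per task, rest baseline below 5 μV, burst-gated 50 Hz
interference) with band-limited colored-noise contractions whose corner
frequencies carry participant-level random effects and repetition-level
jitter that is twice as large in NT as in SP — so the full pipeline can
be validated against known ground truth.

## Worked example

```python
import emgspecvar as ev

params = ev.CohortParams(n_participants=8, seed=7)
model = ev.SpectralVariability.from_synthetic(
    params, orders=(2,), normalizations=("max",))
results = model.fit()
print(results.intra_summary.query("muscle == 'BB'").to_string(index=False))
print(results.posture_tests.to_string(index=False))
```

prints

```
order muscle posture norm     mean      std       cv      min      max  n
    2     BB      NT  max 2.207741 0.423380 0.191771 1.408310 3.308282 80
    2     BB      SP  max 2.000242 0.311299 0.155631 1.312782 2.836027 80

level muscle order norm  statistic  p_value  n_pairs method
intra     BB     2  max        4.0 0.054688        8  exact
intra     BR     2  max        9.0 0.250000        8  exact
inter     BB     2  max      295.0 0.037198       28 approx
inter     BR     2  max      270.0 0.129950       28 approx
```

The intra-subject table lists the pooled repetition-to-reference L2
distances (80 = 8 participants × 10 repetitions): the NT posture shows a
~10% larger mean spectral distance than SP, i.e. repetitions reproduce
the spectrum less consistently in the neutral grip.  The Wilcoxon rows
test that SP–NT difference pairwise (by participant for the intra level,
by participant pair for the inter level); at n = 8 participants the
intra-level biceps effect is borderline (p ≈ 0.055) — at the study's
n = 33 it is reliably significant.

`results.save(out_dir)` writes the segment index, distance tables,
summaries, test results, distribution fits, reference spectra and a JSON
manifest; `emgspecvar.plotting` has diagnostic plots (reference spectra,
intra-distance boxplots, inter-distance histograms with fitted models).

The same analysis runs from the shell:

```sh
emg-specvar synth --config cohort.yml --out data/ --seed 1
emg-specvar run --input-dir data/ --out results/     # or synthetic mode:
emg-specvar run --config cohort.yml --out results/ --seed 1
```

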