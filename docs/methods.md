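# Methods

This note records the models, parameter choices and numerical decisions
behind `emgspecvar`, and what the synthetic validation does and does not
establish about real recordings.

## Signal model of the synthetic cohort

Each contraction burst is zero-mean Gaussian noise colored in the
frequency domain by `sqrt(G(f))`, where

    G(f) = f_h² f² / ((f² + f_l²)(f² + f_h²)²)

is a rational band-pass shape: zero at DC, a single interior maximum, and
monotone decay at high frequency — the standard way to mimic the
low-frequency-dominated, gradually declining sEMG power spectrum with two
interpretable corner frequencies `(f_l, f_h)`.  Coloring is done by
multiplying the FFT of white noise by `sqrt(G)` and inverse-transforming,
which avoids IIR filter-design edge cases and makes the expected
periodogram exactly proportional to `G`.  A trapezoidal envelope (10%
rise, 80% plateau, 10% fall) shapes each burst so that onset/offset are
gradual enough for envelope-based boundary refinement to be meaningful;
the plateau RMS is rescaled exactly to `burst_rms_uv`.

Corner-frequency hierarchy per muscle × posture:

    realized (f_l, f_h) = posture mean + participant effect + repetition jitter

with participant effects drawn once per participant (Normal, SD
`subject_sd`, shared across tasks) and repetition jitter drawn per burst
(Normal, SD `rep_jitter_sd[task]`).  Corners are clipped to stay valid
(`f_l ≥ 5 Hz`, `f_h ≥ f_l + 10 Hz`, below Nyquist).

### Default parameters and how they were set

| parameter | default | rationale |
|---|---|---|
| `fs` | 2000 Hz | acquisition rate of the emulated system |
| `n_repetitions` | 10 | protocol repetition count |
| `burst_duration_s` | 5 s | protocol contraction duration |
| `rest_duration_s` | 2 s | "short rest"; comfortably above the 0.35 s peak-spacing floor |
| corner means | BB 60/120, BR 70/140 Hz; NT +5 Hz | places both muscles' spectra in the sEMG band with distinguishable conditions |
| `burst_rms_uv` | 400 μV | summed-channel contractions clear the 500 μV prominence threshold by a wide margin |
| `baseline_amp_uv` | 5 μV | the acquisition quality criterion (baseline below 5 μV) |
| `line_amp_uv` | 20 μV | visible 50 Hz contamination for the notch stage to remove |
| `rep_jitter_sd` | SP 5 Hz, NT 10 Hz | calibrated so the NT/SP intra-distance ratio (~1.06) matches the reported effect size; NT = 2 × SP is the built-in posture contrast |
| `subject_sd` | 15 Hz | calibrated so inter-subject distances dominate repetition noise (inter/intra distance ratio above 1), as in the reported summary tables |

The two calibrated SDs deserve comment.  A single-contraction
periodogram is a noisy estimator, and after smoothing it still carries a
stochastic repetition-to-repetition component.  Corner jitter of only a
few Hz is invisible underneath that estimator noise; jitter SDs of
5/10 Hz place the deterministic shape variability and the estimator
noise at the relative magnitudes implied by the published summary
statistics (mean intra-distance ratio NT/SP ≈ 1.07, inter/intra ≳ 1).
Between-subject mean-frequency spreads of 10–20 Hz are physiologically
ordinary for these muscles.

The 50 Hz interference term is gated by the contraction envelope: it is
present during bursts (where the notch filter must remove it) and absent
at rest.  This keeps the generator's hard guarantee that rest-interval
amplitudes never exceed `baseline_amp_uv`, mirroring an acquisition
chain whose hardware suppression keeps the measured baseline below 5 μV.

Randomness: per-recording generators are seeded by
`(seed, participant index, task index)` and participant effects by
`(seed, participant index, 2)`, so enlarging the cohort never perturbs
previously generated recordings, and a cohort is bit-reproducible from
`CohortParams` alone.

### What the generator does not emulate

No motor-unit physiology (no MUAP trains, recruitment, firing-rate or
fatigue dynamics), no force output, no electrode-placement or crosstalk
modeling, no non-stationarity within a contraction, and Gaussian
amplitude statistics rather than the super-Gaussian/Laplacian amplitude
densities real sEMG can show.  Consequently, passing pipeline tests on
synthetic cohorts establishes that the *processing chain* recovers known
spectral structure and effect directions — not that real elbow-flexor
data behave like the generator.

## Segmentation

Peaks are detected on the raw summed trace with SciPy's prominence and
spacing rules (ties on spacing resolved toward the taller peak).  The
neighbour-amplitude rule is evaluated on the centred RMS envelope
(window `rms_window_s` = 0.1 s, shrunk at the edges): two adjacent
candidates are distinct contractions only when the envelope valley
between them falls to or below `neighbor_delta_uv` **and** sits at least
`neighbor_delta_uv` below the envelope at both peaks; otherwise the
weaker candidate is merged away.  The absolute-valley clause is what
separates contractions robustly: at default amplitudes the envelope
valley between two true contractions is < 5 μV while within a
contraction plateau it never leaves the ~350–800 μV range, so the margin
on both sides of the 250 μV threshold is two orders of magnitude.  A
pure peak-vs-valley difference rule has no such margin, because the
envelope evaluated *at* raw-trace maxima sits systematically above the
plateau mean.  Every retained peak still exceeds both adjacent
inter-peak envelope minima by at least `neighbor_delta_uv`.

Boundaries are the envelope argmin strictly between consecutive peaks
(first index on ties); the first segment starts at sample 0 and the last
ends at the recording end, so the segments partition the recording.
Trailing rest inside a segment is harmless downstream: the Hann taper
and zero-padding make the segment's spectral content
contraction-dominated.

Defaults `neighbor_delta_uv` = 250 μV (half the prominence floor) and
`rms_window_s` = 0.1 s (standard sEMG envelope scale) are configurable.

## Spectral processing

Order of operations: notch → zero-pad → Hann → FFT → MTF → normalize →
regrid.  The Hann taper is applied to the *zero-padded* segment.  The
notch (second-order IIR, `f0/Q` bandwidth) is applied forward-backward,
doubling stop-band attenuation and halving the transition band at zero
phase.

The Moving Trend Filter: within every length-`M` window covering bin
`n`, an order-`p` polynomial is fitted by least squares on the
normalized coordinate `u ∈ [−1, 1]` and evaluated at `n`; the smoothed
value is the mean of those evaluations.  `M = 2K+1` with `K` = half the
configured span (span 180 → `M` = 181), `p` = 3.  Since fit-and-evaluate
is a fixed projection, the averaged smoother collapses to a convolution
whose kernel is the diagonal average of the projection matrix; the
`M−1` bins at each end average explicitly over their admissible
full-length windows (every bin has at least one once the spectrum is
longer than `M`).  This fast path is exact — tests pin it to a literal
double-loop implementation at 1e−9 — and reproduces any cubic input
identically.  Negative smoothed values are clipped to zero except where
linearity itself is being tested.

Normalization divides by the peak (`max`) or the bin sum (`energy`)
over the analysis band (0–500 Hz default).  Because segment lengths —
and hence native frequency grids — differ between recordings, distances
are computed on a common uniform grid (0.5 Hz default) reached by linear
interpolation, the least-assumptive bridge; the normalization is then
re-applied so its invariant holds exactly on the common grid.  The grid
never extends past the shortest source grid.

## Distances and summaries

Minkowski orders 1, 2 and ∞ are computed binwise on the common grid.
Reference spectra are plain arithmetic means over repetitions (the 1/10
of the ten-repetition protocol generalizes to 1/n).  Summary tables
(mean, STD, CV, min, max) use the sample (n−1) standard deviation and
pool repetitions across participants; CV is undefined (NaN) at zero
mean.  Inter-subject tables cover all n(n−1)/2 participant pairs.

## Inference

Wilcoxon signed-rank, two-sided: zero differences discarded, midranks
for ties, exact null for n ≤ 25 without tied |differences| (verified
against full 2ⁿ sign enumeration), otherwise the normal approximation
with continuity and tie corrections.  Pairing units: participant for the
intra level (each participant's mean repetition distance; a pooled
per-repetition pairing is available via `aggregation="pooled"`), and
participant pair for the inter level.  All-zero differences yield the
degenerate p = 1 rather than an error.  No multiple-testing correction
is applied.

Distribution fits use closed-form MLEs — Normal `(x̄, s_n)`, Laplace
`(median, mean |x − median|)`, Maxwell–Boltzmann `a = sqrt(mean(x²)/3)`
(density ∝ x² exp(−x²/2a²)) — and a chi-square test on equal-probability
bins (`n_bins = max(5, ⌊n/10⌋)`, reduced so every expected count is
≥ 5; `df = n_bins − 1 − n_params`), which is more stable than
equal-width binning for skewed positive samples.  Fits require ≥ 25
observations; with the default cohort that means at least 8
participants.

A caveat the tests reflect: pipeline inter-subject distances are built
from all pairs of a cohort, so the sample fed to the chi-square test is
*dependent*, and with two-dimensional corner-frequency subject effects
their distribution is more sharply skewed than a Maxwell law.  On
synthetic cohorts the qualitative pattern — the symmetric Normal model
consistently rejected, Maxwell–Boltzmann the best-fitting and most often
accepted family — is reproduced; outright Maxwell acceptance in every
condition is not, and should not be expected from this generator
geometry.

## Problem sizes used in validation

Unit tests run on reduced cohorts (2–6 participants, 3–4 repetitions,
1.5–2 s bursts) chosen so the whole suite stays interactive; the
acceptance-level checks use the protocol scale where the property
demands it (20 single-recording seeds for segmentation recovery, a
33-participant cohort for the baseline bound, and twenty 33-participant
cohorts for the NT > SP effect, restricted to L2/peak-normalization).
The end-to-end reproduction of the published human-data tables needs the
archived recordings placed under `data/deposited/` and is reported as a
failure with instructions when they are absent.

## Known limitations

- The spectral generator produces stationary bursts; real contractions
  drift spectrally with fatigue even over 5 s.
- The line-interference model is a constant-amplitude, burst-gated
  50 Hz tone; real mains contamination fluctuates and includes
  harmonics.
- The chi-square test inherits the pair-dependence bias discussed above;
  a block bootstrap over participants would be the principled
  alternative and is out of scope here.
- Segmentation assumes approximate phase synchrony of the two channels
  (summing must not cancel contractions); strongly anti-phase channels
  would need a different reference trace.
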