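# Methods

## The problem

In reflectance photoplethysmography (PPG) the detected light intensity
normally *falls* during systole. Occasionally — particularly when
measuring over a superficial artery such as the dorsalis pedis — the
intensity rises instead, producing an *inverted* pulse whose shape tracks
the arterial blood pressure (ABP) wave. Inversion distorts fiducial-point
extraction (pulse onset, dicrotic notch, maximum-derivative points) and
therefore pulse-wave-analysis and pulse-transit-time applications. This
package quantifies how often and how strongly inversion occurs in a
recording, and aggregates occurrence over a measurement protocol that
varies sensor position relative to the artery, contact pressure, and LED
wavelength.

## Pipeline

Each raw channel is processed by three linear stages:

1. **Negation.** The raw signal is sign-flipped so a non-inverted pulse
   points upward like an ABP wave; an inverted pulse then points downward.
2. **Zero-phase high-pass.** Minimum-order Chebyshev-II design with
   passband edge 0.1 Hz, stopband edge 0.05 Hz and composite stopband
   attenuation ≥ 60 dB, applied forward–backward (`sosfiltfilt`). Zero
   phase preserves fiducial timing; the measured composite response is
   −65 dB at 0.01 Hz, −61 dB at 0.05 Hz, −0.4 dB at 0.1 Hz and flat
   (±0.01 dB) from 0.3 to 2 Hz. The design halves the dB specifications
   per pass because the forward–backward application squares the
   magnitude response.
3. **Savitzky–Golay smoothing**, polynomial order 20, frame 999 samples
   (1.25 s at 800 Hz). At this order/frame the textbook monomial
   formulation is numerically singular (the Vandermonde normal equations
   lose all significance in double precision), so the smoother is
   implemented as a least-squares projection on a Legendre basis over the
   frame scaled to [−1, 1]; it reproduces degree-20 polynomials to ~1e−15
   and has unit DC gain. Its measured response is −1.1 dB at 5 Hz and
   −19 dB at 10 Hz, so the *composite* chain is flat only up to roughly
   2 Hz — a property of the stated frame/order, retained deliberately.
   Edges use polynomial-interpolation mode: the first/last half-frame is
   the polynomial fitted to the leading/trailing full frame, so no margins
   are discarded.

All stages are linear and odd, giving the exact identity
`prepare(−x) = −prepare(x)` that the negation-duality tests assert
bit-for-bit.

## Two-layer classifier

**Candidates.** Every strict interior local extremum of the prepared
series is a pulse candidate marking a possible end of systole; plateaus
(runs of equal samples flanked by lower/higher runs) contribute one
candidate at the run midpoint. Candidates within 240 samples of either
end are dropped (their analysis windows would truncate). For series
produced by `prepare`, candidates inside the smoother's edge-fit regions
(half a frame, 499 samples, at each end) are also dropped: edge-fit
samples have inflated variance, and on a flat diastolic tail the fit's
wiggles otherwise become spurious verified troughs. Raw series analyzed
directly keep the plain 240-sample margin.

**Dominance verification.** A peak candidate is removed if any sample
within ±150 samples exceeds it; a trough if any sample is lower. Ties do
not disqualify (strict comparison), and the window is read as symmetric
— ±150 samples each side, the conservative reading of a "nearest 150
samples" rule. Windows clip at series boundaries.

**Symmetry layer.** Let `m_pre`/`m_post` be the mean absolute first
difference over the 240 samples (~0.3 s) before/after the candidate. The
candidate passes iff `m_pre > m_post` strictly: the systolic deflection
is the steepest limb of a pulse, so a genuine end-of-systole extremum is
approached more steeply than it is left. A tie fails — a symmetric
candidate carries no systole/diastole evidence. Passing peaks are
labelled `a_i = +1` (non-inverted), passing troughs `a_i = −1`
(inverted).

**Triangulation layer.** Each dominance-verified candidate is joined to
its nearest strict non-candidate local extrema of the same kind on each
side (dicrotic waves, ripples), and the cosine of the vertex angle at the
candidate is computed by the law of cosines. Coordinates are time in
*seconds* and per-series z-scored intensity, making the angle
dimensionless, gain-invariant and translation-invariant. Sample-unit time
was considered and rejected: with Δx ≈ 240 samples against z-scored
Δy ≈ 1.5, every vertex collapses to ≈180° (cos ≈ −0.9996 for sharp and
blunt vertices alike); in seconds a sharp systolic apex is acute
(cos ≈ +0.97) and a blunt inter-beat trough is not (cos ≈ +0.5), matching
the acute-positive / obtuse-negative convention the sharpness criterion
is stated in. The recording-level phase is `inverted` when the mean
cosine over troughs exceeds that over peaks, `non-inverted` for the
converse, and `indeterminate` when either kind has no computable angle
(e.g. a signal with no intermediate fiducial points) — in which case only
the symmetry layer is evaluated. Triangulation is applied to all
dominance-verified candidates, not only symmetry-passing ones; otherwise
a clean recording would retain only one extremum kind and the layer-two
cross-check would be vacuous.

The layers are compared but never reconciled automatically: a
disagreement raises a flag that is carried into every output, and
exclusion is a user decision (config/CLI exclusion list). The symmetry
phase is the primary estimate.

## Statistics

For one recording with `N` symmetry-passing pulses:

- `µ_inversion = (1/N) Σ a_i` ∈ [−1, 1]; +1 is consistently
  non-inverted, −1 consistently inverted, near 0 mixed or noisy.
- degree of inversion `DOI = (1 − µ)/2` ∈ [0, 1].
- binary classification: *inverted* iff `DOI > 0.25` (strict). The
  threshold is configurable; 0.25 is the pipeline default.
- noise flag: `|µ| < 0.3`. Inconsistent (noise-dominated) pulse labels
  drive the *mean label* toward 0 (DOI toward 0.5), so the screen is
  applied to |µ|, the only self-consistent reading of a "close to zero
  inversion estimate" rule; whether the original screen was on µ or DOI
  is ambiguous, and this choice is deliberate.
- `N = 0` leaves µ and DOI undefined and marks the recording excluded —
  never imputed.

For a configuration cell (position × pressure × LED): occurrence of
inversion `OOI = (1/N_rec) Σ b_j` with `b_j = 1` iff recording *j*'s
DOI > 0.25, where `N_rec` counts only analyzable (non-excluded)
recordings. Empty cells are reported missing, not zero. Marginal
summaries average *cell* OOI values (per-LED over pressures, per-pressure
over LEDs, grand mean/median over both); the per-subject summary is each
participant's inverted fraction over all their analyzable recordings.
With complete data the grand mean equals the mean of the per-LED
marginals (equal cell counts); with exclusions the marginals are
unweighted means of the surviving cells.

## Synthetic generator

The generator emulates the study protocol: 90 s four-channel recordings
at 800 Hz over a grid of 12 participants × 11 positions (−5…+5 mm) × 3
contact pressures, i.e. 1 584 channel-recordings. Each beat is an
ABP-like template in raw sensor convention (a normal beat *dips* at
systole, so preprocessing's negation is exercised):

- half-cosine upstroke over `systolic_rise_fraction` = 0.15 of the beat
  (≈0.12 s at 60 bpm — a physiologic systolic rise time);
- exponential diastolic decay with time constant 0.18 of the beat;
- Gaussian dicrotic wave, relative height 0.2, centred at 0.45 of the
  beat, width 0.05 — enough to give the triangulation layer its
  non-candidate neighbour extrema, as real dicrotic activity does;
- a closing ramp so every beat starts and ends exactly at baseline; the
  beat schedule is adjusted so the final beat completes exactly at the
  recording end (a truncated last beat otherwise leaves a mid-decay cut
  whose edge shape produces a spurious label).

Beat periods are jittered (SD 3% of the period, clipped to ±30%).
Inversion is per-beat, never mid-beat: a contiguous block of
`round(f·N_beats)` beats (`block` pattern, emulating partly inverted
recordings) or independent Bernoulli draws (`random`). Additive white
noise (default SD 2% of pulse amplitude), sinusoidal baseline wander
(default amplitude equal to the pulse, period 30 s — inside the high-pass
stopband), optional transient motion artifacts, a DC offset of 5×10⁴
counts, and per-LED gains (ir 1.0, red 0.8, green 0.5, blue 0.4)
complete the raw signal. Identical seeds reproduce identical bytes.

Study metadata (contact force per pressure level, skin and room
temperature) is drawn uniformly within the ranges observed across the
twelve participants of the reference protocol table shipped with the
package.

What the generator does **not** model: optical tissue physics,
wavelength-dependent penetration, venous pulsation, respiratory
modulation of pulse amplitude, sub-beat morphing between polarities, or
realistic artifact morphology. Passing tests therefore demonstrate the
algorithm's correctness on morphologically faithful but idealised
signals; they do not certify the real-data accuracy figures, which
require the original recordings.

## Verification at scale

The acceptance suite runs the full pipeline on 200 seeded 90 s recordings
(60 bpm, noise SD 2% of amplitude, block inversion) with per-recording
inverted fractions cycling the grid 0.0, 0.1, …, 1.0 — recordings that
are distinctly normal, partly inverted, or fully inverted, as observed in
practice; the grid keeps the ground-truth binary class well separated
from the 0.25 decision threshold, which recordings generated arbitrarily
close to the cutoff could not guarantee for any finite-accuracy
estimator. Requirements: |DOI − true fraction| ≤ 0.05 per recording and
100% correct binary classification (typical DOI error is ≤ 0.02, from at
most one boundary beat whose candidate falls inside a dropped margin).
Negation duality is asserted exactly on 50 seeded recordings; candidate
gathering + dominance is compared against an independent exhaustive scan
on 100 random series (length ≤ 2 000, including tie/plateau-rich
quantised series). Shorter recordings (5–30 s) are used in unit tests
where the property under test is length-independent.

## Numerical and degenerate-input choices

- Non-finite samples are rejected (naming the first offending index),
  never imputed — imputation would silently alter pulse shape.
- A constant series cannot be z-scored and raises; constant and monotone
  series legitimately yield zero candidates, which propagates to an
  excluded recording rather than an error.
- `cos θ` is clipped to [−1, 1] against floating-point overshoot.
- The high-pass design is cached per parameter set; filter application
  requires the series to exceed the forward–backward padding length and
  raises a too-short error otherwise, as does smoothing on series shorter
  than one frame.
- OOI is stored as a fraction everywhere and rendered as a percentage
  only at the reporting boundary, avoiding double-scaling.

## Known limitations

- The triangulation cosine separates sharp from blunt vertices reliably
  on clean morphology, but its absolute value depends on the time/
  intensity scaling convention; only the peak-vs-trough *ordering* should
  be interpreted.
- On mixed recordings (fractions near 0.5) the two layers can disagree
  legitimately; the disagreement flag marks these for review, and |µ|
  near zero additionally raises the noise flag even for genuinely
  part-inverted clean signals — the flags are screens, not verdicts.
- The 0.25 classification threshold is an empirical convention; moving it
  changes OOI directly.
- Very high heart rates (beat period approaching the 2×240-sample
  analysis window at 800 Hz, i.e. >100 bpm) shrink the margin between
  pulses and window sizes; windows are protocol parameters and should be
  rescaled for other sampling rates.
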