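# ppginv

Detection and quantification of **photoplethysmographic (PPG) signal
inversion** — the anomaly in which reflected light intensity *rises*
instead of falling during systole, flipping the pulse waveform relative
to the expected reflectance-PPG shape. Inversion matters for anyone
extracting fiducial points from peripheral PPG (pulse wave analysis,
pulse transit time, cuffless blood pressure): an inverted or partly
inverted signal silently corrupts those features.

`ppginv` provides, as a Python library with a thin CLI:

- **Preprocessing** — negation to arterial-blood-pressure orientation, a
  zero-phase high-pass (passband 0.1 Hz, ≥ 60 dB stopband) and
  Savitzky–Golay smoothing (order 20, frame 999) for noise suppression.
- **A two-layer per-pulse classifier.** Layer 1 gathers peak/trough pulse
  candidates, verifies each against its nearest ±150 samples, and applies
  a systole/diastole symmetry criterion (mean |first difference| over
  240 samples before vs after the reference point). Layer 2 triangulates
  each candidate with neighbouring non-candidate extrema and scores
  sharpness by the law-of-cosines vertex angle. Disagreement between the
  layers is flagged, never auto-resolved.
- **Inversion statistics.** Per recording: the mean pulse label
  µ_inversion = (1/N) Σ aᵢ with aᵢ = +1 (non-inverted pulse) or −1
  (inverted), the degree of inversion DOI = (1 − µ)/2 ∈ [0, 1], and a
  binary classification at DOI > 0.25. Per protocol cell
  (position × pressure × LED): the occurrence of inversion
  OOI = fraction of analyzable recordings classified inverted, with
  per-LED, per-pressure, per-subject and grand-mean marginals.
- **A synthetic multi-wavelength PPG generator** with per-beat inversion
  ground truth, noise, baseline wander, artifacts and the full
  12-participant × 11-position × 3-pressure × 4-LED protocol grid, so
  every stage is testable without access to clinical recordings.

## Worked example

```python
from ppginv import SimulationPlan, estimate_inversion, generate_recording, prepare

plan = SimulationPlan(seed=42, fraction_inverted=0.4, inversion_pattern="block")
recording, truth = generate_recording(plan)       # 90 s, 800 Hz, 4 LEDs
estimate = estimate_inversion(prepare(recording, "ir"))
print(truth.fraction_inverted("ir"), estimate.n_pulses,
      round(estimate.mu_inversion, 3), round(estimate.doi, 3))
```

prints

```
0.4 89 0.191 0.404
```

A contiguous 40% block of the 90 generated beats was inverted; the
classifier recovers 89 pulses with mean label +0.191, i.e. a degree of
inversion of 0.404 against a ground truth of 0.400. Because DOI > 0.25
this recording counts as significantly inverted in occurrence statistics;
because |µ| < 0.3 it also carries the noise flag that marks mixed or
noisy recordings for review. The scripts in `examples/` extend this to a
planted protocol grid with OOI aggregation and to the preprocessing
filter's measured frequency response.

The same pipeline is available from the shell:

```sh
ppginv simulate --seed 5 --out-dir recs --participants 2 --fraction-inverted 1.0
ppginv analyze recs/*.csv --out estimates.csv
ppginv aggregate estimates.csv --out-dir aggregated
ppginv report aggregated
```

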