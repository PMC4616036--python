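# crocvoice

Juvenile crocodilians call when they are seized, and those distress calls
carry information about the caller's body size: larger animals produce
lower-pitched calls with energy shifted toward lower frequencies, and
mothers respond more readily to the calls of smaller young.  `crocvoice`
is a Python package for the full analysis chain behind that kind of study:

- **Acoustic features** — 13 descriptors per call: five pitch summaries
  (start, max, min, mean, end F0, from an autocorrelation pitch tracker
  with deterministic octave-jump repair) and eight spectral-shape
  descriptors of the 0–5 kHz averaged magnitude spectrum (mode, Q25, Q75,
  IQR, centroid, skewness, kurtosis, spectral flatness).
- **Acoustic space and size coding** — correlation-matrix PCA of the 13
  standardized descriptors into two Acoustic Dimensions (AD1 ≈ spectral
  energy distribution, AD2 ≈ pitch), followed by mixed-model
  likelihood-ratio tests (fixed effects: body length, species, their
  interaction; random effect: individual identity) and per-species
  allometric regressions with slope/intercept comparison.
- **Stimulus synthesis** — frequency-modulated pure tones defined by
  start/mean/end pitch anchors.  The contour peak solves in closed form,
  `f_peak = 2 f_mean − p f_start − (1−p) f_end` for a rise–fall contour
  peaking at fraction `p` of the call; harmonic-stack call mimics and
  jittered playback series are built on top.
- **Synthetic call populations** — a seeded generator calibrated to
  published per-size-class call statistics for five crocodilian species
  (shared negative slopes of pitch and centroid on body length,
  species-specific intercepts, individual- and call-level noise), standing
  in for recordings that were never deposited.
- **Playback analysis** — the ordinal −2..+2 field response scale, a PCA
  composite of captive response criteria, crossed-random-effects tests of
  stimulus category, and Tukey-style single-step pairwise comparisons.

## Worked example

```python
from crocvoice import (
    PopulationConfig, analytic_features, correct_octave_jumps, design_contour,
    extract_f0_contour, fit_acoustic_space, generate_dataset,
    summarize_contour, synth_fm_tone, test_size_effect,
)

# a high-pitched FM stimulus from its printed anchors, and its round trip
spec = design_contour(630, 638, 350, duration=0.16, peak_time_fraction=0.25)
print(f"designed peak: {spec.f_peak:.0f} Hz")
wav = synth_fm_tone(spec, sample_rate=44100)
summary = summarize_contour(correct_octave_jumps(extract_f0_contour(wav)))
print(f"tracked start/mean/end: {summary.start_pitch:.0f} / "
      f"{summary.mean_pitch:.0f} / {summary.end_pitch:.0f} Hz")

# a synthetic two-species population and the size-coding tests
config = PopulationConfig(
    species_counts={"american_alligator": 20, "nile_crocodile": 20},
    calls_mean=8.0)
ds = generate_dataset(config, seed=7, emit_audio=False)
space = fit_acoustic_space(analytic_features(ds.ground_truth))
print(f"explained variance: AD1 {space.explained_variance[0]:.1%}, "
      f"AD2 {space.explained_variance[1]:.1%}")
scores = space.call_scores.merge(ds.metadata, on="individual_id")
print(test_size_effect(scores).tests.round(3).to_string(index=False))
```

prints

```
designed peak: 856 Hz
tracked start/mean/end: 634 / 635 / 353 Hz
explained variance: AD1 58.2%, AD2 27.0%
dimension           term  chi_square  df  p_value
      AD1           size       8.311   1    0.004
      AD1        species      84.167   1    0.000
      AD1 size_x_species       0.014   1    0.905
      AD2           size      39.567   1    0.000
      AD2        species       8.292   1    0.004
      AD2 size_x_species       2.115   1    0.146
```

The designed contour reaches 856 Hz and the tracker returns the three
design anchors (630/638/350 Hz) within about 1 %.  In the synthetic
population both acoustic dimensions carry a significant body-size effect
and a significant species effect, while the size × species interaction is
non-significant — the calls of both species scale with body length along a
shared slope, which is exactly the structure the generator encodes.

## Command line

```sh
crocvoice synth --out-dir stimuli                 # the three playback stimuli as WAV
crocvoice simulate --seed 1 --out-dir pop         # seeded synthetic population
crocvoice features pop/wav pop/metadata.csv      # 13 descriptors per call -> CSV
crocvoice analyze-size features.csv              # loadings, scores, LRT results
crocvoice analyze-playback trials.csv            # composite scores, LRT, pairwise
```

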