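# beamfov

Biosonar beam-pattern estimation from hydrophone-array recordings, built
around the question of how an echolocating animal's acoustic field of view
changes during a target approach.

The package provides a tested pipeline:

- **geometry** — coordinate conventions, the 8-element linear array and the
  two 48-channel star-array configurations, effective angular resolution.
- **beam_model** — circular-piston directivity mathematics (narrowband and
  spectrum-weighted broadband): directivity, −3 dB beamwidth, directivity
  index, and beamwidth→aperture inversion.
- **simulator** — synthetic multichannel scenes of a moving, clicking
  piston source (Gaussian pips, spherical spreading, band-limited
  sub-sample delays, seeded noise), with full ground truth; plus a fast
  energy-domain rendering route.
- **click_processing** — envelope click detection, 120 µs energy-flux-
  density windows (30 µs before / 90 µs after the envelope peak), SNR
  gating (joint 6 dB and per-channel 14 dB dialects), spectral centroid,
  inter-click intervals and buzz labels (ICI ≤ 13 ms).
- **localization** — TDOA estimation with sub-sample peak refinement and
  nonlinear least-squares source fixes; bearing to the array centre.
- **beam_linear** — apparent-source-level radiation patterns with Lagrange
  peak refinement and a 1-D piston fit.
- **beam_star** — per-channel gating, regularized least-squares gridding
  of click energies (0.5 cm cells) with quadratic peak refinement, and the
  Monte-Carlo piston fit (diameters 1/3–3× of 8.3 cm in 0.1 cm steps,
  R² > 0.8 gate, spread from the lowest 5 % of the error curve).
- **validation_sim** — virtual-source error simulations quantifying
  beamwidth and beam-axis errors versus bearing, axis displacement, range
  and aperture; derives inclusion regions for an error budget.
- **tag_echogram** — click-synchronized echograms, delay→range conversion
  (c/2), relative apparent output level series.
- **fov_stats** — ensonified cone areas and area ratios, active-sonar
  detection range, beamwidth–range regression, centroid-linkage
  clustering + ANOVA/Tukey comparison.

## Tests

```sh
python -m pytest tests/
```

The acceptance tests (`tests/test_acceptance.py`) include a virtual-source
ensemble that takes a few minutes; everything else is fast.

## CLI

```sh
beamfov geometry --config star-small -o geom.json
beamfov simulate --geom geom.json --spec trial.json --seed 7 -o trialdir/
beamfov clicks --wav trialdir/array.wav --geom trialdir/geometry.json \
    --full-scale-upa <fs> -o clicks.csv
beamfov localize --clicks clicks.csv --geom trialdir/geometry.json -o fixes.csv
beamfov beam-star --clicks clicks.csv --fixes fixes.csv \
    --geom trialdir/geometry.json --noise-level 120 -o fits.csv
beamfov beam-linear --clicks clicks.csv --fixes fixes.csv --geom geom.json -o fits.csv
beamfov validate --seed 1 -o surface.csv
beamfov fov --fits fits.csv -o summary.json
```

`trial.json` holds the approach schedule, e.g.

```json
{"start_range_m": 4.0, "end_range_m": 0.6, "speed_mps": 1.0,
 "ici_s": 0.05, "beamwidth_deg": 8.2, "noise_level_db": 110.0}
```

## Conventions

Origin at the array centre; +y points from the array toward the
approaching animal; x horizontal in the array plane; z vertical. Sound
speed 1500 m/s. Energy flux density in dB re 1 µPa²·s over the fixed
120 µs window; apparent source level back-calculated with spherical
spreading (no absorption).
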