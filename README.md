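# periomap

Analysis pipeline for mapping two dimensions of sound — spectral frequency
(tonotopy) and amplitude-modulation rate (periodotopy) — across primate
auditory cortex from BOLD fMRI, together with a synthetic-cortex generator
that provides ground-truth topographies for validating every stage.

The scientific question the toolchain addresses: macaque auditory cortex
contains multiple tonotopic fields (core A1, R, RT; belt CL, ML, AL, CM…)
whose frequency gradients reverse at field borders, while preferred
amplitude-modulation rate is organised in concentric iso-rate bands centred
postero-medially. Within a field, how are the two gradients oriented
relative to each other? In A1 they are roughly orthogonal; the package
quantifies this with a per-field relative angle α.

## What it computes

Given sparse-design BOLD series (10 s TR, 1 s acquisition, alternating
silent baseline; 6 AM rates 0.5–512 Hz or 3 noise bands 0.5–16 kHz):

1. **glm** — 2 mm FWHM Gaussian smoothing, global scaling to an in-brain
   mean of 100 (betas read as percent signal change), discrete-cosine
   high-pass (300 s cutoff) inside the design, then voxelwise OLS:
   per-condition betas and t-values vs the silent baseline, an omnibus F,
   and a significance mask (p < 0.001, optionally Bonferroni).
2. **maps** — contrast maps, `mean(beta_high) − mean(beta_low)` (rates:
   {128, 512} vs {0.5, 2} Hz; frequency: high band vs low band), and
   best-rate / best-frequency maps (voxelwise argmax of t).
3. **project** — volume-to-surface projection: each vertex averages (or,
   for labels, takes the majority vote of) the in-mask voxels within a
   1.6 mm sphere.
4. **gradients** — per auditory field, a 2D regression
   `value = b0 + bu·u + bv·v` on flattened coordinates (0° = anterior,
   90° = lateral, right hemispheres mirrored) giving the gradient
   direction, magnitude, R², and F-test p; the relative angle
   `α = fold180(|dir_freq − dir_rate|)`; and a summary table with
   per-field Average / Std-dev rows.
5. **phase** — a continuous phase-encoded tonotopy analysis (1.4 s TR,
   nine half-octave tones in 2 s blocks, 18 s progression + 12 s silence,
   15 cycles, both directions): 0.02–0.1 Hz zero-phase band-pass, percent
   signal change, circular cross-correlation between the two run
   directions; the lag inverts to the preferred-frequency ladder step via
   `k = round((lag + 16 s) / 4 s)` and the shared hemodynamic delay
   cancels.

The estimation cores follow the statsmodels model/results idiom:
`SparseGLM(series, design).fit() -> StatMaps`,
`GradientOLS(coords, values).fit() -> GradientResults`,
`PhaseEncodedModel(pair).fit() -> LagResult`, each with a `summary()`.

The `synth` module is first-class: it builds a flat cortical sheet with an
idealised field parcellation, plants concentric iso-rate bands
(`r(d) = 128·2^(−d/λ)` Hz) and continuous per-band tonotopic gradients
with reversals at the A1/R and R/RT borders, and simulates both the sparse
and the phase-encoded acquisitions with log-Gaussian neural tuning and a
gamma hemodynamic response.

## Worked example

Simulate the default synthetic dataset (full pooled acquisition: 315
volumes per rate stimulus, 360 per frequency stimulus, noise giving
per-condition SNR ≈ 1 per session) and recover the A1 gradients:

```python
from periomap.pipeline import recover_field_gradients

freq_fit, rate_fit, alpha = recover_field_gradients(seed=3)
print(freq_fit.summary())
print(rate_fit.summary())
print(f"relative angle alpha = {alpha:.1f} deg")
```

prints

```
2D gradient fit: direction  342.1 deg, |grad| 0.2028/mm, R2 0.943, p <1E-16, n 72
2D gradient fit: direction  230.8 deg, |grad| 0.05665/mm, R2 0.893, p <1E-16, n 72
relative angle alpha = 111.3 deg
```

The planted A1 axes are 165°/53° (mod 180°, i.e. directions 345°/233.6°),
so the true relative angle is 112°: the frequency gradient is recovered at
342° and the rate gradient at 231° from noisy data, giving α = 111.3° for
this seed (the mean over seeds 1–10 is ≈ 115°, within a few degrees of the
planted value; per-seed scatter is ~10° because the contrast-map noise is
spatially correlated by smoothing and projection).

A full staged run (writes NIfTI/GIFTI/TSV intermediates, a Table-style
summary and a manifest into a run directory):

```bash
periomap run-all --outdir demo_run --seed 1
periomap report --outdir demo_run
```

Note the default configuration simulates the full pooled acquisition for
two hemispheres (~300 MB of intermediates); pass `--config` with smaller
`sparse.rate_volumes` / `sparse.freq_volumes` for a lighter demo.

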