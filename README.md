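# nirsel

Wavelength (variable) selection for near-infrared multivariate calibration,
built around leave-one-out cross-validation (LOOCV) scored by SECV (the
root-mean-square error of the cross-validated predictions) and R_P,CV (the
correlation between measured and cross-validated predicted values).

Three selection strategies share that evaluation machinery:

- **Best-partner projection iteration** (`nirsel.opwc`, "OPWC"): every
  wavelength pair is scored by the LOOCV SECV of a two-predictor linear
  regression (computed with the closed-form leverage identity, so a full
  860-point grid — 369,370 pairs — takes seconds); each wavelength maps to
  its best partner; iterating the image of that fixed map yields a nested,
  strictly shrinking sequence of subsets that converges in at most N steps
  to a stable set on which the map is a bijection (a union of cycles —
  mutual-partner pairs when all scores are distinct). A PLS model with
  LOOCV-tuned factor count is fitted on the stable set.
- **Moving-window PLS** (`nirsel.mwpls`): exhaustive search over window
  start, width and PLS factor count, minimizing LOOCV SECV.
- **Monte Carlo uninformative variable elimination** (`nirsel.mcuve`):
  variables are kept when the stability (mean/SD) of their PLS coefficients
  across random calibration subsets beats that of appended artificial noise
  columns; the procedure is rerun with fresh seeds and the best rerun kept.

`nirsel.pls` implements PLS1 (NIPALS on centered, unscaled data), LOOCV and
the two statistics; `nirsel.dataset` reads/writes wide CSV spectra tables;
`nirsel.synth` generates Beer–Lambert mixture spectra (Gaussian bands,
interfering components, region-dependent noise) with known ground truth, so
every method can be validated without proprietary data.

## CLI

```bash
# synthetic serum-like dataset: 230 samples, 780–2498 nm at 2 nm
nirsel simulate --preset serum --seed 42 --out spectra.csv --truth truth.json

# full-spectrum PLS baseline
nirsel pls --input spectra.csv --reference ref --factors 1:20 --out pls.json

# best-partner projection iteration (with per-iteration diagnostics + score cache)
nirsel opwc --input spectra.csv --factors 1:20 --trace --cache scores.npz --out opwc.json

# moving-window search (range syntax: start:stop[:step], comma unions)
nirsel mwpls --input spectra.csv --I 780:2498:2 --N 1:200,210:860:10 \
    --factors 1:20 --out mwpls.json

# Monte Carlo elimination
nirsel mcuve --input spectra.csv --runs 500 --reruns 50 --fraction 0.8 \
    --factors 1:30 --seed 7 --out mcuve.json
```

Input is a wide CSV (first column sample id, one named reference column,
every other header a wavelength in nm). Results are self-describing JSON:
method, selected wavelengths (nm), factor count, SECV, R_P,CV, and for the
projection method the full shrinkage trace.

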