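# ramanqc

A chemometric calibration pipeline for process Raman spectroscopy of
botanical water extracts, with a built-in synthetic data generator so every
stage is testable without plant data.

The pipeline mirrors a process-analytical calibration study end to end:

1. **simulate** — synthetic three-stage reflux-extraction campaign: linear
   mixtures of pseudo-Voigt component spectra (four phenolic analytes,
   soluble solids, a dominant water band) on a 176–3500 cm⁻¹ axis,
   saturating extraction kinetics, fluorescence-like baseline, triplicate
   acquisitions, planted gross outliers — all reproducible from one seed.
2. **preprocess** — replicate averaging → Savitzky–Golay smoothing →
   per-spectrum min–max scaling to [0, 1].
3. **screen** — Mahalanobis-distance outlier removal in PCA score space
   (95 % variance, ≤ 10 scores; mean + 3·sd or χ² threshold).
4. **split** — deterministic Kennard–Stone partition (default 4:1, so 330
   retained samples give 264 calibration / 66 validation).
5. **select** — characteristic-band selection: CARS (competitive adaptive
   reweighted sampling, the primary method) plus UVE, SPA and siPLS for
   comparison.
6. **train** — one model per attribute: PLSR (RMSECV-chosen latent
   variables), RBF-SVR (grid-searched), and a 1-D convolutional network
   (32 → 16×4 → 32 → 64 filters, kernel 3; batch-norm; attribute-dependent
   pooling/dense depth; Adam 1e-4, batch 50, ≤ 200 epochs, patience 40).
   The CNN is implemented in pure numpy — no deep-learning framework
   required — and trains deterministically from a seed.
7. **evaluate** — Rc²/RMSEC, Rcv²/RMSECV, Rp²/RMSEP per (engine, attribute)
   in a comparison-table report.
8. **predict** — apply saved model bundles to unknown process batches.

## CLI

```bash
ramanqc simulate --seed 1 --out data/                 # synthetic campaign
ramanqc preprocess --in data/spectra.csv --out pp.csv --window 11 --polyorder 3
ramanqc screen --in pp.csv --out retained.csv --report screening.json
ramanqc split --in retained.csv --ratio 4:1 --out split.json
ramanqc select --in retained.csv --references data/references.csv \
               --attribute rosmarinic_acid --method cars --out sel.json
ramanqc train --in retained.csv --references data/references.csv \
              --engine cars-plsr --attribute rosmarinic_acid \
              --selection sel.json --out model
ramanqc predict --model . --in unknown.csv --out predictions.csv
ramanqc run --config configs/default.yaml --out runs/demo   # everything
```

`ramanqc run` executes the whole study from one YAML config and writes
every intermediate artifact plus a manifest with content hashes; a rerun
with the same config and seed is bit-identical.

`configs/default.yaml` is a **desk-scaled** study (coarser axis, 100-epoch
CNN, 3-fold CV) sized for a single CPU; the comments in the file say what
to change for a full-scale run.

## Data formats

- Spectra: wide CSV (first column `wavenumber` in cm⁻¹, one column per
  sample) or minimal JCAMP-DX (one `.jdx` per sample).
- Reference values: tidy CSV `sample_id, analyte, value, units`.
- Splits/selections/reports: JSON and CSV.

## Tests

```bash
python -m pytest tests/            # unit + property + acceptance suite
```

`tests/test_acceptance.py` holds the acceptance criteria (split
arithmetic, screening recovery, Savitzky–Golay oracle, PLSR exactness,
CARS recovery, CNN parameter recovery, end-to-end report shape). The full
suite takes roughly 15–20 minutes on one CPU; everything outside
`test_acceptance.py` finishes in about two.

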