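# helr

Privacy-preserving multi-institutional logistic regression on
homomorphically encrypted data, exercised end-to-end on a synthetic
multi-hospital perioperative cohort generator.

The package re-implements, as a tested reusable pipeline:

* **`helr.synth`** — a three-site synthetic cohort generator (sites `A`,
  `S`, `E`) with per-site feature distributions, block-correlated
  laboratory panels, MCAR missingness, site-heterogeneous logistic
  coefficients and rare (0.2–0.4%) 30-day mortality, calibrated by
  Monte-Carlo bisection of the intercept.
* **`helr.preprocess`** — per-site median imputation, per-site
  standardization (computed before any encryption), fixed-vocabulary
  one-hot encoding (p = 29 model columns from 19 clinical variables),
  6:2:2 splitting and missingness diagnostics at the |r| ≥ 0.7 threshold.
* **`helr.lr`** — plaintext logistic regression from first principles:
  minibatch Nesterov accelerated gradient (lr 0.01, batch 64 defaults),
  binary cross-entropy, optional ridge penalty, a least-squares polynomial
  sigmoid on [−8, 8] for ciphertext-evaluable arithmetic, odds ratios and
  exact linear-model SHAP attributions.
* **`helr.he`** — a CKKS-style leveled homomorphic arithmetic contract
  with a toy reference backend: slot vectors, scale Δ = 2⁴⁰ quantization,
  level bookkeeping (each ciphertext multiply consumes a level),
  randomized key-bound encryption, a deterministic monotone noise-bound
  model, and a privileged refresh authority standing in for CKKS
  bootstrapping. **This is a contract-faithful simulation, not a
  cryptosystem** — see the module docstring.
* **`helr.secure`** — the encrypted trainer: batch-major ciphertext
  packing, decryption-free merging of per-site packs, and a training loop
  that mirrors `helr.lr` operation-for-operation so ciphertext/plaintext
  parity is directly testable (measured mean absolute prediction
  difference ~1e-10 on the toy backend, bounded in tests at 2.02e-5).
* **`helr.metrics`** — midrank AUROC, average-precision AUPRC, DeLong's
  structural-component test for correlated ROC areas, and bootstrap model
  averaging with percentile CIs (stratified by outcome by default, because
  naive resampling at 0.2% prevalence yields all-negative replicates).
* **`helr.experiments`** — the three computational experiments behind one
  CLI: the cross-site validation matrix (singles in plaintext, merged
  combinations on ciphertext), model-adaptation curves (donor data plus
  nested growing host increments), and the ciphertext/plaintext parity
  study.

## CLI

```sh
helr simulate --sites 3 --n 5000 --seed 7 -o cohort.csv
helr preprocess cohort.csv -o prep/
helr cross-site --config cfg.yaml -o out/        # Table-2-style matrix
helr adapt --donor A --host E -o out/            # adaptation curve
helr parity --config cfg.yaml -o out/            # parity report JSON
helr report out/
```

Experiment configs are YAML/JSON mirrors of
`helr.experiments.ExperimentConfig`; every output artifact is stamped with
the config hash and master seed. Desk-scale runs can pass
`--plaintext-only` and a `prevalence` override (the generator's default
0.2% outcome rate needs large cohorts to evaluate).

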