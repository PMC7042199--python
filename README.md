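# connectoml

A tested, reusable pipeline for two-group functional-connectome analysis and
classification: connectivity-network construction, graph-metric extraction,
statistical and group-sparse feature selection, and multi-kernel SVM fusion,
exercised end-to-end on a synthetic cohort generator so every stage is
testable without any external data.

## What it does

1. **`connectoml.syncon`** — generates synthetic two-group cohorts (ROI × time
   matrices, covariates, optional scalar markers) from a latent-factor model
   with planted subnetwork attenuation and hub nodes, plus exportable ground
   truth. Defaults mirror a 39-patient / 60-control, 264-ROI, 230-time-point
   design with 14 subnetworks.
2. **`connectoml.netbuild`** — Pearson connectivity matrices, negative-weight
   zeroing, binarization over a 49-level sparsity grid (0.02…0.50, step 0.01,
   exact edge counts with deterministic tie-breaking), threshold-AUC metric
   summaries (sum over the grid), Fisher-z transforms.
3. **`connectoml.gmetrics`** — global metrics (Cp, Lp, γ, λ, σ against
   degree-preserving rewired null networks, global efficiency, modularity Q),
   seven nodal metrics (betweenness, degree, clustering, local efficiency,
   path length, participation coefficient, within-module degree), greedy
   modularity optimization, module connection densities, mean + 2 SD hub
   detection.
4. **`connectoml.select`** — covariate residualization, pooled t-tests (raw
   or summary form), Pearson chi-square, Benjamini–Hochberg FDR, the
   network-based statistic (NBS) permutation test, and a group-LASSO logistic
   selector (monotone FISTA) over node-grouped metric features.
5. **`connectoml.mklsvm`** — per-view linear kernels (train-fold scalers,
   trace normalization), simplex-grid multiple-kernel SVM with nested
   leave-one-out cross-validation, confusion metrics, rank-based ROC/AUC,
   and the paired DeLong test.
6. **`connectoml.pipeline`** — configuration-driven orchestration, TSV/JSON
   artifacts, demographics tables and a performance report.

## CLI

```bash
connectoml run-all --out runs/demo --seed 1        # scaled-down synthetic demo
connectoml simulate --out runs/demo                # or run stage by stage:
connectoml build-networks --out runs/demo
connectoml metrics --out runs/demo
connectoml select --out runs/demo
connectoml classify --out runs/demo
connectoml report --out runs/demo
```

Options come from flags or a plain `key = value` config file
(`--config run.cfg`); keys mirror `pipeline.RunConfig` fields, e.g.

```
n_rois = 60
edge_effect = 0.8
nbs_nperm = 200
c_exponents = -5, -1, 3
```

The default demo (60 ROIs, 30+30 subjects) finishes in minutes on one CPU;
the full 264-ROI configuration is the same pipeline with larger fields.
Exit codes: 0 success, 2 configuration error, 3 data error.

## Layout

```
src/connectoml/    syncon, netbuild, gmetrics, select, mklsvm, pipeline, io, cli
tests/             unit + property tests per module, test_acceptance.py
scripts/           acceptance.py
```
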