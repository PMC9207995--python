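# netbridge

Network-based regression toolkit linking behavioural trait networks to
functional-connectome correlates. The workflow:

1. **Unique-variance regressors** — correlated trait scores are
   residualized (full or sequential/Gram–Schmidt OLS) so each regressor
   carries only the variance not shared with the other traits.
2. **Connectome construction** — per-subject Pearson, partial-correlation,
   or tangent-space connectomes from ROI time series; upper-triangle edge
   vectorization; edge-wise OLS removal of confounds (age, age², site,
   FD, DVARS, ICV, grey-matter volume); ROI-coverage and motion QC filters.
3. **Connectome-based predictive modelling (CPM)** — mass-univariate edge
   selection by correlation p-value, summed positive/negative brain scores,
   a two-coefficient OLS model, seeded 80/20 outer shuffle-split tuning
   over analysis channels with inner k-fold diagnostics, cross-split
   consensus edges (default 7 of 10), and permutation inference.
4. **Joint behaviour–brain networks** — total brain scores
   (β⁺·S⁺ + β⁻·S⁻) join the trait scores in a 6-node table analysed with
   (a) unregularized Gaussian graphical models selected by extended BIC
   over a graphical-lasso path with stepwise refinement and bootstrap edge
   stability, and (b) constraint-based Bayesian-network structure learning
   (Grow-Shrink, IAMB, Fast-IAMB, Inter-IAMB, MMPC) under four
   conditional-independence tests, with cross-learner consensus.

A seeded `synthetic_data` module generates every fixture the pipeline
needs (trait tables with an *exact* prescribed sample correlation matrix,
edge tables with planted effects, multivariate-normal time series,
confound tables), so the whole analysis is testable offline.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (reference-table
reproduction, planted-signal recovery, permutation and CI-test
calibration, EBIC-oracle equivalence, CPDAG recovery, connectome
identities, end-to-end determinism).

## CLI

All verbs read a YAML config (`--config`) and accept a `--seed` override
of the master seed; per-stage seeds are derived deterministically from it.

```bash
netbridge simulate    --config config.yaml     # write synthetic inputs
netbridge residualize --config config.yaml
netbridge connectome  --config config.yaml --timeseries-dir ts/ --metric pearson --out edges.csv
netbridge cpm         --config config.yaml --trait Social
netbridge network     --config config.yaml --table joint.csv
netbridge dag         --config config.yaml --table joint.csv
netbridge run         --config config.yaml     # full pipeline + report.json
netbridge report      --config config.yaml     # summarize an existing report
```

Example config:

```yaml
seed: 11
output_dir: out
inputs:
  behaviour_csv: behaviour.csv        # subject_id + trait columns, blank = missing
  confounds_csv: confounds.csv        # subject_id, age, site, fd, dvars, icv, gm_volume
  channels:
    - {resolution: 300, metric: pearson, gsr: false, edges_csv: edges_300_pearson.csv}
qc: {fd_max: 0.5, dvars_max: 5.0}
residualization: {scheme: sequential, order: [RRBI, Communication, Social]}
cpm: {p_grid: [0.001, 0.01, 0.05], n_outer: 10, inner_folds: 10, min_count: 7, n_perm: 5000}
ggm: {gamma: 0.5, bootstrap_B: 1000}
bayesnet: {algorithms: [gs, iamb, fast_iamb, inter_iamb, mmpc],
           tests: [pearson_t, fisher_z, mc_permutation, mutual_information],
           alpha: 0.05}
```

Identical config + seed produce a byte-identical `report.json`.
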