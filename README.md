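# egonet

Suicidal-intent network analysis and attempt-lethality classification for
emergency-room cohorts scored with the 15-item Beck Suicide Intent Scale
(SIS) and the C-SSRS actual-lethality grade (1–6; grade ≥ 4 is a lethal
attempt).

The package implements the full analysis chain:

1. **Cohort IO & preprocessing** (`egonet.io_cohort`) — CSV cohort tables
   (15 SIS items scored 0–2, 14 ER confounders, C-SSRS grade), SIS
   calibration to the 1–3 scale, decimal-year date encoding
   (`2013-06-30 → 2013.492`), lethality labelling, and k-nearest-neighbour
   imputation of missing cells (mode for coded/ordinal columns, mean for
   continuous ones).
2. **Synthetic cohorts** (`egonet.synthetic_data`) — seeded Gaussian-copula
   generator with planted group-wise partial-correlation structure: the
   lethal group carries a hub at SIS item 11 (conception of the method's
   lethality), the nonlethal group a hub at item 9 with the method items
   10–11 disconnected; ~17.1 % lethal prevalence, male excess and higher
   age in the lethal group, 2.7 % MCAR missingness.
3. **Relationship features** (`egonet.relationship_features`) — three
   signatures per unordered item pair: interaction `I = s_i·s_j`, harmonic
   mean `H = 2·s_i·s_j/(s_i+s_j)`, and the tangent angle difference
   `T = (s_i−s_j)/(1+s_i·s_j)`; 105 pairs × 3 types = 315 features,
   assembled with the 29 base features and 16 structural zeros into the
   18×20 model input grid.
4. **Network analysis** (`egonet.network_analysis`) — GLASSO
   partial-correlation networks over the 15 SIS items plus the Fatality
   node, EBIC (γ = 0.5) penalty selection, permutation-tested edges
   (column shuffling, two-sided empirical p with +1 correction), degree
   and average-shortest-path topology, GraphML export.
5. **Models** (`egonet.models`) — the E-GONet CNN (three 3×3 conv layers
   with 16/32/64 channels, 2×2 max-pooling after the first two, a
   128-unit FC layer with dropout and a 2-way softmax), implemented in
   pure numpy with exact backpropagation, plus least-squares and
   random-forest baselines on the same flattened grid. A per-cell min–max
   scaler is fitted on training folds only.
6. **Evaluation** (`egonet.evaluation`) — stratified k-fold
   cross-validation, confusion-matrix metrics (weighted F1, PPV, NPV,
   sensitivity, specificity, accuracy) and a from-scratch
   precision-recall-gain curve with trapezoidal AUPRG.
7. **Saliency** (`egonet.saliency`) — gradient×input importance maps of
   the true-class logit, averaged per class within folds and then across
   folds.

## CLI

```sh
egonet --seed 1 --outdir run generate --n-subjects 1112
egonet --outdir run preprocess run/cohort.csv
egonet --outdir run features run/cohort.csv
egonet --seed 1 --outdir run network run/cohort.csv --n-perm 1000
egonet --seed 1 --outdir run train run/cohort.csv --kind egonet
egonet --seed 1 --outdir run evaluate run/cohort.csv
egonet --seed 1 --outdir run all          # full pipeline + manifest
```

`egonet train --no-relationship-features` reproduces the ablation in which
the relationship block of the grid is zeroed. `--config cfg.yaml` supplies
a YAML run configuration (see `egonet.pipeline_cli.RunConfig`); every
resolved value and artifact checksum is echoed into
`<outdir>/manifest.json`.

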