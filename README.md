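# smmbn

Discrete Bayesian-network pipeline for analysing disparities in a rare
binary health outcome (severe maternal morbidity, "SMM") from categorical
birth-record data. The package re-implements, as tested reusable
components:

- **`smmbn.bn_core`** — DAG/PDAG types, d-separation, Markov blankets,
  frequency-count CPT fitting, exact enumeration queries, ancestral
  sampling and structure interchange (model strings `[A][B|A]`, GraphML,
  DOT).
- **`smmbn.structure_learning`** — decomposable scores (log-likelihood,
  AIC, BIC), the G² conditional-independence test, hill climbing and tabu
  search, the Grow-Shrink / IAMB / Fast-IAMB / Inter-IAMB Markov-blanket
  learners, MMPC skeletons and hybrid restrict-maximize search, all under
  layering blacklists / whitelists.
- **`smmbn.ensemble_consensus`** — bootstrap replicate ensembles per
  algorithm, the 1 / 0.5 / 0 consensus score with the strict >70% rule,
  algorithm selection by total arcs, Markov-blanket misclassification
  evaluation and bootstrap arc-strength model averaging.
- **`smmbn.influence_queries`** — distance-weighted influence (DWI) node
  ranking over unblocked simple paths (constant-`w` and arc-strength
  weighted modes) and likelihood-weighting conditional probability queries
  with Monte-Carlo odds-ratio intervals.
- **`smmbn.synthetic_cohort`** — a calibrated three-layer ground-truth
  network (demographics / county quartiles → comorbidities → outcome)
  reproducing ~2% outcome prevalence and race-conditional comorbidity
  gradients exactly, plus small fixture networks for oracle testing.
- **`smmbn.pipeline`** — quartile discretization, train/test splitting,
  random under-sampling and the end-to-end, config-driven pipeline with
  plain-text artifacts (CSV / GraphML / JSON manifest).

## Command line

```bash
smmbn simulate --n 50000 --seed 1 --out cohort.csv      # synthetic cohort
smmbn prepare --input cohort.csv --out prep/            # split + balance
smmbn learn --input prep/train_balanced.csv --out run/  # ensemble consensus
smmbn strength --input prep/train_balanced.csv --out run/
smmbn influence --network run/averaged_network.graphml \
    --strengths run/arc_strengths.csv --target smm --out dwi.csv
smmbn query --input prep/train.csv --network run/averaged_network.graphml \
    --event smm=yes --group race --ref white --out ors.csv
smmbn all --config config.yaml --out results/           # full procedure
```

`smmbn show-config` prints the default pipeline configuration as YAML; any
subset of it can be supplied via `--config`. Every stage is seeded from
the config and the JSON manifest written by `smmbn all` reproduces the run
byte-for-byte.

## Notes

- Scores follow the larger-is-better convention with BIC penalty
  `(ln N)/2` per free parameter; free parameters per family are
  `(r - 1) * q`.
- The G² test defaults to the `N >= 5 df` reliability heuristic
  (configurable off), alpha 0.05, and conditioning sets of size ≤ 3 in
  skeleton phases.
- Layering is enforced as a blacklist: a variable may have parents only in
  its own or upstream layers.
- Quartile coding uses linear-interpolation percentiles with
  left-open/right-closed intervals (ties go to the lower quartile).
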