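# mltc-clusters

Tools for studying how disease clusters should be assigned to people
with multiple long-term conditions (MLTC), and what is lost when they
are.

Clustering studies partition long-term conditions (LTCs) into groups of
diseases that tend to co-occur — here a fixed map of 212 LTCs into 15
clusters.  But a person's diseases usually span several clusters, so any
person-level analysis needs an *assignment strategy*.  This package
implements seven of them — assign a cluster when a person has ≥1, ≥2 or
≥3 diseases in it; assign only the modal cluster (ties broken at
random); assign the cluster holding a strict majority of the person's
diseases; or carry the full count or proportion of diseases per
cluster — and evaluates each strategy's ability to explain three binary
1-year outcomes (death, emergency-department attendance, emergency
admission) with logistic regression, compared by AIC = 2k − 2 lnL
against a reference model that uses the 212 individual diseases as
binary predictors.  It also profiles median age at diagnosis per disease
and cluster, and quantifies how much adjusted odds ratios (aORs) vary
*within* clusters relative to *between* clusters.

Because the EHR data such analyses run on cannot be redistributed, the
package includes a first-class synthetic cohort generator with the
relevant structure: cluster-correlated disease co-occurrence (Dirichlet
propensity per patient), a right-skewed LTC count (median 8, IQR 5–11),
disease-specific onset ages, outcome risks driven by disease-level
log-odds γ_d = μ_c(d) + N(0, τ) with tunable within-cluster
heterogeneity τ, and ~4.9% censoring by de-registration.  See
`docs/methods.md` for the model and all defaults.

## Worked example

A patient with seven LTCs: four in a metabolic cluster, two in a
respiratory-and-vascular cluster, one in an alcohol-and-liver cluster.

```python
>>> import pandas as pd, numpy as np, mltc_clusters as m
>>> counts = pd.Series([4, 2, 1], index=["metabolic", "resp_vasc", "alcohol_liver"])
>>> int(m.assign_threshold(counts, 1).sum()), int(m.assign_threshold(counts, 2).sum()), int(m.assign_threshold(counts, 3).sum())
(3, 2, 1)
>>> m.assign_modal(counts, np.random.default_rng(0))[0].tolist()
[1, 0, 0]
>>> m.assign_majority(counts).tolist()      # 4/7 > 0.5
[1, 0, 0]
>>> m.assign_proportion(counts).round(3).tolist()
[0.571, 0.286, 0.143]
```

Requiring one, two or three diseases per cluster assigns three, two and
one cluster respectively; modal and majority both pick only the
metabolic cluster; count keeps (4, 2, 1); proportion keeps the relative
composition.

## End-to-end pipeline

```sh
mltc-clusters simulate --config config.yaml --seed 1 --out runs/sim
mltc-clusters summarize-assignment --config config.yaml --seed 1 --out runs/summary.csv
mltc-clusters onset     --config config.yaml --seed 1 --out runs/onset.csv
mltc-clusters compare   --config config.yaml --seed 1 --out runs/compare.csv
mltc-clusters dispersion --config config.yaml --seed 1 --out runs/dispersion
```

with a config such as

```yaml
simulate: {n_patients: 20000, heterogeneity_sd: 0.5}
data: {dir: runs/sim}
analysis: {apply_followup_exclusion: true}
```

On this synthetic cohort (seed 1, n = 20,000; 18,977 analysed after
excluding 5.1% de-registered), `compare` reports that the disease-level
model has the lowest AIC for all three outcomes and that `count` is the
best cluster strategy for all three (for death, count's AIC exceeds the
disease model's by ≈1107 and majority's exceeds count's by ≈1817 —
aggregating diseases into clusters loses real information, and the more
a strategy discards, the worse it explains outcomes).  `dispersion`
reports a median within-cluster log-aOR range of ≈2.24 against a
between-cluster range of ≈1.23 for death: individual diseases inside one
cluster relate to mortality far less consistently than the clusters
differ from each other.  `summarize-assignment` shows a modal tie for
36.4% of patients and, under ge1, every patient assigned and fully
represented.

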