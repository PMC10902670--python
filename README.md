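# cytorisk

Single-cell immunometabolic risk stratification for critically ill cohorts.

Patients surviving the acute phase of critical illness (chronic critical
illness, CCI — mechanical ventilation beyond 10 days) carry a high risk of
nosocomial infection driven by immune dysfunction.  Mass cytometry (CyTOF)
with an immunometabolic panel — 26 lineage markers resolving 21 immune
subsets plus 16 metabolic regulator proteins (GLUT1, HK2, CPT1a, NRF1,
PGC1α, …) — measures, per patient, the abundance of every subset and the
metabolic state of its cells.  `cytorisk` implements the full analysis that
turns such data, together with plasma cytokines, into an infection-risk
score, and the scRNA-seq gene-signature comparison used to validate the
NK-cell findings in independent cohorts.  A seeded synthetic-cohort
generator stands in for patient data, so every stage is testable end to end.

## The method

1. **Feature assembly.**  Raw ion counts are transformed to
   `asinh(x/5)`; events are assigned to 21 subsets by a configurable manual
   gating tree; per patient the pipeline emits 21 subset abundances and
   21 × 16 per-subset arcsinh-mean regulator levels (357 cytometry
   features), plus 5 cytokines (below-detection values are 0 pg/mL).
2. **Patient embedding.**  After Z transformation, patients *i*, *j* are
   compared by the squared-rank-difference distance
   `d_ij = Σ_k (r_k(i) − r_k(j))²` (ranks per feature, average ranks for
   ties) and embedded by metric MDS (SMACOF majorization from a
   classical-scaling start), minimizing

   `Stress = Σ (d_ij − d̂_ij)² / Σ d_ij²`,

   with dimensionality chosen from the stress-versus-dimension curve by the
   elbow.
3. **Screening.**  Each coordinate is scored by rank AUROC against the
   infection outcome with a stratified percentile bootstrap CI (1,000
   replications); features are correlated with the selected coordinate by
   Spearman ρ with Storey q-values controlling the false discovery rate.
4. **Risk score.**  Elastic-net logistic regression (coordinate descent,
   leave-one-out λ selection) selects among the NK-related candidate
   features V_k and yields the predicted score

   `score = e^(α + Σ_k β_k V_k) / (1 + e^(α + Σ_k β_k V_k))`,

   evaluated by Mann–Whitney tests and AUROC (apparent and leave-one-out).
5. **Validation stage.**  On labeled cell × gene matrices, per-cell
   binned-control module scores for gene signatures (e.g. mitochondrial
   fatty-acid oxidation, GO:0031998; mitochondrial biogenesis,
   R-HSA-1592230) are compared across severity groups by Kruskal–Wallis
   with Dunn post-hoc adjustment.

The estimators (`RankMDS`, `ZTransform`, `ElasticNetLogit`, `ModuleScorer`,
`ArcsinhTransformer`) follow scikit-learn conventions and compose with its
pipelines; module-level functions wrap them for script use.

## Worked example

```python
import cytorisk as cr

spec = cr.CohortSpec(seed=3)                     # 37 patients, 16 infected
events, cytokines, outcomes = cr.generate_cohort(spec)
res = cr.run_cohort_analysis(events, cytokines, outcomes, reps=1000, seed=3)

print(res.screen.table.round(3))
print(f"selected: {res.selected_coordinate}")
print(f"significant features (q<0.05): {len(res.significant_features)}")
print(f"elastic net kept: {res.model.selected_features_}")
ev = res.evaluation
print(f"score AUROC {ev['auroc']:.2f}, Mann-Whitney p = {ev['mann_whitney_p']:.2g}")
```

```
              auroc  ci_lower  ci_upper
coordinate
coordinate 1  0.604     0.417     0.786
coordinate 2  0.521     0.345     0.714
coordinate 3  0.923     0.795     1.000
selected: coordinate 3
significant features (q<0.05): 6
elastic net kept: ['NRF1_NK(CD56dimCD57-)', 'CPT1a_NK(CD56bright)',
 'CPT1a_NK(CD56dimCD57-)', 'NRF1_NK(CD56dimCD57+)', 'NRF1_NK(CD56bright)',
 'CPT1a_NK(CD56dimCD57+)']
score AUROC 1.00, Mann-Whitney p = 2.8e-07
```

The first two coordinates absorb the cohort's dominant, outcome-neutral
immune variation; coordinate 3 isolates the NK-cell NRF1/CPT1a program the
generator plants in infected patients, and the elastic net recovers exactly
those features.  The same stages are available from a shell:

```sh
cytorisk simulate --seed 3 --out sim/
cytorisk features --events sim/events.tsv --cytokines sim/cytokines.csv \
                  --outcomes sim/outcomes.csv --out features.csv
cytorisk embed --features features.csv --dims 1:6 --seed 3 --out mds/
```

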