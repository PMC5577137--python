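# tnlike

Proteomics-driven discovery and evaluation of a **TN-like** subtype of ER+
breast cancer — a reusable, fully tested re-implementation of the analysis
chain that identifies ER+ tumours whose protein expression resembles
triple-negative breast cancer (TNBC) and evaluates their clinical and
metabolic phenotype. Because patient-level proteomics data of this kind are
not publicly distributable, the package ships a synthetic-cohort generator
that reproduces the statistical structure the analysis relies on, so every
stage runs end to end with no downloads.

**Who it is for:** computational biologists who want the individual building
blocks (SAM-style permutation FDR, minimum-BIC forest Gaussian graphical
models, E-Flux constrained flux balance analysis, the compound covariate
predictor with honest LOOCV) as tested library functions, or the whole
pipeline as a harness for method development on tumour-proteomics-like data.

## The analysis

1. **Preprocessing.** Label-free intensities are kept when detected in ≥75%
   of samples of at least one receptor group with ≥2 unique peptides,
   log2-transformed, imputed from a downshifted normal
   `N(μ_s − 1.8σ_s, (0.3σ_s)²)` per sample (left-censored missingness),
   z-scored per protein and batch-adjusted (location/scale).
2. **Differential expression.** The SAM statistic
   `d_i = (x̄_i1 − x̄_i2)/(s_i + s0)` with permutation FDR
   `FDR(Δ) = π̂0 · med_perm #{|d*| ≥ Δ} / #{|d| ≥ Δ}`; features are called
   at q < 0.05.
3. **Subtype labelling.** Samples are clustered on the selected proteins
   (distance 1 − Pearson r, average linkage, two-cluster cut); ER+ tumours
   falling in the TNBC-majority cluster are labelled *TN-like*, the rest
   *ER-true*.
4. **Graphical model.** A maximum-gain spanning forest over proteins and
   miRNAs scored by `ΔBIC = n·ln(1 − r²) + ln n`, then forward stepwise
   edge addition inside the decomposable (chordal) family using the exact
   clique/separator likelihood. Branches become functional nodes whose
   activity is the mean z-scored expression of member proteins.
5. **Metabolic modelling (E-Flux).** Gene-protein-reaction rules are
   evaluated with sums for OR and minima for AND, normalised per tumour by
   their maximum, and used to cap reaction bounds before maximising biomass:
   `max c'v  s.t.  S·v = 0, lb ≤ v ≤ ub`. A bundled Warburg-style toy
   network makes the lactate-overflow prediction checkable exactly.
6. **Classification.** The compound covariate predictor: features selected
   at p < 0.05 by the random-variance t-test (inverse-gamma variance
   shrinkage), sample score = Σ t_i·x_i, threshold at the midpoint of
   class-mean scores; LOOCV repeats the entire selection per fold and a
   label-permutation test gives the significance of the error rate.
7. **Survival.** Kaplan-Meier curves, log-rank tests and Cox proportional
   hazards (Efron ties) on distant-metastasis-free survival (DMFS), with
   the 5-year (60-month) rate as the endpoint.

## Worked example

```python
from tnlike import CohortSpec, PipelineConfig, run_pipeline

cfg = PipelineConfig(cohort=CohortSpec(seed=7), seed=7)
r = run_pipeline(cfg, out_dir="run")
print(r.subtype.value_counts().to_dict())
print({g: round(s, 3) for g, s in r.km_5y.items()})
print(r.logrank_p)
```

prints (seed 7, the default 97-tumour cohort: 50 ER-true / 21 TN-like /
26 TNBC planted):

```
{'ER-true': 50, 'TNBC': 26, 'TN-like': 21}
{'ER-true': 0.794, 'TN-like': 0.743, 'TNBC': 0.693}
{'ER-true_vs_TN-like': 0.206, 'three_group': 0.107}
```

All 21 planted TN-like tumours are recovered exactly (adjusted Rand index
1.0): SAM finds 211 ER+/TNBC differential proteins, and the cluster cut
separates the ER+ tumours that carry the TNBC-like signature. The 5-year
DMFS ordering (ER-true > TN-like > TNBC) reflects the calibrated hazards,
and — as expected at only 21 TN-like tumours — the log-rank comparison is
directionally right but underpowered (p ≈ 0.21); the survival difference
becomes significant at larger cohort sizes. The FBA stage predicts a
median growth rate about twice as high in TN-like as in ER-true tumours
(Mann-Whitney p < 1e-10), with every tumour exporting lactate.

The same pipeline is available from the shell:

```bash
tnlike pipeline --seed 7 --out run/
tnlike synth --out cohort/          # just the synthetic data
tnlike summarize --annotation run/annotation.tsv --column subtype
```

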