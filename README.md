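# methmod — moderated EWAS analysis of smoking-associated methylation

`methmod` implements a complete moderation analysis for epigenome-wide
association studies (EWAS) of smoking: does a composite promoter-methylation
index at *MTHFR* (mMTHFR) — the rate-limiting enzyme of the methyl cycle —
change how strongly smoking remodels DNA methylation at smoking-associated
CpG loci? The package is aimed at researchers working with Illumina 450K-style
beta-value matrices who want per-locus interaction models, composite
methylation indices, and sign-consistency statistics in one tested pipeline,
plus a synthetic-cohort generator with known ground truth so every stage can
be validated without access to protected cohort data.

## The models

Methylation beta values are fractions in [0, 1], so each locus is fitted by
**beta regression**: y ~ Beta(μφ, (1−μ)φ) with

```
logit(μ_i) = b0 + bS·S_i + bM·M_i [+ bSM·S_i·M_i] + bmale·male_i + bage·age_i
```

where S is smoking status (0/1, or average consumption 0–6), M is the mMTHFR
index (the mean of z-scores of seven promoter-associated first-exon MTHFR
CpGs), and φ > 0 is a constant precision (Var y = μ(1−μ)/(1+φ)). Model 1
omits, Model 2 includes, the S×M interaction. Estimation is exact maximum
likelihood (quasi-Newton with analytic gradient plus Newton polishing);
inference is two-sided Wald from the observed information.

Each locus is classed **hyper** (smokers more methylated, bS > 0) or **hypo**
(bS < 0) from Model 1, and loci with significant Model 2 interactions are
cross-classified by direction × interaction sign into a 2×2 table. A
consistent moderator produces the opposite-sign pattern — hyper loci with
negative and hypo loci with positive interactions — which is tested with an
uncorrected Pearson chi-square (p computed in log space).

Sign-concordant significant loci are standardized and averaged into hypo and
hyper **methylation indices**, which are regressed by OLS on smoking, mMTHFR
and their interaction, controlling sex, age, diet, and the five
mononuclear-cell fractions estimated by reference-based constrained
projection (min ‖y − Rω‖² with ω ≥ 0, Σω ≤ 1). Interactions are explicated
as simple slopes at mMTHFR = mean ± 1 SD.

## Worked example

```python
import numpy as np
from methmod import (ContingencyTable2x2, GeneratorConfig, pearson_chi2,
                     row_proportions, run_pipeline)
from methmod.simulate import simulate_cohort

# Sign-consistency statistics from published direction x sign counts
table = ContingencyTable2x2(np.array([[7, 66], [205, 14]]))
stat, df, p = pearson_chi2(table)
print(f"chi2({df}) = {stat:.3f}, p = {p:.3e}")
print("row % =", np.round(row_proportions(table), 1).tolist())

# End-to-end run on a synthetic cohort (180 samples, 300 loci)
matrix, pheno, reference, truth = simulate_cohort(GeneratorConfig(seed=1))
report = run_pipeline(matrix, pheno, reference=reference).to_dict()
cont = report["contingency"]
print("counts =", cont["counts"])
print(f"sign-concordant fraction = {cont['sign_concordant_fraction']:.3f}")
for name in ("hypo_index", "hyper_index"):
    b = report["index_models"][name]["model2"]["terms"]["smoking_x_mmthfr"]
    print(f"{name} interaction b = {b['b']:+.3f} (p = {b['p']:.2e})")
```

prints

```
chi2(1) = 194.299, p = 3.664e-44
row % = [[9.6, 90.4], [93.6, 6.4]]
counts = [[3, 81], [177, 1]]
sign-concordant fraction = 0.985
hypo_index interaction b = +0.591 (p = 3.10e-64)
hyper_index interaction b = -0.906 (p = 1.61e-64)
```

The first two lines are the sign-consistency analysis of the published
counts: 90.4% of significant interactions at hyper-methylating loci are
negative and 93.6% at hypo-methylating loci are positive, an association far
beyond chance. The synthetic run shows the same structure measured end to
end: 98.5% of classified loci fall in the sign-concordant cells, and the
index-level interaction coefficients carry opposite signs (hypo +, hyper −)
— lower-mMTHFR subjects show an exaggerated methylation response to smoking
in both directions.

## Command line

`methmod simulate|qc|deconvolve|scan|indices|report|run-all` wraps the same
library calls for file-based workflows; see `methmod --help`. Inputs are
plain TSV (probe × sample betas, detection p-values, beadcounts), CSV
phenotypes, and a newline-separated locus list.

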