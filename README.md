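# metstab

Yield-stability analysis for multi-environment variety trials: combined
ANOVA, the AMMI model, ASV/GSI stability indices and GGE biplot geometry,
with a replicated-trial simulator for validating every stage against known
ground truth.

## The problem

Plant-breeding programs test candidate varieties across many locations
because genotype-by-environment interaction (G×E) makes the "best" variety
depend on where it is grown. Given a balanced trial of G genotypes in E
environments (R replicates in randomized complete blocks), the questions
are: how much of the yield variation is environment, genotype and
interaction; which varieties are both high-yielding and *stable*; and which
variety wins where, so the target region can be split into
mega-environments.

`metstab` implements the standard answer pipeline around the AMMI model

    Y_ij = μ + g_i + e_j + Σ_n λ_n α_ni γ_nj + R_ij

where μ is the grand mean, g_i and e_j zero-sum additive effects, and the
multiplicative terms come from the SVD of the double-centered matrix
Z_ij = Y_ij − ḡ_i − ē_j + μ (singular values λ_n, axis scores α, γ; the
interaction principal component axes, IPCA). Scores are reported with
symmetric scaling (each side carries √λ_n). On top of the fit:

* **ASV** (AMMI stability value): √[(w·IPCA1)² + IPCA2²] with
  w = SS_IPCA1/SS_IPCA2 — a genotype's weighted distance from the origin of
  the first two interaction axes; small = stable.
* **GSI** (genotype selection index): rank(ASV, ascending) + rank(mean
  yield, descending); small = stable *and* high-yielding.
* **GGE biplots**: the environment-centered matrix (genotype main effect
  plus G×E) decomposed by SVD; environment vector length measures
  discriminating ability, the angle to the average-environment axis (AEA)
  measures representativeness, and the convex-hull "which-won-where" view
  partitions environments into sectors sharing a winning vertex genotype.
* **Combined ANOVA**: SS partition with replication-within-environment and
  pooled error when replicate-level data are supplied, per-environment
  LSD/CV, and Bartlett's homogeneity-of-variance test.

A 12-variety × 9-location irrigated lowland bread-wheat trial from the
Oromia region of Ethiopia (2 replicates, cell means bundled as packaged
data) serves as the worked example throughout; `metstab.synthetic`
generates RCBD trials with controllable low-rank interaction for testing.

## Worked example

```python
from metstab import load_wheat_fixture, fit_ammi, partition_ss
from metstab.stability import stability_table

wheat = load_wheat_fixture()
print(partition_ss(wheat.means, wheat.replicates)[["source", "SS", "pct_explained"]])
fit = fit_ammi(wheat.means, reps=wheat.replicates)
print(fit.pct_explained[:2])
print(stability_table(fit).head(4).round(4))
```

prints

```
            source          SS  pct_explained
0        Genotypes   10.221620       4.892796
1     Environments  161.291204      77.205473
2     Interactions   37.398796      17.901731
3  Treatment total  208.911620     100.000000
[45.54980522 24.66436319]
           mean_yield   ipca1   ipca2     asv  r_asv  r_ysi   gsi
genotype
Fentale 1      3.6222  0.1433 -0.3148  0.4113    4.0    1.0   5.0
Fentale 2      3.2389 -0.2182 -0.0765  0.4103    3.0    4.0   7.0
Pavon 76       3.1111  0.0851  0.3036  0.3418    1.0    7.0   8.0
ETBW 9578      3.3722 -0.0652 -0.7359  0.7457    8.0    2.0  10.0
```

Environments dominate the trial (77% of treatment SS; the locations range
from 1.95 t/ha at Girja to 4.81 t/ha at Daro Lebu), the first two
interaction axes carry 70% of G×E, and the selection index puts Fentale 1,
Fentale 2, Pavon 76 and ETBW 9578 at the top — high-yielding varieties
whose interaction scores stay near the origin. Ardi (ASV 2.51) is the
extreme opposite: specifically adapted to the high-yield Daro Lebu/Bedeno
locations, which it wins in the which-won-where view.

The same pipeline is scripted step by step under `analysis/`
(`01_trial_overview.py` … `05_synthetic_validation.py`; each writes its
tables and figures to `results/`), and is available from the shell:

```
metstab fixture --out results/fixture      # bundled trial
metstab analyze trial_long.tsv             # your replicate-level data
metstab analyze-means matrix.tsv --reps 2  # your means matrix
metstab simulate --seed 1                  # synthetic RCBD trial
```

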