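# Methods

## Data model

A trial is a balanced set of replicate-level records (genotype,
environment, replicate, yield in t/ha) laid out as a randomized complete
block design within each environment. All decompositions consume the
complete G×E matrix of cell means; missing cells are a hard error — AMMI
and GGE require a full two-way table, and imputation is a modelling choice
this package deliberately does not make. Label matching is exact
(whitespace-stripped, case-sensitive); known spelling variants of the
bundled trial's labels are available in alias tables
(`trial_data.ENVIRONMENT_ALIASES`/`GENOTYPE_ALIASES`) rather than applied
silently. The bundled matrix uses one canonical spelling per label
("Daro Lebu", "Yabello", "Ga'ambo 2", "ETBW 9578").

## ANOVA partition

With cell means Ȳ_ij and r replicates, the treatment partition is

    SS_G   = E·r·Σ_i (ḡ_i − μ)²
    SS_E   = G·r·Σ_j (ē_j − μ)²
    SS_GEI = r·Σ_ij (Ȳ_ij − ḡ_i − ē_j + μ)²

Percent explained is taken over SS_G + SS_E + SS_GEI (not the grand total),
so the three shares sum to exactly 100; replication and error do not belong
in a variability-attribution denominator and are unavailable from means
anyway. With replicate-level data the combined table adds
replication-within-environment (df E·(r−1)) and pooled error rows, and F
tests genotype, environment and interaction against the pooled error MS.
Degrees of freedom follow the design: G−1, E−1, (G−1)(E−1). For the
bundled 12×9×2 trial that is 11/8/88 — the published table's df column is
internally inconsistent with its own design and is not reproduced.

Per-environment LSD = t(1−α/2, df_err)·√(2·MS_err/r) and
CV = 100·√MS_err/mean come from each environment's own RCBD; both need
replicate-level data, so on the bundled means-only matrix they are
exercised on synthetic trials instead. The homogeneity check that licenses
pooling environments is Bartlett's test computed from per-environment
(error variance, df) summaries; a raw-sample variant offers Levene's test
for heavy-tailed residuals. Bartlett is the classical pre-combined-ANOVA
choice; nothing in the pipeline depends on which is used.

## AMMI

The double-centered matrix Z is decomposed by SVD; all min(G−1, E−1) axes
are computed, with per-axis share 100·λ_n²/Σλ². Scores use **symmetric
scaling** (both sides carry √λ_n): the bundled trial's published score
columns satisfy Σ_i score² ≈ λ_n, which identifies that convention, and it
makes the genotype–environment score product equal the axis's interaction
contribution. SVD signs are arbitrary; per axis the sign is fixed so the
largest-magnitude environment score is positive, and comparisons with
published scores are sign-relative. Axis significance uses Gollob degrees
of freedom G + E − 1 − 2n with MS tested against pooled error when
replicate data exist; with means-only input the F column is flagged
unavailable rather than guessed. Everything is computed on the cell-mean
scale; replicated-scale SS (comparable with the combined ANOVA) are r·λ_n².

ASV uses the weight w = SS_IPCA1/SS_IPCA2 = λ₁²/λ₂² from the fitted
decomposition (≈ 1.85 on the bundled trial). The published ANOVA table's
printed axis SS imply w ≈ 1.67, but they are inconsistent with the
published scores and ASVs, which back-solve to w ≈ 1.85 — the fitted-w
convention reproduces the published ASVs to within 0.3%. GSI sums the ASV
rank (ascending) and the mean-yield rank (descending); ties get average
ranks (none occur in the bundled trial); the stability table is sorted by
GSI ascending, ties broken by yield.

## GGE

The environment-centered matrix (zero column means) is decomposed by SVD
with the same sign convention; scaling modes `symmetric` (default),
`genotype` and `environment` are supported, and no column standardization
is applied by default (the trials share units; a flag enables it). The AEA
is the direction of the mean environment score vector. Representativeness
is the angle to the AEA, discrimination the vector length.

Which-won-where: the convex hull of the genotype markers, with rays from
the origin perpendicular to each hull edge. The sector between the normals
of a vertex's two adjacent edges is that vertex's normal cone, so the
vertex genotype maximizes the inner product — and hence the rank-2
reconstruction — for every environment direction in the sector; this makes
the construction independent of the scaling mode and checkable against a
brute-force argmax oracle, which the test-suite does. Environments exactly
on a ray join the counter-clockwise sector (a measure-zero tie-break).
Collinear genotype configurations (interaction rank < 2) are a geometry
error, not a silent answer.

## Synthetic trials

The generator draws from exactly the model AMMI fits:
Y_ijr = μ + g_i + e_j + Σ λ_n u_ni v_nj + b_jr + ε_ijr, with effects
re-centered to sum exactly to zero and score vectors Gram–Schmidt
orthonormalized against the ones vector — so the realized λ, u, v are
precisely what a noise-free fit must return, and closed-form treatment SS
(`ground_truth_ss`: SS_GEI = r·Σλ²) are available for exact ANOVA checks.
One seeded generator stream drives all draws; identical specs give
identical datasets. Yields are truncated at zero (physical floor); default
parameters keep truncation negligible. Defaults mirror the bundled trial's
scale: G=12, E=9, R=2, μ=3.14 t/ha, σ_g=0.23, σ_e=0.93, λ=(2.9, 2.1, 1.6)
(the fitted spectrum of the real matrix), σ_err=0.49 (its residual SD),
σ_block=0.1. What the generator does not emulate: heteroscedastic error
beyond an optional per-environment scale, spatial field trends, missing
plots, or season structure — so passing recovery tests demonstrate
correctness of the estimators under the stated model, not robustness to
real-world messiness.

Parameter-recovery checks run in the small-noise regime (σ_err = 0.05
against λ = (2, 1), 50 seeds), where the mean fitted singular values sit
within three standard errors of truth. At realistic noise the fitted
singular values carry the well-known upward inflation of sample singular
values (order σ²·(G+E)/λ on the cell-mean scale), which is a property of
the estimator, not a bug; the null-structure test covers the opposite
regime, comparing the fitted leading-axis share under zero interaction with
a plain Monte-Carlo SVD of double-centered noise.

## Known published-table discrepancies

Reanalysis of the bundled matrix reproduces the published environment SS
exactly (161.29), the axis shares (45.5/24.7), all twelve ASVs within
0.3%, the hull vertex set, and the Ardi mega-environment. Four published
statements do not follow from the published matrix itself:

1. **Fentale 1 ⇄ Fentale 2 row swap.** The published stability table's
   score/ASV rows for these two varieties are exactly exchanged relative
   to what the published yield matrix implies (the two ASVs, 0.4103 and
   0.4113, differ by only 0.24%). Recomputation therefore gives
   GSI(Fentale 1) = 5 and GSI(Fentale 2) = 7, not the printed 4 and 8.
   The selection-index ordering of the top quartet is unaffected.
2. **Representativeness.** From the matrix, Girja — not Sewena — has the
   smallest AEA angle under every scaling; Sewena's vector is so short
   (0.09) that its angle is numerically meaningless. The published text is
   also internally contradictory about which environment is most
   discriminating; the computed ranking (Daro Lebu longest vector) is
   reported without arbitration.
3. **Sector count.** The environments occupy five sectors, not four: Delo
   Mena's rank-2 winner (Amibara 2) beats Sewena's (ETBW 9578) by
   0.0037 t/ha — below the 0.005 rounding of the published means — so the
   published four-sector grouping is within rounding noise but not what
   the printed matrix yields.
4. **Published df column and axis-SS/% mismatch** (see above); the design
   df and the recomputed shares are used.

The acceptance tests assert the explicitly published values for 1–3 as
printed and are expected to fail there, documenting the discrepancy rather
than tuning the pipeline to reproduce misprints.

## Numerical choices

SVD via LAPACK (`numpy.linalg.svd`); singular values below ~1e-8 of the
leading one are treated as numerically zero in geometry guards (hull
collinearity, zero-length AEA) because symmetric scaling takes square
roots, amplifying machine-epsilon residuals to ~1e-8. Bartlett's statistic
is clamped at zero against round-off at exact equality. Ranks use average
tie-handling throughout. Problem sizes in tests and drivers (matrices up
to 12×9, 50-seed recovery loops) keep the full suite and drivers in the
tens of seconds on one core.
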