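# Methods

This note documents the statistical models the package implements, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Gene-based association tests on summary statistics

Per gene, let `z = (z_1, ..., z_m)` be the GWAS Z-scores of the `m` retained
variants and `R` the LD (Pearson dosage correlation) matrix from a reference
panel. Under the null, `z ~ MVN(0, R)`. Three statistics are computed:

* **Sum (burden) test**: `B = sum z_j`, null `B ~ N(0, 1'R1)`,
  `p = 2*Phi(-|B|/sqrt(1'R1))`. The null variance `1'R1` follows directly
  from the MVN null. Most powerful when effects share sign and size.
* **Squared-sum (SKAT-type) test**: `Q = sum z_j^2`; the null is the
  weighted chi-square(1) mixture with weights the eigenvalues of `R`.
  Robust to mixed effect directions.
* **Adaptive (omnibus) test**: `Q_rho = (1-rho) Q + rho B^2` for `rho` on a
  grid in [0, 1] (default `{0, 0.1, ..., 1}`, 11 points; configurable —
  results at other grids are exposed through the argument, not guessed).
  Each `Q_rho` is a mixture with weights `eig(A_rho R)`,
  `A_rho = (1-rho) I + rho 11'`. The reported statistic is the minimum
  per-rho p-value, calibrated for the minimum-taking (below). Ties in the
  minimizing rho break toward the smaller rho.

### Weighted chi-square mixture tails

`mixture_tail` inverts the characteristic function (Imhof's formula). The
integrand is analytic and oscillates with asymptotic half-period `2*pi/q`,
so the phase-curved head is integrated by Gauss–Legendre panels placed
equi-spaced in total phase variation (≤ ~pi/2 per panel, order 24, with an
order-17 re-evaluation as the error estimate), and the oscillatory tail is
summed over half-period chunks (order 12, batched) with Euler acceleration
of the alternating series. Verified against scaled chi-square closed forms
to ~1e-12 absolute. Below tail mass 1e-10 a Lugannani–Rice saddlepoint
approximation takes over (far-tail relative error well under the absolute
tolerances that matter here). A single positive weight uses the exact
scaled-chi-square closed form. Eigenvalues within -1e-10 of zero are
clamped to zero (numerical noise on near-singular `R` after pruning);
larger negative weights raise an error.

Quantiles invert the tail by bracketing bisection started from a
moment-matched (Liu-type) noncentral chi-square approximation.

### Calibration of the minimum p-value

`calibrate_min_p` computes `P(min_rho p_rho <= t_min)` under `z ~ MVN(0,R)`
analytically, so genome-wide-scale p-values (~1e-9) are reachable where
Monte Carlo is not. Decompose `z = w B + eps` with `w = R1/(1'R1)`,
`B = 1'z ~ N(0, 1'R1)`, and `eps` independent of `B`. Then every
`Q_rho = (1-rho) kappa + tau(rho) B^2` with `tau(rho) = rho + (1-rho) w'w`
shares the single residual form `kappa = eps'eps + 2B w'eps`; given `B = b`
the joint acceptance region over the grid is one upper bound on `kappa`
(the grid point `rho = 1` contributes a direct bound on `|b|` instead).
The conditional law of `kappa` is approximated by a scaled chi-square
matched to its first three cumulants
(`c1 = tr(S)`, `c2 = 2 tr(S^2) + 4 b^2 w'Sw`, `c3 = 8 tr(S^3)` with
`S = cov(eps)`); the approximation is exact whenever the burden direction
is an eigenvector of `R` (identity or exchangeable LD), because the
cross-term `w'Sw` then vanishes and `kappa` is a central mixture. The
survival probability is integrated over `b` by adaptive quadrature (the
integral is written in survival form so no precision is lost at small
p). If the quadrature does not converge, a fixed 96-node Gauss–Legendre
evaluation of the same integrand is used and the result is flagged
(`calibration_fallback`). The result is clipped into the exact Bonferroni
sandwich `[t_min, min(1, t_min * |grid|)]`.

Monte-Carlo checks (10^6 draws of the full min-p statistic) agree within
one MC standard error on identity, pairwise, and exchangeable LD at
m ≤ 5; over 2000 simulated null genes all three p-values pass a
Kolmogorov–Smirnov uniformity test at the 1% level.

## Summary-statistic QC

Retained variants are autosomal (chromosomes 1–22), single-base biallelic,
not strand-ambiguous (not {A,T} or {C,G}), have imputation INFO ≥ 0.9
(INFO = 0.9 is retained since the rule removes scores *below* 0.9; missing
INFO fails the filter, conservatively — the QC report makes this visible),
and carry unique rsIDs (every copy of a duplicate is removed; keeping one
would be a guess). Removals are attributed to the first failing rule in the
order: autosome → biallelic/ACGT → strand-ambiguous → INFO → duplicate
rsID. The order affects only the per-rule counts, never the retained set.
`Z = log(OR)/SE(log OR)` with the natural logarithm.

## Gene windows, harmonization, LD, pruning

A gene's window is its transcription span ±1000 bp (both ends inclusive;
configurable). Coordinates are 1-based inclusive on hg19-style annotation;
the numeric start/end are used regardless of strand (whether "transcription
start" should mean `tx_end` for minus-strand genes is ambiguous in general
annotation; the numeric convention is deterministic). Variants match the
panel by rsID first, chrom:pos as fallback; an rsID whose position
disagrees is dropped with a reason. Alleles equal to the panel's (alt, ref)
in order keep their Z; (ref, alt) flips the sign; anything else drops the
variant. LD is the Pearson correlation of panel dosages; zero-variance
variants are an error (and are dropped with a reason during set assembly).
Pruning removes, iteratively, the later-position member of the
lexicographically smallest pair with `r >= 1 - 1e-8`; only `r = +1` pairs
are pruned (`r = -1` pairs are retained — the pruning rule is stated for
positive perfect correlation, and a sign-flipped duplicate is not
redundant for the burden statistic). Genes with fewer than 2 surviving
variants are dropped. Genes may overlap; a variant can serve several genes.

## Dichotomized-expression logistic model

Per gene, counts are split at the sample median (value = median goes to
"low"); the analysis-set median is recomputed for subset analyses, e.g.
white-only, which is the self-consistent choice. The diagnosis is regressed
on age at death (years), sex (male = 1), race (white = 1, non-white
reference, single binary indicator), PMI (hours), and the high-expression
indicator; the white-only variant drops race. Newton MLE with relative
tolerance 1e-10; constant predictors raise a degenerate-predictor error and
(quasi-)complete separation an explicit non-estimable error naming the
term. Per-term Wald `z = beta/se`, `p = 2*Phi(-|z|)`. Over 200 replicates
at n = 200 drawn from this very model, 95% Wald intervals cover the true
expression coefficient at a rate inside [0.90, 0.99].

## Negative-binomial count model

Genes with total count across all samples < 10 are excluded (the customary
pre-filter reading of "counts at least 10"; configurable). Size factors are
median-of-ratios over genes with all-positive counts, normalized to
geometric mean 1, with an optional positive-entries-only pseudo-reference
for sparse matrices. Per gene, an NB log-link GLM of counts on diagnosis
with log-size-factor offset; dispersion by method of moments within
diagnosis groups (small-sample corrected, floored at 1e-8); Wald test on
the diagnosis coefficient; log2 fold changes; BH adjustment over retained
genes. The Wald statistic is referred to a t distribution with residual
degrees of freedom (n - 2): with a per-gene plug-in dispersion the normal
reference is anti-conservative at n ~ 40 (measured type-I ~0.068 at
nominal 0.05 over 2000 null genes; ~0.05 with the t reference). When one
diagnosis class has all-zero counts the fit uses a half-count
pseudo-observation, the LFC is clamped to ±10, and the row is flagged.

This stage is deliberately a *minimal* NB workflow: per-gene dispersions
are not shared or shrunk across genes, so at tiny designs (3 vs 3) it has
much less power than tools that moderate dispersion genome-wide. Its
acceptance surface is property-based (null calibration, Poisson-limit
agreement), not any published table of p-values.

## Two-sample Mendelian randomization

Per tissue, the top eQTL's exposure effect is paired with the same SNP's
GWAS outcome effect on the log-odds scale (consistent with
`Z = log(OR)/SE`; using the OR scale directly would bias the ratio).
Outcome allele order reversed relative to the exposure flips the outcome
beta (and frequency). Palindromic variants are kept only when allele
frequencies are known on both sides, both minor-allele frequencies are
below 0.42 (the conventional inferability limit; no value is stated for
the original workflow), and the orientations are concordant; otherwise the
tissue is dropped with a reason and does not count toward the Bonferroni
denominator. The causal estimate is the Wald ratio
`beta_out/beta_exp` with first-order delta-method SE `se_out/|beta_exp|`
(the standard single-instrument default, ignoring exposure-side noise;
this under-covers slightly when instruments are weak — measured 94.3%
coverage at simulated instrument strength ~0.5 ± 0.1 with se 0.05).
Tissues are flagged at `alpha / n_tested`.

## Synthetic-data generator

The generator produces every input with exact ground truth; its defaults
are the study conditions the pipeline is verified under.

* **Reference panel**: 503 samples (the size of a phase-3 European
  reference panel), one exchangeable-LD block per gene. Haplotype alleles
  copy a gene-shared draw with probability `sqrt(rho)`, which makes the
  pairwise dosage correlation exactly `rho` in expectation; the construction
  requires a shared per-gene MAF, drawn U(0.05, 0.5). Default block
  `rho = 0.5`, 4–12 SNPs per gene spaced 150 bp.
* **Summary statistics**: null genes draw `z ~ MVN(0, R_sample)` on the
  panel's sample LD; signal genes add a constant per-SNP mean shift
  (default 0.8 for power properties; 4.0 is used as the "strong" injected
  signal in end-to-end recovery runs, chosen to put genes clearly past a
  500-gene Bonferroni threshold). OR and SE are back-filled from z (SE
  U(0.02, 0.05), typical of large case-control meta-analyses), so
  `log(OR)/SE` reproduces z exactly — the association modules consume only
  `(z, R)`, and generating at the Z level makes truth exact. INFO is drawn
  U(0.85, 1.0) so the 0.9 filter actually removes rows; a configured number
  of strand-ambiguous rows and duplicate-rsID pairs is injected with clean
  INFO so each lands in its intended QC counter. About 20% of rows report
  the other allele as effect allele (with consistently negated z) to
  exercise harmonization.
* **Counts**: NB draws with log-normal base means around 25 (the scale of
  the focal gene in the motivating cohorts), dispersion 0.1, default
  design 20 cases / 19 controls, DE genes at log2 fold change 1.17. With
  covariate linkage enabled, diagnosis is drawn from the dichotomized-
  expression logistic model itself (coefficients: age -0.01/yr, sex(male)
  0.02, race(white) 2.71, PMI 0.11/hr, high expression 2.58; intercept
  -2.5 keeps arms roughly balanced), and the focal gene's counts are built
  from disjoint low/high ranges around the median so the split reproduces
  the designed indicator exactly.
* **MR instruments**: 30 tissues, true causal effect `theta = 0.1`,
  exposure effects N(0.5, 0.1^2) with se 0.05, outcome noise se 0.02;
  swapped-allele rows (recoverable) and palindromic rows with eaf 0.45
  (must be dropped) are injected.

What the generator does **not** emulate: realistic haplotype structure or
recombination (exchangeable blocks are enough to exercise eigen-structure,
pruning, and calibration, but not long-range LD), population
stratification, genotype imputation error beyond the INFO column,
library-size and GC biases in counts, batch effects, or pleiotropy in MR
instruments. Passing tests therefore demonstrate correctness of the
statistical machinery under its stated model, not robustness to
real-data artifacts outside it.

## Problem sizes used in the checked runs

Null uniformity uses 2000 simulated genes; Monte-Carlo oracles use 10^6
draws at m ≤ 5; logistic recovery uses 200 replicates at n = 200; NB null
calibration uses 2000 genes at the 20/19 design; MR recovery uses 1000
replicate instruments; the end-to-end discovery run uses 500 genes with 3
injected signal genes. These sizes give the property checks comfortable
statistical resolution (e.g. binomial 99% CIs of ±0.013 on a 5% rate) on a
single CPU.

## Other conventions and edge cases

* Replication p-values just above alpha (up to 1.25x) are flagged
  "near boundary" and reported verbatim.
* Empty QC output, empty gene collections, and tissues dropped in
  harmonization are legal results, not errors; manifests record per-stage
  counts and output digests so reruns are byte-comparable.
* `bonferroni_threshold(n, alpha) = alpha/n` with `n >= 1` enforced.
* All generators are pure functions of `SimConfig` (seed-deterministic).

## Known limitations

* The min-p calibration's conditional moment-match is approximate for
  general (non-exchangeable) LD; the error is far below Monte-Carlo
  resolution in the checked regimes but has no uniform bound.
* The NB stage's per-gene dispersion makes 3-vs-3 designs severely
  underpowered (by design, it is a minimal workflow).
* LD from a reference panel assumes the panel matches the study
  population; nothing in the package can detect mismatch.
* Single-instrument MR inherits all standard Wald-ratio caveats (no
  pleiotropy diagnostics, first-order SE).
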