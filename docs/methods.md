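# Methods

## The problem

Single-locus (marginal) association tests dominate case-control GWAS
analysis, and two-locus methods mostly look for interaction (epistasis).
Neither sees a third pattern: two SNPs in linkage disequilibrium whose joint
effects on disease risk are strong but of opposite sign, so that the
correlation cancels their marginal effects.  In regression terms, if the
joint model is `logit P(Y=1) = b0 + b1*X1 + b2*X2` and the predictors have
correlation rho, the expected marginal slope of X1 is `b1 + b2*rho`; with
`b1 = -b2` and rho near 1 the marginal slope is near zero no matter how
large `b1` is.  This cancelation is called unfaithfulness: the marginal
effects do not faithfully express the joint effect.  No interaction term is
involved — the pattern is invisible to both single-locus scans and product-
term epistasis tests.

`hiddenpair` detects the two-locus version of this pattern: SNP pairs where
*both* single-locus tests are insignificant but the joint two-locus test is
strongly significant.

## Models and statistics

For a pair (X_p, X_q) with genotypes coded as minor-allele counts {0, 1, 2}
and phenotype Y in {0 control, 1 case}, all information used by the tests is
in the 3x3x2 contingency table of cell counts n_ijk.  Cell counts are
modelled as independent Poisson (the log-linear formulation); three nested
log-linear models correspond exactly to the logistic models of interest:

| log-linear model                         | logistic equivalent                     |
|------------------------------------------|-----------------------------------------|
| block independence `[XpXq][Y]`            | intercept-only M0                        |
| partial independence `[XpXq][XpY]`        | one-SNP categorical M1 (M2 for q)        |
| homogeneous association `[XpXq][XpY][XqY]`| two-SNP additive-in-factors M12          |

The correspondence means doubled log-likelihood differences between the
log-linear fits equal the logistic likelihood-ratio statistics, but the
log-linear side is far cheaper: block and partial independence have closed
forms

    mu_B[i,j,k] = n_ij. * n_..k / n
    mu_P[i,j,k] = n_ij. * n_i.k / n_i..   (locus p; symmetric for q)

and the homogeneous association model is fit by iterative proportional
fitting (IPF): starting from mu = 1, cycle scaling updates that match the
three two-way margins {n_ij., n_i.k, n_.jk} until the largest cell change in
a cycle is below tolerance.  The test statistics are deviances

    joint:    G2 = 2 (L_MH - L_MB),   referred to chi-square
    marginal: G2 = 2 (L_MP - L_MB),   df = 2

with 0*log(0) taken as 0 throughout.

**Degrees of freedom for the joint test.**  The homogeneous association
model adds (I-1)(K-1) + (J-1)(K-1) = 4 free parameters over block
independence with 3-level genotype factors, so the default reference is
chi-square(4); simulation under the null confirms this calibration (the
type-I error test in the acceptance suite).  A `joint_df` option exists for
users who want the alternative 2-df convention; the statistic itself is
unaffected.

**Zero margins.**  A zero two-way margin (e.g. no double minor homozygotes
observed) makes the IPF update 0/0.  The affected fitted cells are set to
zero on the first cycle and stay frozen; this is exactly the limiting MLE.
Degrees of freedom are *not* reduced for frozen cells — a deliberate
simplification matching fixed-df testing; for heavily degenerate tables
(perfectly collinear SNPs) the result carries a `zero_margin` flag so users
can treat those pairs with caution.  No continuity correction or minimum
cell count is imposed; instead the scan excludes SNPs with minor-allele
count below 5 (configurable) from the pair stage.

**Numerics.**  IPF defaults: tolerance 1e-6 on the maximum absolute cell
change, 100 cycles maximum (3x3x2 tables typically converge in under 10).
Contexts that need the deviance itself converged to 1e-6 or better (the
logistic-equivalence checks) pass a tighter tolerance; convergence is
geometric, so this costs a few extra cycles.  Statistics are clipped at 0
against roundoff.  The logistic route uses IRLS with at most 50 Newton
steps, convergence on |delta loglik| < 1e-10, a 1e-8 ridge on the weighted
normal equations, and pivoted-QR detection of aliased (collinear) design
columns, which are dropped and reported.

## The two-step scan

1. **Marginal filter.**  Every SNP gets the 2-df single-locus G2 test on its
   collapsed 3x2 table.  P-values are adjusted over all L SNPs (Bonferroni
   or Benjamini-Hochberg, configurable) and SNPs with adjusted P at or below
   the marginal threshold (default 0.1) are *removed* — the scan looks for
   pairs without significant main effects.  A raw-threshold mode is
   available because reasonable analysts disagree about adjusting here.
   Monomorphic SNPs get P = 1 and are kept (then dropped at the pair stage
   by the minor-allele-count rule).
2. **Pair stage.**  All C(L', 2) pairs of surviving SNPs are joint-tested.
   P-values are adjusted with the exact multiple factor L'(L'-1)/2
   (Bonferroni) or step-up BH over all tested pairs.  Pairs at or below the
   joint threshold (default 0.1) are reported, sorted by adjusted P, with an
   optional minimum base-pair distance constraint applied to same-chromosome
   pairs (different-chromosome pairs have no defined distance and pass).

The pair stage is vectorized: per phenotype stratum, one-hot genotype
matrices give all pair tables by batched matrix products (a missing
genotype contributes an all-zero one-hot row, which implements per-pair
listwise deletion for free), and IPF runs on the whole (pairs, 3, 3, 2)
array at once.  All raw P-values are held in memory — a few MB up to ~10^3
kept SNPs, which covers the intended desk scale; a genome-scale streaming
variant is a known limitation, not implemented.

## The simulator

The generator exists to create data sets in which the ground truth is a
two-locus association masked by unfaithfulness, for power and type-I-error
studies.

* **Disease model.**  Odds of disease are multiplicative per minor allele:
  `odds(i, j) = alpha * theta^i * (1/theta)^j` with i, j the minor-allele
  counts at the risk and protective locus.  There is no interaction on the
  log-odds scale by construction, and on the diagonal (i = j) the effects
  cancel exactly.  Penetrance is odds/(1+odds).
* **LD.**  Haplotype frequencies for the causal pair come from the two
  minor-allele frequencies and D = sign * sqrt(r2 * p(1-p)q(1-q)); requests
  beyond the Lewontin bound raise an error reporting the achievable maximum.
  Individuals are random unions of two haplotypes (HWE), so the genotype
  correlation equals the haplotype r.
* **Calibration.**  Users specify population prevalence p(D) (default 0.1)
  and heritability h2 (default 0.02); (alpha, theta >= 1) are solved by
  nested Brent root-finding (alpha against the prevalence equation inside a
  theta search against the heritability equation) to residuals below 1e-10.
  Heritability is defined on the observed binary scale as
  `h2 = Var_G[p(D|G)] / (p(D)(1-p(D)))` — the standard variance-ratio
  definition for odds-table simulators, chosen here as the single
  heritability hook.
* **Sampling.**  Case-control data are drawn retrospectively: population
  individuals are generated, assigned disease by penetrance, and accepted
  until the case and control quotas (default 500/500) fill; a progress guard
  raises if penetrances make the design infeasible.  Null SNPs (default 98,
  giving 100-SNP panels) are independent binomial(2, maf) columns with MAFs
  uniform on [0.05, 0.5]; the causal pair sits at the two middle columns,
  all SNPs nominally on one chromosome at 10 kb spacing.  All randomness
  derives from a single (seed, replicate) pair via numpy's SeedSequence, so
  every data set is bit-reproducible.
* **What it does not emulate.**  Real LD is block-structured along the
  genome; here only the causal pair is correlated and all null SNPs are
  independent, which makes the null side of the scan cleaner than real data.
  No genotyping error, missingness, population stratification, or
  covariates.  Passing power/calibration tests therefore demonstrate the
  statistical machinery under the stated model, not robustness to real-chip
  artifacts — on real data the marginal filter and reported pairs inherit
  whatever QC the input received upstream.

**Power experiments** report, per disease model, the fraction of replicate
panels in which (a) either planted SNP passes the Bonferroni-adjusted
marginal test at level alpha (default 0.05), or (b) the planted pair appears
among the scan's reported pairs at joint threshold alpha.  Default grid:
r2 in {0.1, 0.3, 0.5, 0.7}, equal MAFs in {0.1, 0.3, 0.5}.

## Problem sizes used by the test and acceptance suites

Chosen to make each statistical claim measurable with comfortable margins on
a single core: 200 random tables for the logistic-equivalence sweep; 2000
replicates of n = 1000 for the null-calibration check (exact binomial 99%
acceptance band around 0.05); one 10^6-individual prospective cohort for the
prevalence round trip; 100 replicates of 100-SNP, 1000-sample panels for the
power comparison and the end-to-end scan check.

## Known limitations

* Asymptotic chi-square P-values only; no exact (permutation/Fisher)
  small-sample option.  Sparse tables rely on the zero-margin handling and
  the minor-allele-count exclusion.
* Pairs only; three-or-more-locus unfaithfulness is out of scope.
* No covariate adjustment or stratification; X-chromosome/haploid genotypes
  are not modelled.
* Input formats are text PED/MAP (binary BED is not read); phenotype coding
  must be declared explicitly.
* The df convention for the joint test is a genuine ambiguity in the
  literature this method comes from; we default to the parameter-count df=4
  (which simulation shows is correctly calibrated) and expose the
  alternative.
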