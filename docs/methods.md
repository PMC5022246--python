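# Methods

## The sire model and why it is the estimable one

Survival records exist only on crossbred daughters, dam identities are
unknown, and every cage holds five paternal half-sibs of one cross.  Under
that design the only estimable genetic signal is the *total* sire effect:
the sum of the sire's transmitted direct effect and the indirect effects his
daughters exert on their cage mates.  The package therefore fits

    y = Xb + Wc + Zu + e

with fixed batch, cross and house×row×level effects, a random cage effect
c ~ N(0, I σ²c) absorbing the non-genetic covariance of cage mates, and a
random sire effect u ~ N(0, K σ²u).  Direct and indirect components are
deliberately not separated — the design cannot identify them — and the total
additive variance is reported as σ²_AT = 4σ²u.  The phenotypic variance is
reported as σ²_P = σ²u + σ²c + σ²e: the published variance-component tables
for both layer lines obey this identity exactly (675 + 1403 + 10,350 =
12,428 for line BD), and the alternative 4σ²u + σ²c + σ²e is also exposed
(`sigma2_P_footnote`) for comparison.

Censored hens (alive at their batch's endpoint) enter the linear model at
the censoring-day value.  This is a deliberate modelling choice, not an
oversight: with a common censoring day across batches, survival analysis has
been found to offer no benefit over a linear model for this trait, and the
common-day trade-off (fraction censored versus fraction of data lost) is
itself a first-class computation (`censorcv.censoring_tradeoff`).

## REML

Variance components are estimated by average-information REML driven by the
mixed-model equations, with EM fallback and step-halving whenever an AI step
would leave the parameter space or decrease the restricted likelihood.  The
restricted log-likelihood is evaluated through the standard MME determinant
identity; the identity and the analytic gradient are unit-tested against a
direct dense-V evaluation, so the fast path is anchored to an independent
oracle.  Convergence is declared at a relative log-likelihood change below
1e-8; starting values are phenotypic-variance thirds.  Components collapsing
to zero are floored at 1e-8 of the phenotypic variance and flagged
(`vc.boundary`), never silently zeroed.  Approximate standard errors come
from the inverse AI matrix.  In balanced nested designs with unrelated sires
the estimates coincide with the expected-mean-squares ANOVA estimators
(tested); on censored-as-recorded data all components shrink relative to the
uncensored generative values, so parameter-recovery tests run without
censoring.

## Relationship matrices

* **A** by the tabular method (exact for inbred pedigrees); its inverse by
  Henderson's rules with Mendelian-sampling variances
  d_j = 1 − (a_ss + a_dd)/4 taken from the tabular diagonal, verified
  against dense inversion and a recursive-coancestry oracle.
* **G** by VanRaden's first method at observed allele frequencies, with
  missing genotypes imputed to the column mean 2p_j.  Centering at observed
  frequencies forces the off-diagonal mean to ≈ −mean(diag)/(n−1); tests
  assert that structural bias rather than pretending the mean is zero.
* **H⁻¹** by the single-step block augmentation with the blend αG + βA₂₂.
  The printed weights of the source analysis are α = 0.95, β = 2 − α = 0.05,
  and that convention is the default even though β = 2 − α makes the blend
  2A₂₂ (not A₂₂) when G = A₂₂ — i.e. it shrinks the genotyped block even in
  the no-information limit.  Whether this was intended cannot be decided
  from the text, so `beta_convention="complement"` (β = 1 − α) is available;
  under it, α → 1 with G = A₂₂ recovers H = A exactly (tested), and the
  pedigree and ssGBLUP fits return identical EBV.
* QC order is call-rate → MAF → HWE, with allele frequencies recomputed
  after the call-rate filter; MAF exactly at the threshold (2%) is excluded
  ("2% or less"), and the HWE statistic is the 1-df chi-square against
  p²/2pq/q² expectations.  The filter is idempotent (tested).
* The LD summary is Me = 1/var(G − A₂₂) over off-diagonal pairs, the
  effective number of independently segregating chromosome segments; the
  variance is the unbiased (ddof = 1) variance of the upper-triangle
  entries.

## Censored-rank cross-validation

Folds partition the genotyped sires that have daughter records; a fold's
sires form the validation set and their daughters are removed from training
(in the genotyped-only scenario, non-genotyped sires' daughters are removed
too).  Observed sire performance is the mean daughter rank after
fixed-effect correction, with every censored record assigned the mean of the
ranks above the top non-censored rank — the assign-random-ranks-then-average
procedure collapses to this deterministically, so no randomness is used.
Fold correlations are Spearman (Pearson on average-tie ranks) with
SE = (1 − r²)/√n; the pooled correlation is the correlation of
within-fold-centred ranks, which equals the residual correlation of a
bivariate fixed-fold-effect model with homogeneous residual covariance
(tested against a least-squares oracle).  EBV accuracy follows from the
path-coefficient identity ρ(A,Â) = ρ(Â,P̄)/ρ(A,P̄) with
ρ(A,P̄) = √(σ²u/σ²p̄).  Fold fits are BLUP solves at variance components
estimated once (or supplied), matching the practice of estimating parameters
once and cross-validating predictions.

## The synthetic-data generator

`simdata` emulates the study structure: a nested-mating pedigree (each sire
× `dams_per_sire` dams), gene-dropped biallelic SNPs with founder
frequencies uniform in [maf_low, maf_high] and free recombination (LD arises
from drift and family structure only), and daughter survival built from the
sire-model generative equation with batch-specific censoring and cages of
exactly five half-sib daughters of one cross.  Default variances are the
published scale (σ²u = 675, σ²c = 1403, σ²e = 10,350 days²).

Two architecture modes exist.  The default (`snp`) makes the sire effect a
sum of additive effects at the gene-dropped loci (weights scaled so the
founder variance is σ²u): effects then travel through actual alleles, and
genomic relationships among sires are informative about their effects — a
precondition for ssGBLUP to beat pedigree-BLUP, and the regime the source
analysis occupies.  The `infinitesimal` mode transmits effects through the
pedigree only (half-parental average plus Mendelian deviation); under it G
adds no information beyond A by construction, which is useful as a negative
control.  What passing tests on these data do *not* show: behaviour under
real LD structure (linkage maps, selection-generated LD), genotyping error,
or informative censoring — none of which the generator emulates.

The ssGBLUP-versus-pedigree directional property is tested at desk scale in
a deliberately high-LD regime (80 loci, so few effective segments and strong
realized-relationship signal), 120 sires over two generations with 40
daughters each and ~25–30% censoring; with weak LD the genomic advantage is
present but statistically invisible at this scale.

## The deterministic breeding-scheme engine

A selection-index engine in the SelAction tradition.  Candidates of each sex
carry information sources; index weights solve b = P⁻¹g; accuracies,
post-selection EBV variances and the candidate genetic variance are iterated
to a fixed point (relative change < 1e-10):

    σ²A(t+1) = ½σ²A0 + ¼(1 − k_m r²_m)σ²A(t) + ¼(1 − k_f r²_f)σ²A(t),

with k = i(i − x) from infinite-population truncation intensities.  The
parent-average source uses post-selection parental index variances
¼[(1 − k_m)σ²Î_m + (1 − k_f)σ²Î_f].  For the genomic scheme the recursion
runs on the 2×2 genetic covariance matrix of (survival, marker), the marker
being a fully heritable pseudo-trait with phenotypic variance
r_g²h²σ²_P — the value that makes the regression of true survival breeding
value on marker EBV equal one.

**Progeny-group structure.**  A progeny-tested sire's group of 40 daughters
is modelled as 8 full-sib families of 5, one cage per family, so the progeny
mean carries dam-family covariance (¼σ²A/8) and cage common-environment
covariance (σ²c/8, default σ²c = 1243.5 days², the mean of the two lines'
estimates) on top of the sire term ¼σ²A.  This structural detail matters:
with it the unselected parent-average accuracy converges to 0.448 and the
solved marker correlation to 0.53, matching the published calibration
(0.45, 0.53); treating the 40 progeny as plain half-sibs without a cage
term overstates the progeny-test accuracy and pushes ρ_PA to ≈ 0.49.

**Calibration.**  Step 1 computes ρ_PA in an unselected population
(selected proportions 100%).  Step 2 multiplies it by the cross-validated
ssGBLUP/pedigree accuracy ratio; ρ_PA is rounded to two decimals first,
matching the precision at which the ratio itself is known, so ratio 1.33
gives the target 0.45 × 1.33 = 0.60.  Step 3 bisects on r_g (tolerance
1e-4) until a candidate with a progeny-tested father *and* an own marker
record reaches the target in an unselected population — father plus marker,
no dam term, because the cross-validation sires had progeny-tested fathers
and the father's contribution must not be attributed to the markers.

**Response** per generation is σ_A,eq (i_m r_m + i_f r_f)/2, per year
divided by the mean generation interval (weeks/52; discrete generations).
Selected proportions (8%/8% traditional, 2%/8% genomic) drive intensities;
parent counts (20 sires, 400 dams, 20 dams/sire, 5+5 offspring/dam) drive
the inbreeding structure.  The two are numerically inconsistent in the
scheme definition itself (20/2000 ≠ 8%); the stated proportions are taken
as authoritative for intensity, the counts for family structure.

**Rate of inbreeding.**  ΔF = 1/(2Ne) with Ne from the variance of family
size (Hill's unequal-sex formula).  Family-size (co)variances are computed
from pairwise co-selection probabilities of sib indices — bivariate-normal
upper-orthant probabilities at the structural selected proportions, with
full-sib and paternal-half-sib index correlations derived from the
equilibrium index variance decomposition (a parent-average index makes
full-sib indices identical, correlation 1, so whole families are co-selected;
a fully heritable own marker record leaves only the Bulmer-depleted
between-family fraction, ≈ 0.07).  Zero-accuracy selection recovers
Wright's 1/(8N_m) + 1/(8N_f) within 10% (the residual gap is
binomial-versus-Poisson family sizes).  Known limitation: the formula
captures one generation of co-selection but not the persistence of
selective advantage over descendants, so it is accurate for own-record
schemes (genomic: engine 0.74 %/gen vs stochastic simulation 0.90 ± 0.14
and the published 0.75) but underpredicts schemes with extreme family
co-selection (traditional, engine ≈ 1.6 %/gen vs published ≈ 2.75).  The
direction of every comparison (traditional ≫ genomic > random) is
preserved and tested.

**Stochastic cross-check.**  `scheme.simulate_scheme` runs truncation
selection on own records (marker or phenotype) with explicit breeding
values, random union of the selected parents, hierarchical matings and
pedigree-tracked inbreeding.  At a consistent scaled configuration
(10 sires, 250 dams, structural proportions equal to the stated ones) the
engine's response and ΔF agree with the simulation within the replicate
standard errors; under a noise-only index the simulation reproduces
Wright's formula.  Progeny-testing schemes have no stochastic counterpart
(two-stage progeny testing is not simulated).

## Numerical choices and degenerate inputs

Fixed-effect design matrices use reference-level dummies with a pivoted-QR
rank guard for collinear small designs; factors with one observed level are
dropped (degenerate case: residuals are deviations from the mean).  Sources
with zero variance (a parent average before any ancestor carries an EBV)
get index weight zero rather than making P singular.  Orthant correlations
are clipped at ±0.9999, with the exact limit P = min(p_a, p_b) used for
effectively identical indices.  All-censored rank vectors collapse to the
common mean rank with a warning; path-coefficient accuracies above 1 are
clipped with a warning.  All simulation randomness flows from a single root
seed through named substreams, so every artefact is reproducible from the
seed alone.

## Problem sizes

The test suite runs at desk scale by design: REML parameter recovery uses
20 replicates of 150 sires × 15 daughters (uncensored), the directional
cross-validation comparison 20 replicates of 120 sires × 40 daughters with
80 loci, and the stochastic scheme cross-check 5 replicates × 9 generations
of a 10-sire/250-dam configuration.  These sizes were chosen to give the
relevant checks adequate power while keeping the whole suite around two
minutes; the deterministic engine itself runs the full published scheme
(2000 candidates per sex) in milliseconds.
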