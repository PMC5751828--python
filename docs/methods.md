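# Methods

This note documents the models, numerical choices, and limitations of the
`nichepair` pipeline in the package's own terms.

## Data model

Abundance tables are samples x taxa matrices tagged with site (`NS` for
anterior-nares swab, `NPA` for nasopharyngeal aspirate) and mode (`counts`
or `proportions`; proportions rows must sum to 1 within 1e-9).  A
`PairedCohort` aligns exactly one sample of each type per subject and all
NS/NPA joins go through subject ids, never row positions.  OTU tables
collapse to genus by column summation; unassigned OTUs route to a reserved
`Unclassified` genus so read mass is conserved (it competes in top-genera
ranking like any other genus).  Rarefaction is multivariate-hypergeometric
subsampling without replacement; the default depth is the minimum retained
row sum after dropping samples below a 1000-read floor, and samples below
depth are dropped and reported rather than silently kept.

The "top genera" are the union of each site's 10 most abundant genera by
overall abundance (sum of relative abundances over samples), ordered by
combined NS+NPA overall abundance; ties break lexicographically so the
list is deterministic.

## Synthetic cohort generator

The generator is the package's substitute for the never-deposited cohort
and defines the conditions every simulation-based check runs under:

* 815 subjects across 17 collection hospitals (multinomial-uniform site
  assignment), 15 focal genera.
* Six NS dominance profiles with cohort weights 0.445 (*Staphylococcus*),
  0.144 (mixed), 0.134 (*Corynebacterium*), 0.130 (*Moraxella*), 0.075
  (*Enterobacter*), 0.072 (*Haemophilus*); four NPA profiles
  (*Moraxella*, *Streptococcus*, *Haemophilus*, mixed).  Per-profile
  compositions are Dirichlet draws whose means for the dominant genus
  mirror the observed cluster means (0.48–0.78).  The total Dirichlet
  concentration is 8: this keeps heavy-tailed within-profile variation
  (dominant-share SD ~ 0.14) while leaving the planted six-profile
  structure recoverable by distance-based clustering, which is what the
  planted-recovery experiments require.  A concentration matched naively to
  the published within-cluster SDs (~0.35) would make the "profiles"
  mostly unrecoverable even in principle, because those SDs already include
  the original study's own cluster misassignment.
* Cross-site coupling is a row-stochastic matrix P(NPA profile | NS
  profile): 0.80 same-genus coupling for the *Haemophilus* and *Moraxella*
  NS profiles, and a common diffuse row (0.32/0.30/0.16/0.22 over the four
  NPA profiles) from the *Staphylococcus*, *Corynebacterium*,
  *Enterobacter* and mixed NS profiles — the qualitative mapping in which
  high-*Staphylococcus* nasal samples spread over all nasopharyngeal
  profile groups.
* Sequencing depth is negative binomial (mean 10,000, dispersion 5,
  floored at 1,500 so no paired sample is lost to rarefaction); counts are
  multinomial given the composition.
* Eleven clinical covariates are drawn independently of profile and site
  from simple documented marginals (age ~ discretized gamma with median
  ~ 4 months; binary covariates Bernoulli at cohort-realistic rates;
  race/ethnicity and virology categorical).
* Intensive-care use follows
  `logit P = -2.75 + offset(NS profile) + (-0.04) age + 0.40 abx_prehosp + u_site`,
  `u_site ~ N(0, 0.5^2)`.  Profile offsets are the logs of the target
  unadjusted odds ratios (6.2 for *Haemophilus*-dominant vs the
  *Moraxella*-dominant reference at 0; 2.54, 3.75, 4.51, 3.86 for the
  others), so the planted conditional OR is exact and the marginal crude OR
  is only mildly attenuated (covariate effects are small and independent of
  profile).  Length of stay is negative binomial with profile-shifted mean
  (4.2 days for *Haemophilus*-dominant, 2.2 otherwise, dispersion 3).
* Ground-truth labels, linear predictors and outcome probabilities are
  recorded per subject and never consumed by analysis code.

Random genus trees are ultrametric random-coalescence trees (exponential
height increments).  What the generator does **not** emulate: realistic
phylogenetic signal in composition (profiles are exchangeable with respect
to the tree), covariate–profile confounding, within-site compositional
batch effects, and sequencing error.  Passing recovery tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those real-data features.

## Diversity

Shannon entropy is reported in nats (the published medians, 0.58 and 0.90
at richness ~ 6–12, are only consistent with the natural-log scale).
Weighted UniFrac delegates to scikit-bio; inputs are rescaled to large
integer counts first because scikit-bio truncates count vectors to
integers, and UniFrac is invariant to the common scale.  The normalized
variant (values in [0, 1]) is the default so distances are comparable
across depths; the raw variant is available and on a star topology equals
the Manhattan distance between proportion vectors — a closed-form check
used in the tests.

## Concordance

The cross-site matrix correlates, across subjects, the NS abundance of
genus i with the NPA abundance of genus j; it is deliberately asymmetric.
The permutation test statistic is the mean over subjects of the Spearman
correlation between the subject's NS and NPA top-genera vectors.  The null
re-assigns NPA samples to subjects by uniform shuffles (fixed points
allowed), and `p = (1 + #{null >= observed})/(1 + n_perm)` — never exactly
zero.  Subject pairs where either vector is constant are dropped with an
audit count, identically under every permutation.  Internally the test
ranks each sample vector once and evaluates all pairings through a single
standardized-rank cross-product matrix, so 10,000 permutations on 815
subjects take well under a second.

## Co-occurrence network

Candidate edges are cross-site (bipartite) genus pairs surviving a 10%
prevalence filter per site (present in >= ceil(0.10 n) samples; boundary
inclusive).  Four metrics score each pair; the Kullback-Leibler metric
pseudocounts both profiles with 1e-6 and renormalizes before the
symmetrized divergence.  Significance uses a permutation null (the NPA
profile shuffled across subjects, n_null = 1000 by default) with a
two-sided p centered on the pooled mean of {observed, nulls} so the
observed draw is exchangeable with the null draws and the p-value is
level-valid; measured type-I error is 4.6–4.9% per metric at nominal 5%.

A deliberate design point: the ReBoot-style renormalization — re-closing
each composition after the shuffle — exists to preserve compositional
coupling when **both** genera live in the same composition.  Cross-site
pairs do not: NS and NPA are separate simplices, so the plain shuffle is
already the exchangeable null, and renormalizing only distorts it
(measured 9–12% type-I error for the dissimilarity metrics).  The package
therefore uses the plain permutation null for cross-site edges and keeps
the renormalized variant behind `renormalize=True` for within-site use.

Consensus rule: >= 2 metrics with p < 0.05 and a unanimous sign
(correlations vote co-occurrence when positive; dissimilarities when the
observed value is below the null median).  Sign conflicts drop the edge
with an audit record.  No multiple-testing correction by default, matching
the replication target; per-pair seeds derive from hashes of the genus
names and subjects are canonicalized by id, so the network is invariant to
row and column order.

## Clustering

PAM is the classical BUILD (greedy objective-minimizing medoid addition)
plus SWAP (best improving single exchange, repeated to convergence), fully
deterministic with ties broken toward the lowest sample index.  Note that
BUILD+SWAP is a single-swap local search: on small random instances it
attains the global optimum about 9 times in 10, and on the exceptions it
returns the same locally optimal objective as R's `cluster::pam` — the
test suite checks exactly this (never below the global optimum, global in
>= 80% of instances, single-swap local optimality always, agreement with
`cluster::pam`).

Average silhouette width follows the standard (b - a)/max(a, b) with
singletons contributing 0.  The gap statistic embeds the dissimilarity
matrix by classical MDS (positive-eigenvalue axes), draws 50 uniform
reference sets in the embedding's bounding box, uses the PAM objective as
W with log(W + 1e-12) guarding zero dispersion, and selects the smallest k
with gap(k) >= gap(k+1) - se(k+1).  This is an approximation of the
original gap procedure necessitated by clustering dissimilarities rather
than points.  Silhouette is the primary selection criterion; replication
mode pins k = 10 (composite) and k = 6 (NS profiles) to mirror the study's
figures.

Profile naming: a cluster is `<Genus>-dominant` if the within-cluster mean
relative abundance of its top genus is >= 0.40 (published dominant-profile
means 0.48–0.78 sit above, the mixed profile's 0.29 below); ties break by
higher within-cluster prevalence, then lexicographically.

## Severity models

Crude odds ratios are exact 2x2 arithmetic with Woolf (log-scale Wald)
95% intervals; a zero cell is an error unless the Haldane +0.5 correction
is requested.  The fixed-effects logistic model is ML via statsmodels GLM
with reference-coded categoricals and complete-case filtering (missingness
reported); quasi-separation is flagged when fitted probabilities pin to
0/1 with |coefficient| > 10.  The primary length-of-stay dichotomization
is >= 5 days (>= 3 available).

The mixed model is a random-intercept logistic GLMM fitted by maximum
likelihood with adaptive Gauss-Hermite quadrature (25 probabilists' nodes;
per-site integrals centered and scaled at the conditional mode found by
Newton iteration; sites padded into a single vectorized layout).
Parameters are (beta, log sigma); Wald intervals come from the
finite-difference observed information.  The fit agrees with lme4's
`glmer` (nAGQ = 25) to ~ 0.02 on fixed-effect log-odds and ~ 0.03 on the
site SD in the cross-check test, and collapses to the fixed-effects fit as
sigma -> 0.  Parameter-recovery checks use Monte-Carlo 2.5–97.5 percentile
intervals of the replicate estimates; with only ~ 6 reference-profile
events per replicate, ML odds-ratio point estimates carry a visible
small-sample upward bias, which the percentile interval absorbs but a
mean +- SE check would not.

## Pipeline

Every random stage derives its seed as SHA-256(master seed, stage name)
mod 2^31, so re-running one stage cannot perturb another and results are
independent of stage order.  The run configuration is serialized verbatim
with a hash; a re-run with an identical configuration reuses the simulated
inputs.  If the configured reference profile is absent from a (small)
cohort's clustering, the severity stage falls back to the largest profile
and records the substitution in the summary.

## Problem sizes used in validation

Simulation-based checks run at the study scale of 815 subjects and 17
sites: 100 replicates for mixed-model parameter recovery, 10 seeds for
profile recovery (median ARI) and network edge recovery, 400–1000
replicates for null calibration at n_perm/n_null = 199.  The acceptance
script uses 20 mixed-model replicates and 10/5 seeds for the
clustering/network summaries.

## Known limitations

* The gap statistic's uniform-box reference is defined on an MDS
  embedding, not the original data space.
* The GLMM supports a single random intercept (collection site); no
  crossed or nested effects.
* Profile names are not deduplicated: two clusters can both be
  `Staphylococcus-dominant` when a dominant group splits.
* Crude-OR confidence intervals are Woolf; published intervals appear
  model-based and are not reproduced by 2x2 arithmetic.
* Whether the original analysis computed its concordance statistic over
  all shared genera or the top-genera restriction is not documented; the
  package defaults to top genera and exposes the alternative.
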