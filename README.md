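# nichepair

Paired-site analysis of the infant upper-airway microbiome: do the easy-to-collect
anterior-nares (NS) swabs carry the same clinically relevant signal as the
deeper nasopharyngeal aspirates (NPA)?

The package reimplements, as a tested pipeline over synthetic cohorts, the
statistical core of that question for infants hospitalized with
bronchiolitis:

* **Cross-site concordance** — a permutation test on the mean within-pair
  Spearman correlation between each subject's NS and NPA top-genera
  vectors, plus the full genus-by-genus cross-site correlation matrix.
* **Ensemble co-occurrence network** — every NS-genus x NPA-genus pair is
  scored with Spearman, Pearson, Bray-Curtis and symmetrized
  Kullback-Leibler metrics against a permutation null; edges significant
  (P < 0.05) for at least two metrics with a unanimous
  co-occurrence/co-exclusion call enter the consensus network, weighted by
  the Spearman value.
* **Dominance profiles** — PAM (k-medoids) clustering with BUILD+SWAP, on
  Bray-Curtis dissimilarities of composite NS+NPA vectors (k = 10) and on
  weighted-UniFrac distances of the NS samples alone (k = 6); clusters are
  named `<Genus>-dominant` when the within-cluster mean relative abundance
  of the leading genus reaches 0.40, else `mixed`.  Model selection by
  average silhouette width and a gap statistic is available.
* **Severity models** — crude 2x2 odds ratios (OR = ad/bc, Woolf CI),
  maximum-likelihood logistic regression with 11 patient-level covariates,
  and a logistic GLMM with a collection-site random intercept fitted by
  adaptive Gauss-Hermite quadrature, for intensive-care use and hospital
  length of stay >= 5 days.

Because the original sequence data were never deposited, a first-class
synthetic-cohort generator (`nichepair.synthetic`) emulates the study
design — 815 subjects, 17 collection sites, 15 focal genera, six NS and
four NPA dominance profiles with cross-site coupling, negative-binomial
sequencing depth, and a planted ICU odds ratio of 6.2 for the
*Haemophilus*-dominant NS profile against the *Moraxella*-dominant
reference — so every downstream stage can be validated against known
ground truth.

## Worked example

The published per-profile outcome counts are the one part of the original
cohort that can be recomputed exactly.  `analysis/06_severity_models.py`
prints:

```
published-count worked examples (ICU, crude):
  Haemophilus-dominant vs Moraxella-dominant: OR 6.20
  Corynebacterium-dominant vs Moraxella-dominant: OR 3.75
  Enterobacter-dominant vs Moraxella-dominant: OR 4.51
  Moraxella-dominant vs all others: OR 0.30
```

i.e. 16/59 *Haemophilus*-dominant infants used intensive care against
6/106 in the *Moraxella*-dominant profile: OR = (16 x 100)/(43 x 6) = 6.20 —
the *Haemophilus*-dominant nasal profile carries six-fold higher intensive
care odds, while *Moraxella* dominance is protective (OR 0.30 against
everyone else).

The full simulated analysis is a numbered sequence:

```bash
python analysis/01_simulate_cohort.py       # 815 subjects, 17 sites
python analysis/02_diversity_tables.py      # richness/Shannon by sample type
python analysis/03_concordance.py           # cross-site permutation test
python analysis/04_cooccurrence_network.py  # 4-metric consensus network
python analysis/05_dominance_profiles.py    # PAM profiles + ARI vs truth
python analysis/06_severity_models.py       # crude + GLMM odds ratios
```

On the default seed this prints, among other things,

```
17 consensus edges from 196 pairs (0 sign conflicts dropped)
same-genus co-occurrence across sites: Haemophilus, Moraxella
NS profiles (k = 6): {'Moraxella-dominant': 108, 'mixed': 129, ...}
adjusted Rand index vs planted profiles: 0.846
```

— the network finds the planted *Haemophilus* and *Moraxella* cross-site
coupling, and weighted-UniFrac PAM recovers the six planted dominance
profiles.

A `nichepair` console command exposes the same stages
(`nichepair simulate`, `nichepair run-all`, ...).

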