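"""Seeded generator of paired two-site airway microbiome cohorts.

The generator emulates the statistical structure of a multicenter infant
bronchiolitis cohort sampled at two upper-airway sites: for every subject an
anterior-nares (NS) dominance profile is drawn from cohort-level weights, a
nasopharyngeal (NPA) profile is drawn from a coupling matrix conditional on
the NS profile, per-site compositions come from profile-specific Dirichlet
distributions, and read counts from a multinomial at a negative-binomially
distributed sequencing depth.  Clinical covariates have simple documented
marginals, independent of profile; intensive-care use follows a logistic
model with an NS-profile offset, covariate terms and a collection-site
random intercept; length of stay is a profile-shifted negative binomial.

Defaults are calibrated once to the dominance structure of a real two-site
cohort (six NS profiles led by a large *Staphylococcus*-dominant group, four
NPA profiles, *Haemophilus* and *Moraxella* coupled across sites, ICU odds
ratio 6.2 for the NS *Haemophilus*-dominant profile against the
*Moraxella*-dominant reference).  Ground truth labels are recorded for every
subject but never consumed by the analysis modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import skbio

from .datamodel import AbundanceTable, PairedCohort, PhyloTree, ValidationError

__all__ = [
    "Profile",
    "OutcomeModel",
    "CohortSpec",
    "generate_cohort",
    "generate_random_tree",
    "DEFAULT_GENERA",
]

#: The 15 focal genera, in overall-abundance order.
DEFAULT_GENERA = (
    "Staphylococcus",
    "Moraxella",
    "Streptococcus",
    "Haemophilus",
    "Corynebacterium",
    "Dolosigranulum",
    "Enterobacter",
    "Neisseria",
    "Enterococcus",
    "Bacillus",
    "Acinetobacter",
    "Prevotella",
    "Alloprevotella",
    "Veillonella",
    "Gemella",
)


@dataclass(frozen=True)
class Profile:
    """A dominance profile: a name and a Dirichlet concentration over genera.

    ``dominant`` is the dominating genus name, or ``None`` for a mixed
    profile.  The Dirichlet mean of genus g is ``alpha[g] / sum(alpha)``.
    """

    name: str
    alpha: dict[str, float]
    dominant: str | None = None

    def concentration(self, genera: tuple[str, ...]) -> np.ndarray:
        vec = np.array([self.alpha.get(g, 0.0) for g in genera], dtype=float)
        if np.any(vec <= 0):
            missing = [g for g in genera if self.alpha.get(g, 0.0) <= 0]
            raise ValidationError(
                f"profile {self.name!r}: nonpositive Dirichlet concentration for {missing}"
            )
        return vec


def _profile(name: str, genera: tuple[str, ...], dominant: str | None,
             dominant_mean: float = 0.0, total: float = 8.0,
             minor: dict[str, float] | None = None) -> Profile:
    """Build a profile whose Dirichlet mean puts ``dominant_mean`` on the
    dominant genus and spreads the rest (optionally weighted by ``minor``)."""
    alpha: dict[str, float] = {}
    if dominant is None:
        weights = dict(minor or {})
        rest = [g for g in genera if g not in weights]
        spread = max(1.0 - sum(weights.values()), 0.0)
        for g in rest:
            weights[g] = spread / len(rest)
        for g in genera:
            alpha[g] = max(weights[g], 1e-3) * total
        return Profile(name=name, alpha=alpha, dominant=None)
    others = [g for g in genera if g != dominant]
    minor = minor or {}
    spread = 1.0 - dominant_mean - sum(minor.values())
    base = spread / max(len(others) - len(minor), 1)
    for g in genera:
        if g == dominant:
            alpha[g] = dominant_mean * total
        else:
            alpha[g] = max(minor.get(g, base), 1e-3) * total
    return Profile(name=name, alpha=alpha, dominant=dominant)


def default_ns_profiles(genera: tuple[str, ...] = DEFAULT_GENERA) -> tuple[Profile, ...]:
    """Six NS profiles; dominant-genus Dirichlet means follow the observed
    cluster means (Staphylococcus 0.78, Haemophilus 0.74, Corynebacterium
    0.59, Enterobacter 0.52, Moraxella 0.48)."""
    return (
        _profile("Staphylococcus-dominant", genera, "Staphylococcus", 0.78),
        _profile("Corynebacterium-dominant", genera, "Corynebacterium", 0.59,
                 minor={"Dolosigranulum": 0.13, "Staphylococcus": 0.07}),
        _profile("Moraxella-dominant", genera, "Moraxella", 0.48,
                 minor={"Acinetobacter": 0.12, "Streptococcus": 0.05, "Corynebacterium": 0.05}),
        _profile("mixed", genera, None,
                 minor={"Staphylococcus": 0.29, "Streptococcus": 0.14, "Moraxella": 0.13,
                        "Corynebacterium": 0.07, "Dolosigranulum": 0.07, "Haemophilus": 0.06}),
        _profile("Enterobacter-dominant", genera, "Enterobacter", 0.52,
                 minor={"Staphylococcus": 0.03}),
        _profile("Haemophilus-dominant", genera, "Haemophilus", 0.74,
                 minor={"Moraxella": 0.06, "Staphylococcus": 0.05}),
    )


def default_npa_profiles(genera: tuple[str, ...] = DEFAULT_GENERA) -> tuple[Profile, ...]:
    """Four NPA profiles mirroring the nasopharyngeal dominance structure."""
    return (
        _profile("Moraxella-dominant", genera, "Moraxella", 0.70,
                 minor={"Streptococcus": 0.08, "Haemophilus": 0.05}),
        _profile("Streptococcus-dominant", genera, "Streptococcus", 0.70,
                 minor={"Moraxella": 0.07, "Haemophilus": 0.05}),
        _profile("Haemophilus-dominant", genera, "Haemophilus", 0.70,
                 minor={"Streptococcus": 0.08, "Moraxella": 0.06}),
        _profile("mixed", genera, None,
                 minor={"Moraxella": 0.20, "Streptococcus": 0.20, "Haemophilus": 0.12,
                        "Prevotella": 0.06, "Neisseria": 0.06}),
    )


#: NS profile weights (Staphylococcus-led cohort mix).
DEFAULT_NS_WEIGHTS = {
    "Staphylococcus-dominant": 0.445,
    "mixed": 0.144,
    "Corynebacterium-dominant": 0.134,
    "Moraxella-dominant": 0.130,
    "Enterobacter-dominant": 0.075,
    "Haemophilus-dominant": 0.072,
}


def default_coupling() -> dict[str, dict[str, float]]:
    """P(NPA profile | NS profile): same-genus coupling is strong for
    Haemophilus and Moraxella; the Staphylococcus NS profile maps diffusely
    onto all NPA profiles."""
    diffuse = {"Moraxella-dominant": 0.32, "Streptococcus-dominant": 0.30,
               "Haemophilus-dominant": 0.16, "mixed": 0.22}
    return {
        "Haemophilus-dominant": {"Haemophilus-dominant": 0.80, "Moraxella-dominant": 0.06,
                                 "Streptococcus-dominant": 0.06, "mixed": 0.08},
        "Moraxella-dominant": {"Moraxella-dominant": 0.80, "Streptococcus-dominant": 0.07,
                               "Haemophilus-dominant": 0.05, "mixed": 0.08},
        "Staphylococcus-dominant": dict(diffuse),
        "Corynebacterium-dominant": dict(diffuse),
        "Enterobacter-dominant": dict(diffuse),
        "mixed": dict(diffuse),
    }


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic intensive-care model plus a negative-binomial length of stay.

    ``logit P(icu) = intercept + profile_log_or[ns_profile] + x'beta + u_site``
    with ``u_site ~ N(0, site_sd^2)`` (``site_sd`` lives on
    :class:`CohortSpec`).  ``covariate_coefs`` maps numeric/boolean metadata
    columns to coefficients.  ``los_mean`` gives the negative-binomial mean
    LOS (days) per NS profile; ``los_default_mean`` covers the rest.
    """

    intercept: float = -2.75
    profile_log_or: dict[str, float] = field(default_factory=lambda: {
        "Moraxella-dominant": 0.0,
        "Haemophilus-dominant": math.log(6.2),
        "Staphylococcus-dominant": math.log(2.54),
        "Corynebacterium-dominant": math.log(3.75),
        "Enterobacter-dominant": math.log(4.51),
        "mixed": math.log(3.86),
    })
    covariate_coefs: dict[str, float] = field(default_factory=lambda: {
        "age_months": -0.04,
        "antibiotics_prehosp_visit": 0.40,
    })
    los_mean: dict[str, float] = field(default_factory=lambda: {
        "Haemophilus-dominant": 4.2,
    })
    los_default_mean: float = 2.2
    los_dispersion: float = 3.0


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic paired cohort.

    Defaults reproduce the study conditions: 815 subjects across 17
    collection sites, 15 genera, six NS and four NPA profiles, a
    site-random-intercept SD of 0.5 on the log-odds scale, and mean
    sequencing depth 10,000 reads.
    """

    n_subjects: int = 815
    genera: tuple[str, ...] = DEFAULT_GENERA
    ns_profiles: tuple[Profile, ...] = field(default_factory=default_ns_profiles)
    npa_profiles: tuple[Profile, ...] = field(default_factory=default_npa_profiles)
    ns_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NS_WEIGHTS))
    profile_coupling: dict[str, dict[str, float]] = field(default_factory=default_coupling)
    depth_mean: float = 10_000.0
    depth_dispersion: float = 5.0
    depth_min: int = 1_500
    n_sites: int = 17
    site_sd: float = 0.5
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not self.ns_profiles or not self.npa_profiles:
            raise ValidationError("profile lists must be nonempty")
        if self.site_sd < 0:
            raise ValidationError("site_sd must be >= 0")
        ns_names = [p.name for p in self.ns_profiles]
        npa_names = {p.name for p in self.npa_profiles}
        if set(self.ns_weights) != set(ns_names):
            raise ValidationError("ns_weights keys must match NS profile names")
        if abs(sum(self.ns_weights.values()) - 1.0) > 1e-9:
            raise ValidationError("ns_weights must sum to 1")
        for ns_name, row in self.profile_coupling.items():
            if ns_name not in ns_names:
                raise ValidationError(f"coupling row for unknown NS profile {ns_name!r}")
            if set(row) - npa_names:
                raise ValidationError(f"coupling row {ns_name!r} names unknown NPA profiles")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValidationError(f"coupling row {ns_name!r} does not sum to 1")
        missing = set(ns_names) - set(self.profile_coupling)
        if missing:
            raise ValidationError(f"coupling rows missing for NS profiles: {sorted(missing)}")


def _independent_coupling(spec: CohortSpec) -> "CohortSpec":
    """Replace the coupling with uniform rows (NS and NPA independent)."""
    npa_names = [p.name for p in spec.npa_profiles]
    row = {n: 1.0 / len(npa_names) for n in npa_names}
    return replace(spec, profile_coupling={p.name: dict(row) for p in spec.ns_profiles})


# hook used by tests and calibration experiments
CohortSpec.with_independent_sites = _independent_coupling  # type: ignore[attr-defined]


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Simple documented marginals, drawn independently of profile and site."""
    age = np.clip(np.round(rng.gamma(shape=2.0, scale=2.2, size=n)), 0, 23).astype(int)
    race = rng.choice(["white", "black", "hispanic", "other"], size=n,
                      p=[0.44, 0.22, 0.30, 0.04])
    virus = rng.choice(["rsv_only", "rhinovirus_only", "other"], size=n,
                       p=[0.58, 0.05, 0.37])
    gest = np.clip(np.round(rng.normal(39.0, 1.8, size=n)), 32, 42).astype(int)
    return pd.DataFrame({
        "age_months": age,
        "male_sex": rng.random(n) < 0.60,
        "race_ethnicity": race,
        "gestational_age_weeks": gest,
        "prev_breathing_problems": rng.random(n) < 0.21,
        "daycare": rng.random(n) < 0.24,
        "other_children_home": rng.random(n) < 0.79,
        "hx_antibiotics": rng.random(n) < 0.32,
        "hx_corticosteroids": rng.random(n) < 0.15,
        "antibiotics_prehosp_visit": rng.random(n) < 0.34,
        "virus_pcr": virus,
    })


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with mean ``mean`` and size (dispersion) parameter r."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_cohort(spec: CohortSpec) -> tuple[PairedCohort, pd.DataFrame]:
    """Generate a paired cohort and its per-subject ground truth.

    Returns ``(cohort, truth)`` where ``truth`` is indexed by subject id with
    columns ``ns_profile``, ``npa_profile``, ``site_id``, ``linear_predictor``
    and ``outcome_prob``.  Fully reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    genera = spec.genera
    subjects = [f"S{i:04d}" for i in range(1, n + 1)]

    ns_by_name = {p.name: p for p in spec.ns_profiles}
    npa_by_name = {p.name: p for p in spec.npa_profiles}
    ns_names = [p.name for p in spec.ns_profiles]
    npa_names = [p.name for p in spec.npa_profiles]

    ns_w = np.array([spec.ns_weights[nm] for nm in ns_names])
    ns_profile = rng.choice(len(ns_names), size=n, p=ns_w / ns_w.sum())
    npa_profile = np.empty(n, dtype=int)
    for i, k in enumerate(ns_profile):
        row = spec.profile_coupling[ns_names[k]]
        p = np.array([row.get(nm, 0.0) for nm in npa_names])
        npa_profile[i] = rng.choice(len(npa_names), p=p / p.sum())

    def site_counts(profile_idx: np.ndarray, by_name: dict[str, Profile],
                    names: list[str]) -> np.ndarray:
        counts = np.zeros((n, len(genera)), dtype=np.int64)
        depths = np.maximum(
            _nb_draw(rng, spec.depth_mean, spec.depth_dispersion, n), spec.depth_min
        )
        for i in range(n):
            alpha = by_name[names[profile_idx[i]]].concentration(genera)
            comp = rng.dirichlet(alpha)
            counts[i] = rng.multinomial(depths[i], comp)
        return counts

    ns_counts = site_counts(ns_profile, ns_by_name, ns_names)
    npa_counts = site_counts(npa_profile, npa_by_name, npa_names)

    covariates = _draw_covariates(n, rng)
    covariates.index = pd.Index(subjects, name="subject_id")

    site_ids = rng.integers(0, spec.n_sites, size=n)
    site_effects = rng.normal(0.0, spec.site_sd, size=spec.n_sites)

    om = spec.outcome_model
    eta = np.full(n, om.intercept)
    for i, k in enumerate(ns_profile):
        eta[i] += om.profile_log_or.get(ns_names[k], 0.0)
    for col, beta in om.covariate_coefs.items():
        eta += beta * covariates[col].to_numpy(dtype=float)
    eta += site_effects[site_ids]
    prob = 1.0 / (1.0 + np.exp(-eta))
    icu = rng.random(n) < prob

    los_means = np.array([
        om.los_mean.get(ns_names[k], om.los_default_mean) for k in ns_profile
    ])
    los = np.array([
        _nb_draw(rng, m, om.los_dispersion, 1)[0] for m in los_means
    ])

    metadata = covariates.copy()
    metadata.insert(0, "site_id", [f"H{j:02d}" for j in site_ids])
    metadata["icu_use"] = pd.array(icu, dtype="boolean")
    metadata["los_days"] = pd.array(los, dtype="Int64")

    def table(counts: np.ndarray, site: str) -> AbundanceTable:
        return AbundanceTable(
            data=pd.DataFrame(counts, index=pd.Index(subjects, name="sample_id"),
                              columns=list(genera)),
            site=site,
            mode="counts",
        )

    cohort = PairedCohort(
        subjects=tuple(subjects),
        ns_table=table(ns_counts, "NS"),
        npa_table=table(npa_counts, "NPA"),
        metadata=metadata,
    )
    truth = pd.DataFrame(
        {
            "ns_profile": [ns_names[k] for k in ns_profile],
            "npa_profile": [npa_names[k] for k in npa_profile],
            "site_id": metadata["site_id"],
            "linear_predictor": eta,
            "outcome_prob": prob,
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    return cohort, truth


def generate_random_tree(genera: list[str] | tuple[str, ...], seed: int) -> PhyloTree:
    """Random rooted ultrametric binary tree over the given genus leaves.

    Built by random sequential coalescence: clusters merge in random pairs at
    strictly increasing heights (exponential increments), so every
    root-to-leaf path has the same length.
    """
    names = list(genera)
    if len(names) < 2:
        raise ValidationError("need at least 2 genera for a tree")
    if len(set(names)) != len(names):
        raise ValidationError("duplicate genus names")
    rng = np.random.default_rng(seed)
    clusters: list[tuple[skbio.TreeNode, float]] = [
        (skbio.TreeNode(name=nm), 0.0) for nm in names
    ]
    height = 0.0
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (a, ha) = clusters[i]
        (b, hb) = clusters[j]
        height += float(rng.exponential(1.0))
        a.length = height - ha
        b.length = height - hb
        parent = skbio.TreeNode(children=[a, b])
        del clusters[j], clusters[i]
        clusters.append((parent, height))
    root = clusters[0][0]
    root.length = None
    return PhyloTree(root)
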