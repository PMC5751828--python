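"""Published outcome counts of the original two-site bronchiolitis cohort.

These are the per-profile subject totals and severity-outcome event counts
of the 815-infant multicenter cohort whose anterior-nares dominance
profiles this package models.  They serve as *inputs* for worked
odds-ratio examples — the raw sequence data were never deposited, so the
printed counts are the only cohort-level quantities that can be recomputed
exactly.
"""

from __future__ import annotations

from .severity import TwoByTwo

__all__ = [
    "PROFILE_SIZES",
    "ICU_EVENTS",
    "LOS5_EVENTS",
    "icu_two_by_two",
    "icu_one_vs_all",
]

#: subjects per anterior-nares dominance profile
PROFILE_SIZES = {
    "Haemophilus-dominant": 59,
    "Moraxella-dominant": 106,
    "Staphylococcus-dominant": 363,
    "Corynebacterium-dominant": 109,
    "Enterobacter-dominant": 61,
    "mixed": 117,
}

#: intensive-care-use events per profile
ICU_EVENTS = {
    "Haemophilus-dominant": 16,
    "Moraxella-dominant": 6,
    "Staphylococcus-dominant": 47,
    "Corynebacterium-dominant": 20,
    "Enterobacter-dominant": 13,
    "mixed": 21,
}

#: hospital length of stay >= 5 days events per profile
LOS5_EVENTS = {
    "Haemophilus-dominant": 19,
    "Moraxella-dominant": 16,
    "Staphylococcus-dominant": 47,
    "Corynebacterium-dominant": 10,
    "Enterobacter-dominant": 8,
    "mixed": 18,
}


def icu_two_by_two(exposed: str, reference: str) -> TwoByTwo:
    """2x2 ICU table for one profile against a reference profile."""
    return TwoByTwo(
        a=ICU_EVENTS[exposed],
        b=PROFILE_SIZES[exposed] - ICU_EVENTS[exposed],
        c=ICU_EVENTS[reference],
        d=PROFILE_SIZES[reference] - ICU_EVENTS[reference],
    )


def icu_one_vs_all(exposed: str) -> TwoByTwo:
    """2x2 ICU table for one profile against all other profiles combined."""
    a = ICU_EVENTS[exposed]
    b = PROFILE_SIZES[exposed] - a
    c = sum(v for k, v in ICU_EVENTS.items() if k != exposed)
    d = sum(PROFILE_SIZES[k] - ICU_EVENTS[k] for k in PROFILE_SIZES if k != exposed)
    return TwoByTwo(a=a, b=b, c=c, d=d)
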