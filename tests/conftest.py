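import numpy as np
import pandas as pd
import pytest

from nichepair.datamodel import AbundanceTable
from nichepair.profiling import ClusteringResult
from nichepair.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-subject default-spec cohort shared across read-only tests."""
    return generate_cohort(CohortSpec(n_subjects=200, seed=42))


def make_table(matrix, site="NS", mode="counts", samples=None, taxa=None):
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    samples = samples or [f"s{i}" for i in range(n)]
    taxa = taxa or [f"t{j}" for j in range(m)]
    return AbundanceTable(
        data=pd.DataFrame(matrix, index=samples, columns=taxa), site=site, mode=mode
    )


def truth_clusters(truth: pd.DataFrame) -> ClusteringResult:
    """Wrap ground-truth NS profiles as a ClusteringResult for model tests."""
    names = sorted(truth["ns_profile"].unique())
    lmap = {n: i for i, n in enumerate(names)}
    labels = np.array([lmap[p] for p in truth["ns_profile"]])
    return ClusteringResult(
        k=len(names),
        labels=labels,
        medoids=(),
        objective=0.0,
        sample_ids=tuple(truth.index),
        profile_names={i: n for n, i in lmap.items()},
    )
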