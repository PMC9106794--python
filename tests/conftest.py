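import numpy as np
import pytest

from petnet import CohortTable, RegionSet, SubjectRecord


@pytest.fixture
def abc_regions() -> RegionSet:
    return RegionSet(("A", "B", "C"))


def make_cohort(
    n: int,
    region_set: RegionSet,
    seed: int = 0,
    id_prefix: str = "S",
) -> CohortTable:
    """Random well-conditioned cohort for unit tests."""
    rng = np.random.default_rng(seed)
    m = region_set.m
    suv = np.abs(rng.normal(loc=3.0, scale=1.0, size=(n, m)))
    ages = rng.uniform(30, 70, size=n)
    sexes = np.tile([0, 1], (n + 1) // 2)[:n]
    subjects = tuple(
        SubjectRecord(
            subject_id=f"{id_prefix}{i:03d}",
            age=float(ages[i]),
            sex=int(sexes[i]),
            suv=dict(zip(region_set.names, suv[i])),
        )
        for i in range(n)
    )
    return CohortTable(subjects=subjects, region_set=region_set)


@pytest.fixture
def small_cohort(abc_regions) -> CohortTable:
    return make_cohort(8, abc_regions, seed=7)
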