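import numpy as np
import pandas as pd
import pytest

from snkaryo import genome as gn
from snkaryo.pipeline import run_cohort


@pytest.fixture(scope="session")
def build():
    return gn.load_build()


@pytest.fixture(scope="session")
def units(build):
    return gn.build_default_units(build)


@pytest.fixture(scope="session")
def grid(build):
    return gn.make_bins(build)


@pytest.fixture(scope="session")
def cohorts(build, units, grid):
    """All three fixture cohorts run end to end (simulate -> call ->
    classify -> hotspots -> CIN) at the default seed. Computed once per
    session; most cohort-level tests read from this."""
    return {
        name: run_cohort(name, 123, units, grid, build) for name in ("HC", "NT", "TUM")
    }


def toy_build(n_chroms=1, length=10_000_000, cen=(4_900_000, 5_100_000)):
    """Small genome for segmentation/unit toys."""
    chroms = tuple(
        gn.Chromosome(
            name=str(i + 1),
            length=length,
            centromere=gn.Interval(str(i + 1), *cen),
        )
        for i in range(n_chroms)
    )
    return gn.GenomeBuild(assembly_id="toy", chromosomes=chroms, acrocentric=frozenset())


@pytest.fixture
def toy_grid_20():
    """One 20-bin chromosome, nothing blacklisted."""
    b = toy_build()
    return gn.make_bins(b, bin_size=500_000, blacklist=[])
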