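import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from musselmix.genotypes import GenotypeTable, build_registry
from musselmix.simulate import ParentalFrequencies
from musselmix.synthetic import default_parental_frequencies

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def diag_freqs() -> ParentalFrequencies:
    """Fully diagnostic references: each taxon fixed for its own allele."""
    return ParentalFrequencies.diagnostic()


@pytest.fixture(scope="session")
def default_freqs() -> ParentalFrequencies:
    """The study's default partially diagnostic references."""
    return default_parental_frequencies()


@pytest.fixture(scope="session")
def default_registry(default_freqs):
    return default_freqs.registry()


@pytest.fixture()
def biallelic_registry():
    """One T and one E allele per locus, refs 0.1/0.9 at every locus."""
    loci = ["L1", "L2", "L3", "L4"]
    me = {l: {"100": 0.9, "110": 0.1} for l in loci}
    mt = {l: {"100": 0.1, "110": 0.9} for l in loci}
    return build_registry(me, mt)


@pytest.fixture()
def small_table() -> GenotypeTable:
    """Six individuals, two samples, four loci, one missing cell."""
    loci = ["L1", "L2", "L3", "L4"]
    recs = [
        ("i1", "s1", "siteA", "algae", [("110", "110"), ("110", "110"), ("110", "110"), ("110", "110")]),
        ("i2", "s1", "siteA", "bottom", [("100", "110"), ("100", "110"), ("100", "110"), ("100", "110")]),
        ("i3", "s1", "siteA", "unknown", [("100", "100"), ("100", "100"), ("100", "100"), None]),
        ("i4", "s2", "siteB", "algae", [("110", "110"), ("100", "110"), ("100", "100"), ("110", "110")]),
        ("i5", "s2", "siteB", "bottom", [("100", "100"), ("100", "100"), ("100", "100"), ("100", "100")]),
        ("i6", "s2", "siteB", "unknown", [("110", "110"), ("110", "110"), ("100", "110"), ("110", "100")]),
    ]
    return GenotypeTable.from_records(loci, recs)


def make_dosage_frame(dosages, loci=None):
    """Helper: dosage matrix -> PooledTable via the public constructor."""
    from musselmix.genotypes import pooled_from_dosages
    return pooled_from_dosages(np.asarray(dosages, dtype=float), loci)
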