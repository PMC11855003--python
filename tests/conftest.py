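import pytest

from methylhit import load_fixture
from methylhit.io import CpGSite, GateRegion, MethylationProfile


@pytest.fixture(scope="session")
def cohort():
    """The packaged 32-sample cohort transcribed from the published tables."""
    return load_fixture()


@pytest.fixture(scope="session")
def pipeline_result(cohort):
    from methylhit.integrate import run_fixture_pipeline

    return run_fixture_pipeline(cohort)


def make_profile(sample_id, group, ratios, chrom="chr1", start=100, spacing=10):
    """Build a profile with evenly spaced CpGs carrying the given ratios."""
    sites = [
        CpGSite(chrom, start + i * spacing, float(r)) for i, r in enumerate(ratios)
    ]
    return MethylationProfile(sample_id, group, sites)


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def wide_gate():
    return GateRegion("wide", "chr1", 0, 10_000_000)
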