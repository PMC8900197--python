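import pytest
from hypothesis import HealthCheck, settings

import nicscreen as ns

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_genome() -> ns.GenomeBins:
    """~310-bin genome (all 24 chromosomes) for fast unit tests."""
    return ns.build_genome(scale=0.1, seed=1)


@pytest.fixture(scope="session")
def full_genome() -> ns.GenomeBins:
    """Full-size 1 Mb genome (~3,100 bins)."""
    return ns.build_genome(seed=1)


@pytest.fixture(scope="session")
def scm_profile() -> ns.SourceProfile:
    return ns.DEFAULT_PROFILES["SCM"]


@pytest.fixture(scope="session")
def fitted_normalizer(full_genome, scm_profile) -> ns.CopyRatioNormalizer:
    """Normalizer fitted on a 20-sample euploid panel at full genome size."""
    panel, _ = ns.simulate_reference_panel(20, scm_profile, full_genome, seed=5)
    return ns.CopyRatioNormalizer(genome=full_genome).fit(panel)


@pytest.fixture(scope="session")
def fitted_screen(full_genome, fitted_normalizer) -> ns.AneuploidyScreen:
    screen = ns.AneuploidyScreen(genome=full_genome, random_state=7)
    screen.normalizer_ = fitted_normalizer
    screen.segmenter_ = ns.CBSSegmenter(genome=full_genome, random_state=7)
    screen.caller_ = ns.AneuploidyCaller()
    return screen


def whole_chrom_event(genome: ns.GenomeBins, chrom: str, cn: int, m: float = 1.0) -> ns.CnvEvent:
    sl = genome.chrom_slice(chrom)
    return ns.CnvEvent(chrom, 0, sl.stop - sl.start, cn, m)
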