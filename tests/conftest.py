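import numpy as np
import pytest

from orthoarray import fixtures, libbuild, probematch, rma

MASTER_SEED = 1234


@pytest.fixture(scope="session")
def default_bundle():
    """The full-size default synthetic dataset (200 probe sets, 18 arrays)."""
    return fixtures.generate(fixtures.FixtureSpec(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def default_hits(default_bundle):
    return probematch.find_all_hits(
        default_bundle.probe_rows, default_bundle.transcripts
    )


def build_library_from(bundle, hits, config=None):
    """Run the selection → collapse → assembly chain on a fixture bundle."""
    config = config or probematch.MatchConfig()
    by_set = {}
    for r in bundle.probe_rows:
        if r.role == "PM":
            by_set.setdefault(r.probeset_id, []).append(r)
    selected, rejections = [], []
    for psid in sorted(by_set):
        res = libbuild.select_probes(by_set[psid], hits, config)
        (rejections if isinstance(res, libbuild.Rejection) else selected).append(res)
    kept, redundant = libbuild.collapse_redundancy(selected)
    rejections.extend(redundant)
    library = libbuild.build_library(
        kept, name="test-library", source_array="synthetic", target_species="target",
        config=config, checksum=libbuild.database_checksum(bundle.transcripts),
    )
    return library, rejections


@pytest.fixture(scope="session")
def default_library(default_bundle, default_hits):
    return build_library_from(default_bundle, default_hits)


@pytest.fixture(scope="session")
def default_expression(default_bundle, default_library):
    """RMA estimates on the default bundle (no additive background planted,
    so the background stage is off)."""
    library, _ = default_library
    return rma.rma_pipeline(
        default_bundle.intensities, library, rma.RmaConfig(background=False)
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small bundle for fast unit tests."""
    return fixtures.generate(
        fixtures.FixtureSpec(
            seed=42, n_genes=30, n_probesets=30, core_length=400,
            flank_length=80, n_planted_de=5, n_gene_sets=10,
            gene_set_size=8, enriched_de_overlap=4,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
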