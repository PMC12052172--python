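import pytest

import ecclong as e

# The default study design: a 5 x 400 kb genome plus a mitochondria-like
# contig, 20 simple and 5 complex circles of 300-8000 bp, 10 reads per
# circle with geometric pass counts of mean 4.  Session-scoped: the
# fixtures are treated as read-only by every test.


@pytest.fixture(scope="session")
def study():
    genome = e.generate_genome(5, 400_000, 0.41, seed=1, include_mito=True)
    circles = e.sample_circles(
        genome, 20, 5, (300, 8_000), mssi_fraction=0.2, include_mito_like=True, seed=2
    )
    return genome, circles


@pytest.fixture(scope="session")
def genome(study):
    return study[0]


@pytest.fixture(scope="session")
def nuclear_circles(study):
    return [c for c in study[1] if not c.is_mito_like]


@pytest.fixture(scope="session")
def clean_readset(study, nuclear_circles):
    genome, _ = study
    return e.simulate_reads(
        nuclear_circles, genome, 10, ("geometric", 4.0),
        linear_read_count=0, error_rates=(0.0, 0.0, 0.0), seed=3,
    )


@pytest.fixture(scope="session")
def clean_profiles(clean_readset):
    profiles = e.load_alignments(clean_readset.paf_lines())
    kept, _ = e.filter_reads(profiles)
    return kept
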