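import pytest

from fqstat.fixtures import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(
        n_samples=2,
        lanes_per_sample=2,
        paired=True,
        reads_per_lane=120,
        read_length=75,
        quality_mean=30.0,
        quality_sd=3.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_manifest(small_spec, tmp_path_factory):
    """2 samples x 2 lanes x R1/R2 = 8 plain FASTQ files, 120 reads each."""
    out = tmp_path_factory.mktemp("dataset_a")
    return generate_fixture(small_spec, out)


@pytest.fixture
def fastq_text():
    """Two well-formed records, hand-written."""
    return (
        "@r1\nACGT\n+\nII!!\n"
        "@r2\nAC\n+\nBB\n"
    )
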