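import pytest

from pgcodec.io_fastq import SyntheticSpec, generate_synthetic_reads


@pytest.fixture(scope="session")
def clean_readset():
    """Error-free 10x coverage of a 2 kb reference."""
    return generate_synthetic_reads(
        SyntheticSpec(ref_length=2000, coverage=10, read_length=100, seed=7))


@pytest.fixture(scope="session")
def noisy_readset():
    """Realistic mix: substitutions, Ns, strand flips, low-quality reads."""
    return generate_synthetic_reads(SyntheticSpec(
        ref_length=3000, coverage=10, read_length=100,
        substitution_rate=0.01, n_rate=0.005, rc_fraction=0.5,
        low_quality_fraction=0.3, seed=11))
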