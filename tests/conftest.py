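import pytest

from pksline import (
    analyze_records,
    assembly_from_architecture,
    generate_proteins,
    make_rdm_fixture,
    predict_chemotype,
    scan_records,
)


@pytest.fixture(scope="session")
def rdm_arch():
    return make_rdm_fixture()


@pytest.fixture(scope="session")
def rdm_truth(rdm_arch):
    """Noise-free synthetic Rdm cluster with ground truth."""
    return generate_proteins(rdm_arch)


@pytest.fixture(scope="session")
def rdm_hits(rdm_truth):
    """Detected domain hits per ORF of the noise-free fixture."""
    return scan_records(rdm_truth.records)


@pytest.fixture(scope="session")
def rdm_line(rdm_truth):
    """Fully analyzed assembly line from the noise-free fixture proteins."""
    return analyze_records(rdm_truth.records)


@pytest.fixture(scope="session")
def rdm_fixture_line(rdm_arch):
    """Assembly line built directly from the architecture labels."""
    return assembly_from_architecture(rdm_arch)


@pytest.fixture(scope="session")
def rdm_raw_chemotype(rdm_fixture_line):
    return predict_chemotype(rdm_fixture_line)
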