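import pytest

from markerkit import load_cel48_mix2
from markerkit.synth import SynthConfig, make_correlated_pairs, make_genbank


@pytest.fixture(scope="session")
def mix():
    return load_cel48_mix2()


@pytest.fixture(scope="session")
def primer_by_id(mix):
    return {p.id: p for p in mix.primers}


@pytest.fixture(scope="session")
def pair_data():
    """Default-condition correlated-divergence fixture, no jitter."""
    return make_correlated_pairs(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def genbank_fixture(tmp_path_factory):
    """Synthetic genomes written to disk once per session."""
    fixture = make_genbank(SynthConfig(seed=7))
    outdir = tmp_path_factory.mktemp("genomes")
    path = fixture.write(outdir)
    return fixture, path
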