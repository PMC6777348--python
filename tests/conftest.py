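import pytest

from genomehub.fixtures import (
    FixtureConfig,
    make_genome,
    make_snv_vcf,
    make_toy_model_dirs,
)
from genomehub.registry import get_entry, load_model


@pytest.fixture(scope="session")
def fixture_cfg():
    return FixtureConfig(seed=11)


@pytest.fixture(scope="session")
def genome_fa(tmp_path_factory, fixture_cfg):
    """A 100 kb random genome; never mutated by tests."""
    path = tmp_path_factory.mktemp("genome") / "genome.fa"
    make_genome(fixture_cfg, path)
    return path


@pytest.fixture(scope="session")
def registry_root(tmp_path_factory, fixture_cfg):
    root = tmp_path_factory.mktemp("registry")
    make_toy_model_dirs(root, fixture_cfg, overwrite=True)
    return root


@pytest.fixture(scope="session")
def pwm_model(registry_root):
    model, _ = load_model(get_entry(registry_root, "pwm/toy_pwm"))
    return model


@pytest.fixture(scope="session")
def mlp_model(registry_root):
    model, _ = load_model(get_entry(registry_root, "mlp/toy_mlp"))
    return model


@pytest.fixture(scope="session")
def snv_vcf(tmp_path_factory, fixture_cfg, genome_fa):
    path = tmp_path_factory.mktemp("vcf") / "variants.vcf"
    make_snv_vcf(fixture_cfg, genome_fa, path)
    return path


@pytest.fixture()
def tiny_fasta(tmp_path):
    """chr1=ACGTACGT, chrM=AAAACCCC — hand-checkable coordinates."""
    path = tmp_path / "tiny.fa"
    path.write_text(">chr1\nACGTACGT\n>chrM\nAAAACCCC\n")
    return path
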