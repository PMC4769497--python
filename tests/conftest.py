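import pytest

from poremap.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """50 synthetic reads with mixed read types; returns (folder, manifest)."""
    folder = tmp_path_factory.mktemp("fast5_small")
    cfg = SimulationConfig(n_reads=50, seed=7)
    manifest = generate_dataset(cfg, folder)
    return folder, manifest, cfg


@pytest.fixture(scope="session")
def large_dataset(tmp_path_factory):
    """1,000 synthetic reads; the workhorse for end-to-end checks."""
    folder = tmp_path_factory.mktemp("fast5_1k")
    cfg = SimulationConfig(n_reads=1000, seed=11)
    manifest = generate_dataset(cfg, folder)
    return folder, manifest, cfg


@pytest.fixture(scope="session")
def archive_dataset(tmp_path_factory):
    """200 synthetic reads for archive round-trip checks."""
    folder = tmp_path_factory.mktemp("fast5_200")
    cfg = SimulationConfig(n_reads=200, seed=13)
    manifest = generate_dataset(cfg, folder)
    return folder, manifest, cfg
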