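import pytest
from hypothesis import HealthCheck, settings

from skipedit import synthetic_fixtures as sf
from skipedit import genome_io as gio

settings.register_profile(
    "det", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


@pytest.fixture(scope="session")
def toy():
    """Small toy genome with ABE+BE3 plants and planted off-target copies.

    Off-target plants: for guide 0 a 1-mismatch, a 2-mismatch and a
    3-mismatch copy; for guide 1 a perfect duplicate.
    """
    spec = sf.FixtureSpec(
        seed=11, n_genes=4, exons_per_gene=4,
        offtarget_plants=(
            sf.OffTargetPlant(0, (7,)),
            sf.OffTargetPlant(0, (5, 15)),
            sf.OffTargetPlant(0, (3, 9, 12)),
            sf.OffTargetPlant(1, ()),
        ))
    return sf.make_toy_genome(spec)


@pytest.fixture(scope="session")
def toy_paths(toy, tmp_path_factory):
    out = tmp_path_factory.mktemp("toy")
    return toy.write(str(out))


@pytest.fixture(scope="session")
def toy_inner_exons(toy):
    return gio.enumerate_inner_exons(toy.transcripts, toy.genome)
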