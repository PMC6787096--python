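import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcgi import Guide, SimulationConfig, build_screen_library, load_components, simulate_screen

settings.register_profile(
    "det", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def components():
    return load_components()


@pytest.fixture(scope="session")
def small_screen():
    """A small simulated screen shared by deconvolution/scoring tests."""
    cfg = SimulationConfig(
        n_genes=12, guides_per_gene=3, n_controls_pos2=10, depth=60_000, seed=7, multinomial=True
    )
    pos1, pos2, library = build_screen_library(cfg)
    counts, sample_sheet, truth = simulate_screen(cfg, library)
    return cfg, library, counts, sample_sheet, truth


def random_protospacer(rng: np.random.Generator, length: int = 20) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_guides():
    g = lambda i, t, p, s: Guide(id=i, target=t, protospacer=p, slot=s)
    anchor = g("anchorA", "TAZ", "ACGTACGTACGTACGTACGT", 1)
    ctrl1 = g("ctrlX", "CONTROL", "TTTTACGTACGTACGTAAAA", 1)
    gene_b = g("geneB", "BRCA1", "CCCCACGTACGTACGTAAAA", 2)
    gene_c = g("geneC", "MCL1", "GGGGACGTACGTACGTAAAA", 2)
    ctrl2 = g("ctrlY", "CONTROL", "AAAAACGTACGTACGTCCCC", 2)
    return anchor, ctrl1, gene_b, gene_c, ctrl2
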