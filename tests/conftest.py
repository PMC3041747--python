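import numpy as np
import pytest

from splicegc.annotation_assembly import classify_all
from splicegc.folding import make_model
from splicegc.synthetic_data import SyntheticConfig, generate_genome_annotation


@pytest.fixture(scope="session")
def model37():
    return make_model(37.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth():
    """A shared synthetic genome with planted effects (25 genes)."""
    cfg = SyntheticConfig(seed=42, n_genes=25)
    genome, models, truth = generate_genome_annotation(cfg)
    return cfg, genome, models, truth


@pytest.fixture(scope="session")
def synth_classified(synth):
    cfg, genome, models, truth = synth
    return classify_all(models)


def random_rna(rng, n, alphabet="ACGU"):
    return "".join(rng.choice(list(alphabet), n))


def random_gc_sequence(rng, n, gc):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), n, p=p))
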