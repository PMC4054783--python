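import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from esekit.motif_sets import HexamerSet
from esekit.synthetic_data import SyntheticSpec, gen_genome


@pytest.fixture(scope="session")
def small_pool_genome():
    """300 exons with a tiny 8-motif pool stamped into the flanks.

    The small pool keeps accidental background matches rare, so the truth
    mask is dominated by deliberate embedding.
    """
    spec = SyntheticSpec(
        seed=42,
        n_exons=300,
        pool_size=8,
        embed_floor=0.0,
        embed_plateau=0.05,
        embed_midpoint=40.0,
        embed_scale=5.0,
    )
    exons, truth = gen_genome(spec)
    pool = HexamerSet.from_iterable("pool", truth["params"]["pool"])
    return spec, exons, truth, pool


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
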