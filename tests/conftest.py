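import numpy as np
import pytest

from circtrans.screen import DEFAULT_VECTOR, VectorContext


@pytest.fixture
def vector() -> VectorContext:
    return DEFAULT_VECTOR


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_read(insert: str, ctx: VectorContext = DEFAULT_VECTOR) -> str:
    return ctx.upstream_flank + insert + ctx.downstream_flank


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
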