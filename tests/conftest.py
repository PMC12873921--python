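import random

import numpy as np
import pytest

from mosaicbc.extract import DEFAULT_TEMPLATE, SYNTHETIC_PREFIX, SYNTHETIC_SUFFIX, ReadTemplate


@pytest.fixture(scope="session")
def template() -> ReadTemplate:
    return DEFAULT_TEMPLATE


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_read(barcode: str, template: ReadTemplate = DEFAULT_TEMPLATE) -> str:
    """Error-free template-oriented read carrying the given barcode."""
    return (
        SYNTHETIC_PREFIX
        + template.upstream_anchor
        + barcode
        + template.downstream_anchor
        + SYNTHETIC_SUFFIX
    )


def random_seq(n: int, rand: random.Random) -> str:
    return "".join(rand.choice("ACGT") for _ in range(n))
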