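import io as _io

import numpy as np
import pytest

from loxevo.msa import MultipleAlignment


@pytest.fixture
def toy_alignment():
    return MultipleAlignment(ids=["a", "b", "c"], rows=["ACD", "ACD", "ACD"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def stream(text: str) -> _io.StringIO:
    return _io.StringIO(text)
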