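import numpy as np
import pandas as pd
import pytest

from ledkit.profiles import TissueExpressionTable


@pytest.fixture
def tiny_table():
    """3 genes × 3 tissues with known TPM values."""
    data = pd.DataFrame(
        {
            "leaf": [3.0, 1.0, 0.0],
            "anther": [3.0, 0.0, 9.0],
            "pistil": [3.0, 0.0, 1.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    return TissueExpressionTable(species="sp", data=data)


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name: str, text: str):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


@pytest.fixture
def random_profiles():
    """Factory for random relative-abundance profile matrices."""

    def _make(n: int, t: int = 9, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        raw = rng.random((n, t)) + 1e-6
        return raw / raw.sum(axis=1, keepdims=True)

    return _make
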