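import numpy as np
import pytest

from karyomap.genetic_map import Marker, MarkerType

DOM_CODES = np.array(["0", "1", "-"])
COD_CODES = np.array(["A", "H", "B", "-"])


def make_dominant(mid, calls, q=None):
    return Marker(id=mid, marker_type=MarkerType.DOMINANT, calls=tuple(calls), q_score=q)


def make_snp(mid, calls, q=5.0):
    return Marker(id=mid, marker_type=MarkerType.CODOMINANT, calls=tuple(calls), q_score=q)


def random_markers(rng, m, n, missing=0.1, codominant=True):
    """m markers over n individuals with MCAR missingness."""
    out = []
    for i in range(m):
        if codominant:
            calls = COD_CODES[rng.integers(0, 3, size=n)]
        else:
            calls = DOM_CODES[rng.integers(0, 2, size=n)]
        mask = rng.random(n) < missing
        calls = np.where(mask, "-", calls)
        out.append(
            make_snp(f"m{i:03d}", calls.tolist())
            if codominant
            else make_dominant(f"m{i:03d}", calls.tolist())
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
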