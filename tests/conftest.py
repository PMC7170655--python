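import numpy as np
import pytest

from tadakit.genome import FragmentMap
from tadakit.tracks import FragmentTrack


@pytest.fixture
def make_fmap():
    """Factory for uniform fragment maps: n fragments of frag_len bp."""

    def _make(n: int, frag_len: int = 100, chrom: str = "chr1") -> FragmentMap:
        return FragmentMap({chrom: np.arange(n + 1, dtype=np.int64) * frag_len})

    return _make


@pytest.fixture
def make_track(make_fmap):
    """Factory for tracks over a fresh uniform fragment map."""

    def _make(values, missing=None, frag_len: int = 100, units: str = "log2") -> FragmentTrack:
        values = np.asarray(values, dtype=float)
        fmap = make_fmap(values.size, frag_len)
        if missing is None:
            missing = np.zeros(values.size, dtype=bool)
        return FragmentTrack(fmap, values, np.asarray(missing, dtype=bool), units=units)

    return _make
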