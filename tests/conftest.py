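import numpy as np
import pandas as pd
import pytest

from micseq.genome import GenomeLayout, WindowGrid
from micseq.io import FragmentRecord


@pytest.fixture
def toy_layout():
    return GenomeLayout.from_dict({"chr1": 10_000_000, "chr2": 6_000_000})


@pytest.fixture
def toy_grid(toy_layout):
    return WindowGrid(toy_layout, 40_000, 20_000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_fragment(chrom="chr1", start=100, end=300, mid=None, mapq=60,
                  proper=True, dup=False):
    if mid is None:
        mid = start + 50
    return FragmentRecord(chrom, start, end, mid, mapq, proper, dup)


@pytest.fixture
def fragment_factory():
    return make_fragment


def random_fragments(rng, layout, n, chrom=None):
    """Uniform random valid fragments on the layout."""
    rows = []
    chroms = [chrom] if chrom else list(layout.chrom_names)
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        L = layout.length(c)
        start = int(rng.integers(0, L - 1000))
        end = start + int(rng.integers(100, 1000))
        end = min(end, L)
        mid = int(rng.integers(start, end))
        rows.append(FragmentRecord(c, start, end, mid, 60, True, False))
    return rows


@pytest.fixture
def random_fragment_factory():
    return random_fragments


def fragments_to_frame(frags):
    return pd.DataFrame([f.__dict__ for f in frags])
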