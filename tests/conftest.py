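import numpy as np
import pytest

from peaksyn.core import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=1000, max_len=50):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def brute_force_merge(intervals, max_gap):
    """Quadratic oracle: repeatedly fuse any two intervals with gap < max_gap."""
    items = [[iv.chrom, iv.start, iv.end] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] != b[0]:
                    continue
                gap = max(a[1], b[1]) - min(a[2], b[2])
                if gap < max_gap:
                    a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((c, s, e) for c, s, e in items)
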