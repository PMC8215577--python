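import math

import numpy as np
import pytest

from hboscnv.preprocess import RDProfile


def make_profile(
    rd,
    bin_size=1000,
    chrom="chrT",
    gc=None,
    masked=None,
    gap=None,
    smoothed=None,
):
    """Hand-rolled RDProfile for unit tests."""
    rd = np.asarray(rd, dtype=float)
    n = rd.size
    return RDProfile(
        chrom=chrom,
        bin_size=bin_size,
        starts=np.arange(n, dtype=np.int64) * bin_size,
        raw_rd=rd.copy(),
        rd=rd.copy(),
        gc=np.full(n, 0.45) if gc is None else np.asarray(gc, dtype=float),
        n_masked=np.zeros(n, dtype=bool) if masked is None else np.asarray(masked, bool),
        gap=gap,
        smoothed_rd=smoothed,
    )


def brute_force_hbos(values, k):
    """Independent sort-and-scan reference for the dynamic-width histogram.

    Pure-Python re-derivation from the stated rules: sort ascending, fill
    columns by cumulative quota ceil((i+1)*n/k), extend a column over values
    tied with its last one, height = count / (width + 1), normalise by the
    max height, score = ln(1/normalised height) shared by every value of the
    column.  Returns (columns, heights, per-value scores in input order).
    """
    n = len(values)
    order = sorted(range(n), key=lambda i: (values[i], i))
    sv = [values[i] for i in order]
    cols = []
    start, i = 0, 0
    while start < n:
        target = math.ceil((i + 1) * n / k) if i < k - 1 else n
        end = max(target, start + 1)
        while end < n and sv[end] == sv[end - 1]:
            end += 1
        cols.append((start, end))
        start = end
        i += 1
    heights = [(e - s) / ((sv[e - 1] - sv[s]) + 1.0) for s, e in cols]
    hmax = max(heights)
    col_scores = [math.log(hmax / h) for h in heights]
    scores = [0.0] * n
    for ci, (s, e) in enumerate(cols):
        for j in range(s, e):
            scores[order[j]] = col_scores[ci]
    return cols, heights, scores


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
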