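"""Dynamic-width histogram density estimation and histogram-based outlier
scores (HBOS).

Instead of equal-interval columns, the histogram sorts the smoothed RD
values and packs a fixed quota of consecutive sorted values into each
column, so column width adapts to local density: dense value ranges give
narrow, tall columns, sparse ranges wide, short ones.  With ``n`` scored
bins the column count defaults to ``k = round(sqrt(n))`` and the quota to
``S = n / k``.  A column's height is::

    hist(i) = count_i / ((r_max_i - r_min_i) + 1)

(the +1 keeps the denominator positive when all values in a column tie) and
heights are normalised so the tallest column is 1.0.  Each bin is then
scored by its column::

    HBOS = log(1 / normalised_height)

so bins in the tallest column score exactly 0 and rarer RD values score
higher.  Tied values are never split across a column boundary: a column
absorbs every value equal to its last one, possibly exceeding its quota.
That overflow rule is what keeps telomere/centromere gaps out of the call
set -- the thousands of zero-RD gap bins collapse into one enormous column
whose height dominates the normalisation, so gap bins score ~0 while every
genuinely rare RD value scores high.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .preprocess import RDProfile


@dataclasses.dataclass
class DynamicHistogram:
    """Equal-quota histogram over a vector of RD values.

    Column arrays are ordered by ``r_min``.  ``bin_to_column[j]`` is the
    column of the j-th value of the *input vector* the histogram was built
    from (not genomic order; callers keep that mapping).
    """

    k: int
    quota: float
    r_min: np.ndarray
    r_max: np.ndarray
    counts: np.ndarray
    heights: np.ndarray
    norm_heights: np.ndarray
    bin_to_column: np.ndarray

    @property
    def n_values(self) -> int:
        return int(self.counts.sum())

    @property
    def n_columns(self) -> int:
        return int(self.counts.size)


@dataclasses.dataclass
class HBOSProfile:
    """Per-bin outlier scores aligned to an :class:`RDProfile`.

    Masked bins carry 0.0 (they are excluded from calling anyway); gap bins
    carry their overflow column's score, which is ~0 by construction.
    """

    scores: np.ndarray
    log_base: float = math.e

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


def choose_k(n: int) -> int:
    """Default column count: the square root of the bin count, rounded."""
    if n < 1:
        raise ValueError("need at least one bin")
    return max(1, int(round(math.sqrt(n))))


def build_histogram(rd: np.ndarray, k: int | None = None) -> DynamicHistogram:
    """Build the dynamic-width histogram of a value vector.

    Values are sorted ascending and filled into columns by cumulative
    quota: column ``i`` closes at sorted position ``ceil((i+1) * n / k)``,
    which distributes a fractional quota ``S = n/k`` evenly, then extends
    to absorb any values tied with its last one.
    """
    rd = np.asarray(rd, dtype=float)
    n = rd.size
    if n == 0:
        raise ValueError("empty RD vector")
    if not np.all(np.isfinite(rd)):
        raise ValueError("RD values must be finite")
    if k is None:
        k = choose_k(n)
    if k < 1:
        raise ValueError("k must be >= 1")

    order = np.argsort(rd, kind="stable")
    sv = rd[order]

    starts: list[int] = []
    ends: list[int] = []
    col_of_sorted = np.empty(n, dtype=np.int64)
    start = 0
    i = 0
    while start < n:
        target = int(math.ceil((i + 1) * n / k)) if i < k - 1 else n
        end = max(target, start + 1)
        while end < n and sv[end] == sv[end - 1]:
            end += 1
        col_of_sorted[start:end] = len(starts)
        starts.append(start)
        ends.append(end)
        start = end
        i += 1

    s = np.array(starts)
    e = np.array(ends)
    counts = (e - s).astype(np.int64)
    r_min = sv[s]
    r_max = sv[e - 1]
    heights = counts / ((r_max - r_min) + 1.0)
    norm_heights = heights / heights.max()

    bin_to_column = np.empty(n, dtype=np.int64)
    bin_to_column[order] = col_of_sorted

    return DynamicHistogram(
        k=int(k),
        quota=n / k,
        r_min=r_min,
        r_max=r_max,
        counts=counts,
        heights=heights,
        norm_heights=norm_heights,
        bin_to_column=bin_to_column,
    )


def column_scores(hist: DynamicHistogram) -> np.ndarray:
    """Per-column HBOS: ``log(1 / normalised_height)`` (natural log)."""
    return np.log(1.0 / hist.norm_heights)


def score_bins(hist: DynamicHistogram, profile: RDProfile) -> HBOSProfile:
    """Map column scores back onto the genomic bin order of ``profile``.

    The histogram must have been built from the profile's scored values
    (usable bins, gap bins included) in genomic order.
    """
    scored_idx = np.flatnonzero(profile.usable)
    if scored_idx.size != hist.n_values:
        raise ValueError(
            "histogram was not built from this profile "
            f"({hist.n_values} values vs {scored_idx.size} usable bins)"
        )
    scores = np.zeros(profile.total_bins, dtype=float)
    scores[scored_idx] = column_scores(hist)[hist.bin_to_column]
    return HBOSProfile(scores=scores)


def score_profile(
    profile: RDProfile, k: int | None = None
) -> tuple[DynamicHistogram, HBOSProfile]:
    """Histogram + HBOS for a smoothed profile in one call.

    Uses ``smoothed_rd`` when the smoothing stage has run, else ``rd``.
    ``k`` defaults to ``round(sqrt(n))`` over all usable bins, gap bins
    included, so the zero column of a gapped chromosome behaves as the
    overflow column described in the module docstring.
    """
    values = profile.smoothed_rd if profile.smoothed_rd is not None else profile.rd
    scored = values[profile.usable]
    hist = build_histogram(scored, k)
    return hist, score_bins(hist, profile)
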