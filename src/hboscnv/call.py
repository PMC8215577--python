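"""Thresholding, CNV calling, tumor purity and absolute copy number.

The HBOS profile has no natural null distribution, so the outlier threshold
is the Tukey boxplot upper fence, ``Q3 + 1.5 * IQR``, over all bin scores
(quartiles by the linear-interpolation / "type 7" rule).  Bins strictly
above the fence are outliers; maximal runs of outlier bins (bridging short
sub-threshold gaps) become CNV calls.  Each call is classified by its mean
GC-corrected RD ``r_t`` against the normal-bin mean ``rbar`` (computed with
called bins removed): gain when ``r_t > rbar``, else loss.  The absolute
copy number follows the standard purity/ploidy mixture inversion::

    CN = (r_t - (1 - phi) * rbar) * rho / (phi * rbar)

with ploidy ``rho = 2`` for human autosomes.  Tumor purity ``phi`` is
estimated from the loss calls: a hemizygous loss has expected RD
``r_hem = phi * rbar / 2 + (1 - phi) * rbar`` and a homozygous loss
``r_hom = (1 - phi) * rbar``, inverted as ``phi1 = 2 * (1 - r_hem / rbar)``
and ``phi2 = 1 - r_hom / rbar``; the estimate is the mean of the two.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.cluster import KMeans

from .hbos import HBOSProfile
from .preprocess import RDProfile

logger = logging.getLogger(__name__)

#: bridge runs of outlier bins separated by at most this many normal bins
MERGE_GAP = 1
#: drop calls spanning fewer bins than this; 10 bins is the smallest event
#: the method targets (10 kb at the default 1 kb bin size)
MIN_BINS = 10
#: baseline ploidy for human autosomes
PLOIDY = 2.0
#: minimum separation of the two loss-level cluster means (as a fraction of
#: rbar) before they are trusted as distinct hemi-/homozygous levels
LOSS_CLUSTER_SEPARATION = 0.08
#: fallback hemi/homozygous split when loss levels do not separate: losses
#: below this fraction of rbar are homozygous
HOM_RD_FRACTION = 0.25
_PHI_EPS = 1e-3


@dataclasses.dataclass
class CNVCall:
    """One contiguous copy-number variant.

    Coordinates are 0-based half-open.  ``copy_number`` is the raw Eq.-style
    mixture inversion, ``copy_number_rounded`` its nearest integer (both
    floored at 0); they are None until :func:`classify_and_quantify` runs.
    """

    chrom: str
    start: int
    end: int
    first_bin: int
    last_bin: int  # inclusive
    n_bins: int
    mean_rd: float
    hbos_mean: float
    type: str | None = None
    copy_number: float | None = None
    copy_number_rounded: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class PurityEstimate:
    """Tumor purity phi in (0, 1] with its two loss-level solutions."""

    phi: float
    phi1: float = float("nan")
    phi2: float = float("nan")
    r_hem: float = float("nan")
    r_hom: float = float("nan")
    ploidy: float = PLOIDY
    estimated: bool = True


def boxplot_threshold(scores: np.ndarray) -> float:
    """Tukey upper fence ``Q3 + 1.5 * IQR`` over all finite scores."""
    s = np.asarray(scores, dtype=float)
    s = s[np.isfinite(s)]
    if s.size < 4:
        raise ValueError("need at least 4 finite scores for a boxplot fence")
    q1, q3 = np.percentile(s, [25, 75])  # linear interpolation (type 7)
    return float(q3 + 1.5 * (q3 - q1))


def call_segments(
    hbos: HBOSProfile,
    threshold: float,
    profile: RDProfile,
    merge_gap: int = MERGE_GAP,
    min_bins: int = MIN_BINS,
) -> list[CNVCall]:
    """Merge consecutive outlier bins into candidate CNV calls.

    A bin is an outlier when its score is strictly above ``threshold`` and
    it is neither masked nor a gap bin.  Runs separated by at most
    ``merge_gap`` scoreable non-outlier bins are bridged (never across gap
    or masked bins); merged runs spanning fewer than ``min_bins`` bins are
    dropped.  Calls carry the mean GC-corrected RD and mean HBOS of their
    outlier bins; classification is left to :func:`classify_and_quantify`.
    """
    gap = (
        profile.gap
        if profile.gap is not None
        else np.zeros(profile.total_bins, dtype=bool)
    )
    scoreable = profile.usable & ~gap
    outlier = scoreable & (hbos.scores > threshold)

    runs: list[list[int]] = []
    for i in np.flatnonzero(outlier):
        i = int(i)
        if runs:
            s, e = runs[-1]
            between = np.arange(e + 1, i)
            if i - e - 1 <= merge_gap and np.all(scoreable[between]):
                runs[-1][1] = i
                continue
        runs.append([i, i])

    calls: list[CNVCall] = []
    for s, e in runs:
        if e - s + 1 < min_bins:
            continue
        idx = np.arange(s, e + 1)
        idx = idx[scoreable[idx]]
        calls.append(
            CNVCall(
                chrom=profile.chrom,
                start=int(profile.starts[s]),
                end=int(profile.starts[e]) + profile.bin_size,
                first_bin=s,
                last_bin=e,
                n_bins=e - s + 1,
                mean_rd=float(profile.rd[idx].mean()),
                hbos_mean=float(hbos.scores[idx].mean()),
            )
        )
    return calls


def called_mask(profile: RDProfile, calls: list[CNVCall]) -> np.ndarray:
    mask = np.zeros(profile.total_bins, dtype=bool)
    for c in calls:
        mask[c.first_bin : c.last_bin + 1] = True
    return mask


def normal_mean_rd(profile: RDProfile, calls: list[CNVCall]) -> float:
    """Mean GC-corrected RD over normal bins (variant bins removed)."""
    gap = (
        profile.gap
        if profile.gap is not None
        else np.zeros(profile.total_bins, dtype=bool)
    )
    normal = profile.usable & ~gap & ~called_mask(profile, calls)
    if not normal.any():
        raise ValueError("no normal bins left to estimate the mean RD")
    return float(profile.rd[normal].mean())


def classify_and_quantify(
    call: CNVCall,
    profile: RDProfile,
    purity: PurityEstimate,
    rbar: float,
) -> CNVCall:
    """Set gain/loss type and absolute copy number on a call (in place).

    ``rbar`` must be the normal-bin mean RD (see :func:`normal_mean_rd`).
    """
    if not purity.phi > 0:
        raise ValueError("tumor purity must be positive")
    call.type = "gain" if call.mean_rd > rbar else "loss"
    cn = (call.mean_rd - (1.0 - purity.phi) * rbar) * purity.ploidy / (
        purity.phi * rbar
    )
    call.copy_number = max(0.0, float(cn))
    call.copy_number_rounded = int(round(call.copy_number))
    return call


def estimate_purity(
    calls: list[CNVCall],
    profile: RDProfile,
    rbar: float | None = None,
    ploidy: float = PLOIDY,
    default_phi: float = 1.0,
) -> PurityEstimate:
    """Estimate tumor purity from the loss calls.

    Loss calls are grouped into hemizygous and homozygous levels.  When
    their RD/rbar ratios form two clusters separated by more than
    ``LOSS_CLUSTER_SEPARATION`` (1-D 2-means, deterministic init), the lower
    cluster is homozygous and the upper hemizygous; a single unresolved
    level falls back to the fixed split at ``HOM_RD_FRACTION * rbar``.
    Cluster means are weighted by call size.  With no loss calls at all the
    purity defaults to ``default_phi`` with a warning (``estimated=False``).
    """
    if rbar is None:
        rbar = normal_mean_rd(profile, calls)
    if not rbar > 0:
        raise ValueError("mean RD must be positive")

    losses = [c for c in calls if c.mean_rd < rbar]
    if not losses:
        logger.warning(
            "no loss calls; purity defaults to %.3f (supply one explicitly "
            "for gain-only samples)",
            default_phi,
        )
        return PurityEstimate(phi=default_phi, ploidy=ploidy, estimated=False)

    ratios = np.array([c.mean_rd / rbar for c in losses])
    weights = np.array([c.n_bins for c in losses], dtype=float)

    r_hem = r_hom = float("nan")
    if ratios.size >= 2 and np.unique(ratios).size >= 2:
        init = np.array([[ratios.min()], [ratios.max()]])
        km = KMeans(n_clusters=2, init=init, n_init=1, random_state=0)
        labels = km.fit_predict(ratios.reshape(-1, 1))
        centers = km.cluster_centers_.ravel()
        low, high = int(np.argmin(centers)), int(np.argmax(centers))
        if centers[high] - centers[low] > LOSS_CLUSTER_SEPARATION:
            r_hom = np.average(ratios[labels == low], weights=weights[labels == low])
            r_hem = np.average(ratios[labels == high], weights=weights[labels == high])

    if np.isnan(r_hem) and np.isnan(r_hom):
        hom = ratios < HOM_RD_FRACTION
        if hom.any():
            r_hom = np.average(ratios[hom], weights=weights[hom])
        if (~hom).any():
            r_hem = np.average(ratios[~hom], weights=weights[~hom])

    phi1 = 2.0 * (1.0 - r_hem) if np.isfinite(r_hem) else float("nan")
    phi2 = 1.0 - r_hom if np.isfinite(r_hom) else float("nan")
    estimates = [p for p in (phi1, phi2) if np.isfinite(p)]
    phi = float(np.clip(np.mean(estimates), _PHI_EPS, 1.0))
    clip = lambda p: float(np.clip(p, _PHI_EPS, 1.0)) if np.isfinite(p) else p

    return PurityEstimate(
        phi=phi,
        phi1=clip(phi1),
        phi2=clip(phi2),
        r_hem=float(r_hem * rbar) if np.isfinite(r_hem) else float("nan"),
        r_hom=float(r_hom * rbar) if np.isfinite(r_hom) else float("nan"),
        ploidy=ploidy,
    )
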