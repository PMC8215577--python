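"""Read-depth binning and GC-bias correction.

The detector works on a per-chromosome read-depth (RD) profile: the
chromosome is divided into non-overlapping, equal-width bins; positions that
are ``N`` in the reference are excluded; each usable bin carries the mean
read count over its non-``N`` positions and the GC fraction of its non-``N``
bases.  GC-content bias is removed by stratifying bins on GC fraction and
rescaling each bin by the ratio of the global mean RD to its stratum's mean
RD::

    r_m = (rbar / rbar_gc[m]) * raw_r_m

where ``rbar`` is the mean raw RD over usable bins of the chromosome and
``rbar_gc[m]`` the mean raw RD of bins in the same GC stratum as bin ``m``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

logger = logging.getLogger(__name__)

#: default stratum width in GC fraction for the bias correction
GC_STRATUM_WIDTH = 0.01
#: strata with fewer bins than this borrow the nearest populated stratum
GC_MIN_STRATUM_BINS = 10
#: a bin is masked when more than this fraction of its reference bases is 'N'
N_MASK_FRACTION = 0.5


@dataclasses.dataclass
class RDProfile:
    """Per-bin read-depth profile of one chromosome.

    Coordinates are 0-based, half-open; bin ``i`` covers
    ``[starts[i], starts[i] + bin_size)``.

    Attributes
    ----------
    chrom : str
        Chromosome name.
    bin_size : int
        Bases per bin.
    starts : ndarray of int
        Per-bin start coordinates, strictly increasing, step ``bin_size``.
    raw_rd : ndarray of float
        Mean read count per non-'N' position (NaN for masked bins).
    rd : ndarray of float
        GC-corrected RD values (NaN for masked bins).
    gc : ndarray of float
        GC fraction of the bin's non-'N' bases, in [0, 1].
    n_masked : ndarray of bool
        True where the bin was dropped for excess reference 'N' content.
    gap : ndarray of bool or None
        True where the bin lies in a telomere/centromere-like zero-coverage
        gap; filled in by :func:`hboscnv.smooth.split_gap_segments`.
    smoothed_rd : ndarray of float or None
        Sliding-window-smoothed RD; filled in by the smoothing stage.
    """

    chrom: str
    bin_size: int
    starts: np.ndarray
    raw_rd: np.ndarray
    rd: np.ndarray
    gc: np.ndarray
    n_masked: np.ndarray
    gap: np.ndarray | None = None
    smoothed_rd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.raw_rd = np.asarray(self.raw_rd, dtype=float)
        self.rd = np.asarray(self.rd, dtype=float)
        self.gc = np.asarray(self.gc, dtype=float)
        self.n_masked = np.asarray(self.n_masked, dtype=bool)
        if self.gap is not None:
            self.gap = np.asarray(self.gap, dtype=bool)

    @property
    def total_bins(self) -> int:
        """All bins, masked or not."""
        return self.starts.size

    @property
    def n_bins(self) -> int:
        """Usable (non-masked) bins; the ``n`` of the k = sqrt(n) rule."""
        return int((~self.n_masked).sum())

    @property
    def usable(self) -> np.ndarray:
        return ~self.n_masked

    def copy(self) -> "RDProfile":
        return RDProfile(
            chrom=self.chrom,
            bin_size=self.bin_size,
            starts=self.starts.copy(),
            raw_rd=self.raw_rd.copy(),
            rd=self.rd.copy(),
            gc=self.gc.copy(),
            n_masked=self.n_masked.copy(),
            gap=None if self.gap is None else self.gap.copy(),
            smoothed_rd=None if self.smoothed_rd is None else self.smoothed_rd.copy(),
        )

    def validate(self) -> None:
        """Raise ``ValueError`` on an internally inconsistent profile."""
        n = self.total_bins
        for name in ("raw_rd", "rd", "gc", "n_masked"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} length does not match starts")
        if n > 1 and not np.all(np.diff(self.starts) == self.bin_size):
            raise ValueError("bin starts must increase in steps of bin_size")
        us = self.usable
        if np.any(~np.isfinite(self.rd[us])) or np.any(self.rd[us] < 0):
            raise ValueError("usable RD values must be finite and >= 0")
        if np.any((self.gc[us] < 0) | (self.gc[us] > 1)):
            raise ValueError("usable GC fractions must lie in [0, 1]")


def extract_read_counts(
    alignment_path: str, chrom: str, min_mapq: int = 0
) -> np.ndarray:
    """Per-base read-start counts for one chromosome of an indexed BAM.

    Each primary, non-duplicate alignment increments the position of its
    leftmost mapped base, so one read contributes to exactly one genomic bin
    downstream.  Deterministic for a fixed file.

    Parameters
    ----------
    alignment_path
        Coordinate-sorted, indexed BAM (or CRAM) file.
    chrom
        Reference name as it appears in the BAM header.
    min_mapq
        Discard alignments below this mapping quality (default keeps all).

    Returns
    -------
    ndarray of int64, length = chromosome length.
    """
    import pysam

    with pysam.AlignmentFile(alignment_path) as af:
        if not af.has_index():
            raise FileNotFoundError(
                f"{alignment_path} has no index; run 'samtools index' first"
            )
        if chrom not in af.references:
            raise ValueError(
                f"chromosome {chrom!r} not in {alignment_path}; "
                f"available: {', '.join(af.references)}"
            )
        length = af.get_reference_length(chrom)
        counts = np.zeros(length, dtype=np.int64)
        for read in af.fetch(chrom):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                continue
            if read.mapping_quality < min_mapq:
                continue
            counts[read.reference_start] += 1
    return counts


def bin_profile(
    counts: np.ndarray,
    reference_seq: str | bytes,
    bin_size: int,
    chrom: str = "chr",
    n_mask_fraction: float = N_MASK_FRACTION,
) -> RDProfile:
    """Aggregate per-base counts into an equal-width binned RD profile.

    'N' reference positions are excluded: a bin's ``raw_rd`` is the mean
    count over its non-'N' positions and its ``gc`` the G+C fraction of its
    non-'N' bases.  Bins whose 'N' fraction exceeds ``n_mask_fraction`` (or
    that are entirely 'N') are masked.  A trailing partial bin is dropped so
    all bins share the same width.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    counts = np.asarray(counts)
    if isinstance(reference_seq, str):
        reference_seq = reference_seq.encode("ascii")
    seq = np.frombuffer(reference_seq, dtype="S1")
    if seq.size != counts.size:
        raise ValueError("reference length must match counts length")

    n_bins = counts.size // bin_size
    if n_bins == 0:
        logger.warning(
            "bin_size %d exceeds chromosome length %d; using a single bin",
            bin_size,
            counts.size,
        )
        n_bins, bin_size = 1, counts.size

    upper = seq[: n_bins * bin_size]
    upper = np.char.upper(upper)
    is_n = (upper == b"N").reshape(n_bins, bin_size)
    is_gc = ((upper == b"G") | (upper == b"C")).reshape(n_bins, bin_size)
    c = counts[: n_bins * bin_size].reshape(n_bins, bin_size)

    n_count = is_n.sum(axis=1)
    usable_pos = bin_size - n_count
    masked = (n_count / bin_size > n_mask_fraction) | (usable_pos == 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        raw_rd = c.sum(axis=1, where=~is_n) / usable_pos
        gc = is_gc.sum(axis=1) / usable_pos
    raw_rd = np.where(masked, np.nan, raw_rd)
    gc = np.where(masked, np.nan, gc)

    return RDProfile(
        chrom=chrom,
        bin_size=bin_size,
        starts=np.arange(n_bins, dtype=np.int64) * bin_size,
        raw_rd=raw_rd,
        rd=raw_rd.copy(),
        gc=gc,
        n_masked=masked,
    )


def correct_gc_bias(
    profile: RDProfile,
    stratum_width: float = GC_STRATUM_WIDTH,
    min_stratum_bins: int = GC_MIN_STRATUM_BINS,
) -> RDProfile:
    """Rescale raw RD by GC stratum so every stratum's mean matches the
    chromosome mean.

    Bins are stratified on GC fraction in windows of ``stratum_width``.
    The stratum average ``rbar_gc`` is the *median* raw RD of the stratum:
    unlike the mean it is not dragged around by the minority of
    copy-number-variant bins that happen to share a stratum, so the
    correction does not leak event signal into normal bins.  Strata holding
    fewer than ``min_stratum_bins`` usable bins borrow the nearest
    populated stratum; if no stratum is populated the profile is returned
    uncorrected.

    Returns a new profile with ``rd`` set; ``raw_rd`` is untouched.
    """
    out = profile.copy()
    us = out.usable & np.isfinite(out.raw_rd)
    if not us.any():
        raise ValueError("no usable bins")
    rbar = float(out.raw_rd[us].mean())
    if rbar == 0:
        logger.warning("mean RD is zero; skipping GC correction")
        out.rd = out.raw_rd.copy()
        return out

    n_strata = int(np.ceil(1.0 / stratum_width)) + 1
    stratum = np.zeros(out.total_bins, dtype=int)
    stratum[us] = np.clip(
        np.floor(out.gc[us] / stratum_width).astype(int), 0, n_strata - 1
    )

    counts = np.bincount(stratum[us], minlength=n_strata)
    medians = np.full(n_strata, np.nan)
    for s in np.flatnonzero(counts):
        medians[s] = np.median(out.raw_rd[us][stratum[us] == s])
    valid = (counts >= min_stratum_bins) & (medians > 0)

    rbar_gc = np.full(n_strata, rbar)
    if valid.any():
        valid_idx = np.flatnonzero(valid)
        for s in range(n_strata):
            if valid[s]:
                rbar_gc[s] = medians[s]
            elif counts[s] > 0:
                nearest = valid_idx[np.argmin(np.abs(valid_idx - s))]
                rbar_gc[s] = medians[nearest]
    else:
        logger.warning(
            "no GC stratum reaches %d bins; profile left uncorrected",
            min_stratum_bins,
        )

    rd = np.full(out.total_bins, np.nan)
    rd[us] = rbar / rbar_gc[stratum[us]] * out.raw_rd[us]
    out.rd = rd
    return out
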