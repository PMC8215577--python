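"""Tabular readers and writers: depth tables, profile dumps, BED and VCF."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .call import CNVCall
from .preprocess import RDProfile
from .simulate import TruthInterval, TruthSet

DEPTH_COLUMNS = ["chrom", "start", "end", "count", "gc"]


def read_depth_table(path: str) -> list[RDProfile]:
    """Read a per-bin depth table (``chrom start end count gc``, with
    header) into one RDProfile per chromosome, in file order.

    Rows with a missing or negative count are masked.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DEPTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing depth-table columns {missing}")
    profiles = []
    for chrom in df["chrom"].unique():
        sub = df[df["chrom"] == chrom].sort_values("start")
        widths = (sub["end"] - sub["start"]).to_numpy()
        if np.unique(widths).size != 1:
            raise ValueError(f"{path}: bins of {chrom} are not equal width")
        counts = sub["count"].to_numpy(dtype=float)
        masked = ~np.isfinite(counts) | (counts < 0)
        counts = np.where(masked, np.nan, counts)
        profiles.append(
            RDProfile(
                chrom=str(chrom),
                bin_size=int(widths[0]),
                starts=sub["start"].to_numpy(dtype=np.int64),
                raw_rd=counts,
                rd=counts.copy(),
                gc=sub["gc"].to_numpy(dtype=float),
                n_masked=masked,
            )
        )
    return profiles


def write_depth_table(profile: RDProfile, path: str) -> None:
    pd.DataFrame(
        {
            "chrom": profile.chrom,
            "start": profile.starts,
            "end": profile.starts + profile.bin_size,
            "count": profile.raw_rd,
            "gc": profile.gc,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_profile(profile: RDProfile, path: str) -> None:
    """Intermediate dump with raw, corrected and (if present) smoothed RD."""
    data = {
        "chrom": profile.chrom,
        "start": profile.starts,
        "end": profile.starts + profile.bin_size,
        "raw_rd": profile.raw_rd,
        "rd": profile.rd,
        "gc": profile.gc,
        "masked": profile.n_masked.astype(int),
    }
    if profile.smoothed_rd is not None:
        data["smoothed_rd"] = profile.smoothed_rd
    if profile.gap is not None:
        data["gap"] = profile.gap.astype(int)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_calls_bed(calls: list[CNVCall], path: str, header: str | None = None) -> None:
    """BED-like TSV: chrom start end type copy_number mean_rd hbos_mean n_bins."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip().split("\n"):
                fh.write(f"#{line}\n")
        fh.write("#chrom\tstart\tend\ttype\tcopy_number\tmean_rd\thbos_mean\tn_bins\n")
        for c in calls:
            cn = "." if c.copy_number is None else f"{c.copy_number:.4g}"
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.type or '.'}\t{cn}\t"
                f"{c.mean_rd:.4g}\t{c.hbos_mean:.4g}\t{c.n_bins}\n"
            )


def read_calls_bed(path: str) -> list[CNVCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            calls.append(
                CNVCall(
                    chrom=parts[0],
                    start=start,
                    end=end,
                    first_bin=-1,
                    last_bin=-1,
                    n_bins=int(parts[7]) if len(parts) > 7 else 0,
                    mean_rd=float(parts[5]) if len(parts) > 5 else float("nan"),
                    hbos_mean=float(parts[6]) if len(parts) > 6 else float("nan"),
                    type=parts[3] if parts[3] != "." else None,
                    copy_number=float(parts[4])
                    if len(parts) > 4 and parts[4] != "."
                    else None,
                )
            )
    return calls


def write_truth_bed(truth: TruthSet, path: str, chrom: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttype\tcopy_number\n")
        for t in truth.intervals:
            fh.write(f"{chrom}\t{t.start}\t{t.end}\t{t.type}\t{t.copy_number}\n")


def read_truth_bed(path: str) -> TruthSet:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            if len(parts) > 4:
                cn = int(round(float(parts[4])))
            else:
                cn = 3 if len(parts) > 3 and parts[3] == "gain" else 1
            intervals.append(TruthInterval(start=start, end=end, copy_number=cn))
    return TruthSet(intervals=intervals)


def write_calls_vcf(calls: list[CNVCall], path: str, sample: str = "SAMPLE") -> None:
    """Minimal VCF 4.2 with SVTYPE=DUP/DEL, END and CN."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hboscnv\n")
        fh.write('##ALT=<ID=DUP,Description="Copy number gain">\n')
        fh.write('##ALT=<ID=DEL,Description="Copy number loss">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##FORMAT=<ID=CN,Number=1,Type=Float,Description="Copy number">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for i, c in enumerate(calls, 1):
            svtype = "DUP" if c.type == "gain" else "DEL"
            cn = "." if c.copy_number is None else f"{c.copy_number:.3f}"
            fh.write(
                f"{c.chrom}\t{c.start + 1}\tcnv{i}\tN\t<{svtype}>\t.\tPASS\t"
                f"SVTYPE={svtype};END={c.end}\tCN\t{cn}\n"
            )
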