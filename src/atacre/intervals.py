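"""Genomic interval algebra and plain-text format I/O.

All coordinates inside the package are 0-based half-open (the BED
convention).  1-based inclusive coordinates — the convention used by
genome browsers and by printed ``chrN:A-B`` spans — appear only at the
parse/format boundary.

Region tables are plain :class:`pandas.DataFrame` objects with at least
``chrom``, ``start`` and ``end`` columns; single spans are
:class:`GenomicInterval` records.  Gene models are tables with
``gene_id``, ``chrom``, ``tss``, ``tes`` and ``strand`` columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakRecord",
    "parse_region_string",
    "format_region",
    "merge_overlapping",
    "overlap_query",
    "overlap_pairs",
    "nearest_tss",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "write_bedgraph",
    "read_gene_models",
    "write_gene_models",
    "read_gene_models_gtf",
    "read_fasta",
    "write_fasta",
]

_REGION_RE = re.compile(r"^\s*([\w.]+):([\d,]+)-([\d,]+)\s*$")

#: accepted coordinate conventions for parse/format
CONVENTIONS = ("one_based_inclusive", "zero_based_half_open")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open coordinate span on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: start={self.start} end={self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakRecord:
    """One called peak: interval, enrichment score, summit position."""

    interval: GenomicInterval
    score: float
    summit_offset: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.summit_offset < self.interval.width:
            raise ValueError(
                f"summit offset {self.summit_offset} outside width {self.interval.width}"
            )


def parse_region_string(
    text: str, convention: str = "one_based_inclusive"
) -> GenomicInterval:
    """Parse ``"chrN:A-B"`` into a half-open interval.

    Comma thousands-separators are accepted.  Under
    ``one_based_inclusive`` (the convention of printed browser spans)
    ``(A, B)`` maps to ``start = A - 1, end = B`` so the width is
    ``B - A + 1``; under ``zero_based_half_open`` the numbers are taken
    as-is.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    m = _REGION_RE.match(text)
    if m is None:
        raise ValueError(f"malformed region string: {text!r}")
    chrom = m.group(1)
    a = int(m.group(2).replace(",", ""))
    b = int(m.group(3).replace(",", ""))
    if b < a:
        raise ValueError(f"end before start in {text!r}")
    if convention == "one_based_inclusive":
        if a < 1:
            raise ValueError("1-based coordinates start at 1")
        return GenomicInterval(chrom, a - 1, b)
    return GenomicInterval(chrom, a, b)


def format_region(
    iv: GenomicInterval, convention: str = "one_based_inclusive", sep: bool = False
) -> str:
    """Format an interval back to ``chrN:A-B`` under either convention."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if convention == "one_based_inclusive":
        a, b = iv.start + 1, iv.end
    else:
        a, b = iv.start, iv.end
    if sep:
        return f"{iv.chrom}:{a:,}-{b:,}"
    return f"{iv.chrom}:{a}-{b}"


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def _as_region_frame(regions: pd.DataFrame) -> pd.DataFrame:
    for col in ("chrom", "start", "end"):
        if col not in regions.columns:
            raise ValueError(f"region table missing column {col!r}")
    return regions


def merge_overlapping(regions: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping (and book-ended) intervals into disjoint spans.

    Output is sorted by (chrom, start).  Intervals that merely touch
    (``end == start`` of the next) are merged, mirroring ``bedtools
    merge`` defaults.
    """
    regions = _as_region_frame(regions)
    if len(regions) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = regions[["chrom", "start", "end"]].sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    )
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        run_end = np.maximum.accumulate(ends)
        # new block wherever the interval starts strictly after the
        # running max end of everything before it (book-ended => merged)
        new_block = np.ones(len(sub), dtype=bool)
        new_block[1:] = starts[1:] > run_end[:-1]
        block = np.cumsum(new_block) - 1
        for b in range(block[-1] + 1):
            sel = block == b
            out_chrom.append(chrom)
            out_start.append(int(starts[sel][0]))
            out_end.append(int(run_end[sel][-1]))
    return pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})


def overlap_pairs(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = 1
) -> pd.DataFrame:
    """All index pairs (i, j) where a.iloc[i] and b.iloc[j] share
    ``>= min_overlap`` bases.

    Sweep over start-sorted intervals per chromosome; returns a frame
    with columns ``a_index``, ``b_index``, ``overlap`` (positional
    indices into the input frames).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    a = _as_region_frame(a)
    b = _as_region_frame(b)
    ai_out: list[int] = []
    bi_out: list[int] = []
    ov_out: list[int] = []
    if len(a) == 0 or len(b) == 0:
        return pd.DataFrame({"a_index": [], "b_index": [], "overlap": []}, dtype=int)
    b_by_chrom = {
        chrom: (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub.index.to_numpy(),
        )
        for chrom, sub in b.reset_index(drop=True).sort_values(["chrom", "start"]).groupby("chrom")
    }
    a_reset = a.reset_index(drop=True)
    for chrom, sub in a_reset.groupby("chrom"):
        if chrom not in b_by_chrom:
            continue
        bs, be, bidx = b_by_chrom[chrom]
        be_cummax = np.maximum.accumulate(be)
        for ai, a_start, a_end in zip(
            sub.index.to_numpy(), sub["start"].to_numpy(), sub["end"].to_numpy()
        ):
            # candidates: b.start < a_end and running-max b.end > a_start
            hi = int(np.searchsorted(bs, a_end - min_overlap, side="right"))
            lo = int(np.searchsorted(be_cummax[:hi], a_start, side="right"))
            if lo >= hi:
                continue
            ov = np.minimum(be[lo:hi], a_end) - np.maximum(bs[lo:hi], a_start)
            keep = ov >= min_overlap
            n = int(keep.sum())
            if n:
                ai_out.extend([int(ai)] * n)
                bi_out.extend(bidx[lo:hi][keep].tolist())
                ov_out.extend(ov[keep].tolist())
    return pd.DataFrame({"a_index": ai_out, "b_index": bi_out, "overlap": ov_out})


def overlap_query(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = 1
) -> pd.DataFrame:
    """Subset of ``a`` sharing ``>= min_overlap`` bases with any interval
    of ``b``; adds an ``overlap`` column with the largest shared span."""
    pairs = overlap_pairs(a, b, min_overlap=min_overlap)
    if len(pairs) == 0:
        out = a.iloc[0:0].copy()
        out["overlap"] = pd.Series(dtype=int)
        return out
    best = pairs.groupby("a_index")["overlap"].max()
    out = a.reset_index(drop=True).iloc[best.index.to_numpy()].copy()
    out["overlap"] = best.to_numpy()
    return out


def nearest_tss(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each region its nearest gene by midpoint-to-TSS distance.

    The signed distance is positive when the region midpoint lies
    downstream of the TSS in the gene's orientation.  Equidistant ties
    go to the lexicographically smaller ``gene_id``.  Regions on
    chromosomes without genes get ``nearest_gene = None``.

    Returns a copy of ``regions`` with ``nearest_gene`` and
    ``tss_distance`` columns.
    """
    regions = _as_region_frame(regions)
    out = regions.reset_index(drop=True).copy()
    out["nearest_gene"] = None
    out["tss_distance"] = pd.NA
    if len(regions) == 0 or len(genes) == 0:
        return out
    mids = (out["start"].to_numpy() + out["end"].to_numpy()) // 2
    for chrom, sub in out.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if len(g) == 0:
            continue
        g = g.sort_values(["tss", "gene_id"], kind="mergesort")
        tss = g["tss"].to_numpy()
        gid = g["gene_id"].to_numpy()
        strand = g["strand"].to_numpy()
        for i in sub.index:
            mid = int(mids[i])
            j = int(np.searchsorted(tss, mid))
            cand = [k for k in (j - 1, j) if 0 <= k < len(tss)]
            dmin = min(abs(mid - int(tss[k])) for k in cand)
            # all genes whose TSS sits at distance dmin (either side)
            best: list[int] = []
            for t in {mid - dmin, mid + dmin}:
                lo = int(np.searchsorted(tss, t, side="left"))
                hi = int(np.searchsorted(tss, t, side="right"))
                best.extend(range(lo, hi))
            k = min(best, key=lambda k: str(gid[k]))
            sign = 1 if strand[k] == "+" else -1
            out.at[i, "nearest_gene"] = gid[k]
            out.at[i, "tss_distance"] = int(sign * (mid - int(tss[k])))
    out["tss_distance"] = out["tss_distance"].astype("Int64")
    return out


# ---------------------------------------------------------------------------
# readers / writers (tab-separated, headerless where the format says so)
# ---------------------------------------------------------------------------

_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]
_NARROWPEAK_COLS = _BED6_COLS + ["signal", "pvalue", "qvalue", "summit_offset"]


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into a region frame (extra columns kept by name)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED6_COLS[: df.shape[1]]
    return df


def write_bed(regions: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    if columns is None:
        columns = [c for c in _BED6_COLS if c in regions.columns]
    regions[columns].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _NARROWPEAK_COLS[: df.shape[1]]
    return df


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    df = peaks.copy()
    for col, default in (
        ("name", "."),
        ("score", 0),
        ("strand", "."),
        ("signal", 0.0),
        ("pvalue", -1.0),
        ("qvalue", -1.0),
        ("summit_offset", -1),
    ):
        if col not in df.columns:
            df[col] = default
    df[_NARROWPEAK_COLS].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track, path) -> None:
    """Write a binned track (see :mod:`atacre.atac`) as bedGraph text,
    collapsing runs of equal values."""
    vals = np.asarray(track.values, dtype=float)
    n = len(vals)
    with open(path, "w") as fh:
        if n == 0:
            return
        change = np.flatnonzero(np.diff(vals) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [n]])
        for s, e in zip(starts, ends):
            lo = int(s) * track.bin_width
            hi = min(int(e) * track.bin_width, track.chrom_length)
            fh.write(f"{track.chrom}\t{lo}\t{hi}\t{vals[s]:g}\n")


_GENE_COLS = ["gene_id", "chrom", "tss", "tes", "strand"]


def read_gene_models(path) -> pd.DataFrame:
    """Gene models from the 5-column TSV (gene_id, chrom, tss, tes, strand)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"gene model table missing columns {missing}")
    return df


def write_gene_models(genes: pd.DataFrame, path) -> None:
    cols = _GENE_COLS + [c for c in genes.columns if c not in _GENE_COLS]
    genes[cols].to_csv(path, sep="\t", index=False)


_GTF_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_gene_models_gtf(path) -> pd.DataFrame:
    """Derive a TSS table from GTF ``gene`` (fallback ``transcript``)
    records; the attribute key ``gene_id`` is required."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in ("gene", "transcript"):
                continue
            m = _GTF_GENE_ID_RE.search(parts[8])
            if m is None:
                raise ValueError(f"GTF record without gene_id: {line!r}")
            chrom, start, end, strand = parts[0], int(parts[3]) - 1, int(parts[4]), parts[6]
            tss, tes = (start, end) if strand == "+" else (end - 1, start)
            rows.append((m.group(1), chrom, tss, tes, strand, parts[2]))
    df = pd.DataFrame(rows, columns=_GENE_COLS + ["feature"])
    genes = df[df["feature"] == "gene"]
    if len(genes) == 0:
        genes = df.drop_duplicates("gene_id")
    return genes[_GENE_COLS].reset_index(drop=True)


def read_fasta(path) -> dict[str, str]:
    """Chromosome name -> uppercase sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
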