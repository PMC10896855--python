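"""Tn5 insertion-site processing and coverage tracks.

The transposase inserts adapters as a pair 9 bp apart, so the true
insertion point sits +4 bases into a plus-strand read and -5 bases into
a minus-strand read.  Each aligned fragment contributes two corrected
single-base insertion events (one per end); events are optionally
re-extended to 150-bp pseudo-reads centered on the insertion, binned
into fixed-width windows (default 300 nt), downsampled for
depth-matched group tracks, and scanned for enriched windows by a
simplified Poisson peak caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = [
    "BinnedTrack",
    "fragment_to_insertions",
    "fragments_to_insertions",
    "recenter_insertion",
    "recenter_insertions",
    "binned_coverage",
    "downsample_insertions",
    "group_average_track",
    "normalize_cpm",
    "difference_track",
    "call_peaks_simple",
]

PLUS_SHIFT = 4   # plus-strand 5' ends move 4 bases 3'-ward
MINUS_SHIFT = 5  # minus-strand 5' ends move 5 bases 5'-ward


@dataclass
class BinnedTrack:
    """Per-bin signal along one chromosome."""

    chrom: str
    chrom_length: int
    bin_width: int
    values: np.ndarray
    tag: str = "raw"  # raw | per-million | group-mean | difference

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        expected = math.ceil(self.chrom_length / self.bin_width)
        self.values = np.asarray(self.values)
        if len(self.values) != expected:
            raise ValueError(
                f"expected {expected} bins for length {self.chrom_length}, "
                f"got {len(self.values)}"
            )
        if self.tag != "difference" and np.any(self.values < 0):
            raise ValueError("negative values in a non-difference track")

    @property
    def n_bins(self) -> int:
        return len(self.values)


def fragment_to_insertions(start: int, end: int, chrom_length: int) -> list[int]:
    """Corrected insertion positions for one fragment (both ends).

    The left end is a plus-strand 5' end at ``start`` (shifted +4); the
    right end is a minus-strand 5' end at ``end - 1`` (shifted -5).
    Positions falling outside the chromosome are dropped.
    """
    out = []
    for pos in (start + PLUS_SHIFT, (end - 1) - MINUS_SHIFT):
        if 0 <= pos < chrom_length:
            out.append(pos)
    return out


def fragments_to_insertions(
    fragments: pd.DataFrame, chrom_sizes: dict[str, int]
) -> tuple[pd.DataFrame, int]:
    """Vectorised fragment-end correction for a fragment table.

    Parameters
    ----------
    fragments : frame with ``chrom``, ``start``, ``end`` columns.
    chrom_sizes : chromosome name -> length.

    Returns the insertion events (``chrom``, ``pos``, ``source_strand``)
    and the number of events dropped for falling off a chromosome end.
    """
    chroms = fragments["chrom"].to_numpy()
    starts = fragments["start"].to_numpy()
    ends = fragments["end"].to_numpy()
    pos = np.concatenate([starts + PLUS_SHIFT, ends - 1 - MINUS_SHIFT])
    strand = np.concatenate(
        [np.full(len(starts), "+"), np.full(len(ends), "-")]
    )
    chrom2 = np.concatenate([chroms, chroms])
    lengths = np.array([chrom_sizes[c] for c in chrom2])
    ok = (pos >= 0) & (pos < lengths)
    dropped = int((~ok).sum())
    events = pd.DataFrame(
        {"chrom": chrom2[ok], "pos": pos[ok].astype(int), "source_strand": strand[ok]}
    )
    return events, dropped


def recenter_insertion(
    pos: int, chrom_length: int, flank: int = 75
) -> tuple[int, int, bool]:
    """150-bp pseudo-read centered on an insertion (start, end, clipped?).

    With ``flank = 0`` the event stays a single base.  Intervals are
    clipped at chromosome edges and flagged.
    """
    start = pos - flank
    end = max(pos + flank, pos + 1)
    clipped = start < 0 or end > chrom_length
    return max(start, 0), min(end, chrom_length), clipped


def recenter_insertions(
    events: pd.DataFrame, chrom_sizes: dict[str, int], flank: int = 75
) -> pd.DataFrame:
    """Recentered intervals for an event table; adds a ``clipped`` flag."""
    pos = events["pos"].to_numpy()
    lengths = np.array([chrom_sizes[c] for c in events["chrom"]])
    start = pos - flank
    end = np.maximum(pos + flank, pos + 1)
    clipped = (start < 0) | (end > lengths)
    return pd.DataFrame(
        {
            "chrom": events["chrom"].to_numpy(),
            "start": np.maximum(start, 0),
            "end": np.minimum(end, lengths),
            "clipped": clipped,
        }
    )


def binned_coverage(
    positions: np.ndarray, chrom: str, chrom_length: int, bin_width: int = 300
) -> BinnedTrack:
    """Count insertion events per fixed-width bin (``pos // bin_width``).

    Every event lands in exactly one bin, so the track total equals the
    event count.
    """
    n_bins = math.ceil(chrom_length / bin_width)
    positions = np.asarray(positions, dtype=int)
    if np.any((positions < 0) | (positions >= chrom_length)):
        raise ValueError("event position outside chromosome")
    counts = np.bincount(positions // bin_width, minlength=n_bins)
    return BinnedTrack(chrom, chrom_length, bin_width, counts, tag="raw")


def downsample_insertions(
    events: pd.DataFrame, n_target: int, seed: int
) -> pd.DataFrame:
    """Uniform subsample without replacement (identity when
    ``n_target >= len(events)``); deterministic under ``seed``."""
    if n_target < 0:
        raise ValueError("n_target must be >= 0")
    if n_target >= len(events):
        return events.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(events), size=n_target, replace=False)
    return events.iloc[np.sort(idx)].reset_index(drop=True)


def group_average_track(
    sample_events: list[pd.DataFrame],
    chrom: str,
    chrom_length: int,
    n_group_target: int | None = None,
    bin_width: int = 300,
    seed: int = 0,
) -> BinnedTrack:
    """Aggregate track for one treatment group on one chromosome.

    All samples' events are concatenated, downsampled to
    ``n_group_target`` (kept whole when ``None``), and binned.
    """
    if not sample_events:
        raise ValueError("need at least one sample")
    pooled = pd.concat(sample_events, ignore_index=True)
    if n_group_target is not None:
        pooled = downsample_insertions(pooled, n_group_target, seed)
    pos = pooled.loc[pooled["chrom"] == chrom, "pos"].to_numpy()
    track = binned_coverage(pos, chrom, chrom_length, bin_width)
    track.tag = "group-mean"
    return track


def normalize_cpm(track: BinnedTrack, total: float | None = None) -> BinnedTrack:
    """Counts-per-million scaling so tracks from different depths are
    comparable before subtraction."""
    t = total if total is not None else float(np.sum(track.values))
    if t <= 0:
        raise ValueError("cannot CPM-normalize an empty track")
    return BinnedTrack(
        track.chrom,
        track.chrom_length,
        track.bin_width,
        np.asarray(track.values, dtype=float) * 1e6 / t,
        tag="per-million",
    )


def difference_track(cci: BinnedTrack, naive: BinnedTrack) -> BinnedTrack:
    """Injured-minus-naive signal per bin; positive bins gained
    accessibility.  Both inputs must share chromosome, bin width and
    length (normalize to equal totals first)."""
    if (
        cci.chrom != naive.chrom
        or cci.bin_width != naive.bin_width
        or cci.n_bins != naive.n_bins
    ):
        raise ValueError("track shapes do not match")
    return BinnedTrack(
        cci.chrom,
        cci.chrom_length,
        cci.bin_width,
        np.asarray(cci.values, dtype=float) - np.asarray(naive.values, dtype=float),
        tag="difference",
    )


def call_peaks_simple(
    events: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bin_width: int = 300,
    q_max: float = 0.05,
    merge_gap: int = 1,
    local_window: int = 10_000,
    sample_id: str = "",
) -> pd.DataFrame:
    """Poisson-enrichment peak caller over fixed-width bins.

    Each bin's count is tested against a Poisson null with rate
    ``max(genome-wide mean, local mean over a 10-kb window)``; p-values
    are Benjamini-Hochberg adjusted genome-wide, bins with ``q <= q_max``
    are kept and merged when separated by at most ``merge_gap``
    non-significant bins.  The summit is the center of the
    highest-count bin; the score is ``-log10(q)`` at the summit bin.

    Returns a narrowPeak-like frame: chrom, start, end, score,
    summit_offset, n_events.
    """
    if len(events) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "score", "summit_offset", "n_events"]
        )
    tracks = {}
    for chrom, length in chrom_sizes.items():
        pos = events.loc[events["chrom"] == chrom, "pos"].to_numpy()
        tracks[chrom] = binned_coverage(pos, chrom, length, bin_width)
    all_counts = np.concatenate([t.values for t in tracks.values()])
    global_mean = float(all_counts.mean())
    pvals = []
    lambdas = {}
    for chrom, t in tracks.items():
        counts = t.values.astype(float)
        w = max(1, round(local_window / bin_width))
        kernel = np.ones(w) / w
        local = np.convolve(counts, kernel, mode="same")
        # centered moving average shrinks at edges; rescale by coverage
        norm = np.convolve(np.ones_like(counts), kernel, mode="same")
        local = local / norm
        lam = np.maximum(global_mean, local)
        lambdas[chrom] = lam
        pvals.append(stats.poisson.sf(t.values - 1, lam))
    p_all = np.concatenate(pvals)
    q_all = bh_adjust(p_all)
    rows = []
    offset = 0
    for chrom, t in tracks.items():
        n = t.n_bins
        q = q_all[offset : offset + n]
        offset += n
        sig = np.flatnonzero(q <= q_max)
        if len(sig) == 0:
            continue
        # group significant bins allowing merge_gap non-significant bins
        breaks = np.flatnonzero(np.diff(sig) > merge_gap + 1)
        groups = np.split(sig, breaks + 1)
        for g in groups:
            lo, hi = int(g[0]), int(g[-1])
            counts = t.values[lo : hi + 1]
            summit_bin = lo + int(np.argmax(counts))
            start = lo * bin_width
            end = min((hi + 1) * bin_width, t.chrom_length)
            summit = min(
                summit_bin * bin_width + bin_width // 2, t.chrom_length - 1
            )
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "score": float(-np.log10(max(float(q[summit_bin]), 1e-300))),
                    "summit_offset": summit - start,
                    "n_events": int(t.values[lo : hi + 1].sum()),
                }
            )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "score", "summit_offset", "n_events"]
    )
    if sample_id:
        out["sample_id"] = sample_id
    return out
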