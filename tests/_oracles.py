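"""Independent brute-force oracles used to verify the library's
interval, counting and scoring primitives on small random instances.

Everything here is deliberately naive (per-base masks, quadratic
scans, exhaustive enumeration) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def mask_union(regions: pd.DataFrame, chrom_len: int, chrom: str) -> np.ndarray:
    """Boolean per-base occupancy of a region set on one chromosome."""
    mask = np.zeros(chrom_len, dtype=bool)
    for _, r in regions.iterrows():
        if r["chrom"] == chrom:
            mask[r["start"] : r["end"]] = True
    return mask


def quadratic_overlap_pairs(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = 1
) -> set[tuple[int, int]]:
    """All (i, j) positional pairs sharing >= min_overlap bases."""
    out = set()
    for i, ra in a.reset_index(drop=True).iterrows():
        for j, rb in b.reset_index(drop=True).iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            ov = min(ra["end"], rb["end"]) - max(ra["start"], rb["start"])
            if ov >= min_overlap:
                out.add((i, j))
    return out


def exhaustive_nearest_tss(
    region_row, genes: pd.DataFrame
) -> tuple[str | None, int | None]:
    """Scan every gene; minimal |mid - tss|, ties to smaller gene_id."""
    mid = (region_row["start"] + region_row["end"]) // 2
    best = None
    for _, g in genes.iterrows():
        if g["chrom"] != region_row["chrom"]:
            continue
        d = abs(mid - g["tss"])
        key = (d, str(g["gene_id"]))
        if best is None or key < best[0]:
            sign = 1 if g["strand"] == "+" else -1
            best = (key, g["gene_id"], sign * (mid - g["tss"]))
    if best is None:
        return None, None
    return best[1], best[2]


def histogram_coverage(positions, chrom_len: int, bin_width: int) -> np.ndarray:
    edges = np.arange(0, chrom_len + bin_width, bin_width)
    h, _ = np.histogram(positions, bins=edges)
    return h


def stepup_bh(p: np.ndarray) -> np.ndarray:
    """Direct Benjamini-Hochberg step-up formula."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def neighborhood_normalize(grid: np.ndarray, radius: int = 1) -> np.ndarray:
    """Per-cell neighbourhood-median normalization by explicit loops."""
    grid = np.asarray(grid, dtype=float)
    nrow, ncol = grid.shape
    out = np.full_like(grid, np.nan)
    for i in range(nrow):
        for j in range(ncol):
            nb = []
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nrow and 0 <= jj < ncol and not np.isnan(grid[ii, jj]):
                        nb.append(grid[ii, jj])
            if nb:
                med = float(np.median(nb))
                if med > 0:
                    out[i, j] = grid[i, j] / med
    return out


def enumerate_pwm_tail(matrix: np.ndarray, background: np.ndarray, pseudocount: float):
    """Exact (score, probability) pairs of a short PWM under the
    background model, by enumerating every k-mer."""
    w = matrix.shape[0]
    p = matrix + pseudocount
    p = p / p.sum(axis=1, keepdims=True)
    lo = np.log2(p / background[None, :])
    scores, probs = [], []
    for idx in np.ndindex(*([4] * w)):
        s = sum(lo[pos, b] for pos, b in enumerate(idx))
        pr = float(np.prod([background[b] for b in idx]))
        scores.append(s)
        probs.append(pr)
    return np.array(scores), np.array(probs)


def random_regions(
    rng: np.random.Generator,
    n: int,
    chrom_len: int,
    chroms=("chr1",),
    max_width: int = 500,
) -> pd.DataFrame:
    start = rng.integers(0, chrom_len - max_width, size=n)
    width = rng.integers(1, max_width, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": start,
            "end": start + width,
        }
    )
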