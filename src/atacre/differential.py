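"""Consensus accessible regions and negative-binomial differential testing.

The candidate region set is the merged union of per-sample peak calls,
kept only where reproduced in at least ``min_support`` samples of each
group and overlapped by an H3K4me1 enhancer mark.  Per-region insertion
counts are normalized by median-of-ratios size factors and tested for a
group difference under a negative-binomial model: per-region pooled
method-of-moments dispersion floored at the experiment-wide mean
dispersion (cross-feature information sharing, without which a Wald
test at 2-3 replicates per group is badly anti-conservative), then a
normal-reference Wald statistic on the log2 ratio of group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from . import intervals as gi

__all__ = [
    "RegionCountMatrix",
    "reproducible_consensus",
    "subset_by_mark",
    "count_matrix",
    "estimate_size_factors",
    "nb_group_test",
    "bh_adjust",
    "sample_qc",
]

#: default raw-p significance threshold for differential accessibility;
#: deliberately permissive because single-region effects are small
DEFAULT_ALPHA = 0.05
DISPERSION_FLOOR = 1e-8
LFC_PSEUDOCOUNT = 0.5


@dataclass
class RegionCountMatrix:
    """Insertion counts per consensus region per sample."""

    regions: pd.DataFrame           # chrom, start, end (+ extras)
    samples: list[str]
    groups: dict[str, str]          # sample -> group label
    counts: np.ndarray              # len(regions) x len(samples), int
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("count matrix shape inconsistent with regions/samples")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    def normalized(self) -> np.ndarray:
        sf = (
            self.size_factors
            if self.size_factors is not None
            else estimate_size_factors(self.counts)
        )
        return self.counts / sf[None, :]

    def group_columns(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.regions[["chrom", "start", "end"]].reset_index(drop=True).copy()
        for i, s in enumerate(self.samples):
            df[s] = self.counts[:, i]
        return df


def reproducible_consensus(
    peak_sets: dict[str, pd.DataFrame],
    groups: dict[str, str],
    min_support_per_group: int = 2,
    mode: str = "each_group",
) -> pd.DataFrame:
    """Merged consensus loci supported by >= ``min_support_per_group``
    samples per group.

    A candidate locus is any maximal merged span of the union of all
    samples' peaks.  Support in a group is the number of that group's
    samples with at least one peak overlapping the locus.  With
    ``mode="each_group"`` the locus must meet the support threshold in
    every group (a peak "present in both CCI samples and 2 of the 3
    naive samples"); ``mode="any_group"`` keeps loci reproducible in at
    least one group.

    Returns the kept loci with per-group ``support_<group>`` columns.
    """
    if mode not in ("each_group", "any_group"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = sorted(set(groups[s] for s in peak_sets))
    for g in labels:
        n = sum(1 for s in peak_sets if groups[s] == g)
        if n < min_support_per_group:
            raise ValueError(
                f"group {g!r} has {n} samples, fewer than min_support "
                f"{min_support_per_group}"
            )
    union = pd.concat(
        [df[["chrom", "start", "end"]] for df in peak_sets.values()],
        ignore_index=True,
    )
    loci = gi.merge_overlapping(union)
    support = {g: np.zeros(len(loci), dtype=int) for g in labels}
    for sample, peaks in peak_sets.items():
        pairs = gi.overlap_pairs(loci, peaks)
        hit = np.zeros(len(loci), dtype=bool)
        if len(pairs):
            hit[pairs["a_index"].unique()] = True
        support[groups[sample]] += hit
    keep_per_group = np.column_stack(
        [support[g] >= min_support_per_group for g in labels]
    )
    keep = keep_per_group.all(axis=1) if mode == "each_group" else keep_per_group.any(axis=1)
    out = loci[keep].reset_index(drop=True)
    for g in labels:
        out[f"support_{g}"] = support[g][keep]
    return out


def subset_by_mark(
    consensus: pd.DataFrame, mark_regions: pd.DataFrame, min_overlap: int = 1
) -> pd.DataFrame:
    """Keep consensus regions overlapping an enhancer-mark (H3K4me1)
    region by >= ``min_overlap`` bp; records the overlap fraction."""
    if len(mark_regions) == 0:
        warnings.warn("empty mark region set: no consensus region survives")
        out = consensus.iloc[0:0].copy()
        out["mark_overlap_frac"] = pd.Series(dtype=float)
        return out
    marks = gi.merge_overlapping(mark_regions)
    pairs = gi.overlap_pairs(consensus, marks, min_overlap=min_overlap)
    if len(pairs) == 0:
        out = consensus.iloc[0:0].copy()
        out["mark_overlap_frac"] = pd.Series(dtype=float)
        return out
    total = pairs.groupby("a_index")["overlap"].sum()
    out = consensus.reset_index(drop=True).iloc[total.index.to_numpy()].copy()
    width = out["end"].to_numpy() - out["start"].to_numpy()
    out["mark_overlap_frac"] = total.to_numpy() / width
    return out.reset_index(drop=True)


def count_matrix(
    consensus: pd.DataFrame,
    sample_events: dict[str, pd.DataFrame],
    groups: dict[str, str],
) -> RegionCountMatrix:
    """Count corrected insertion positions per region per sample
    (half-open membership: ``start <= pos < end``)."""
    samples = list(sample_events)
    counts = np.zeros((len(consensus), len(samples)), dtype=int)
    cons = consensus.reset_index(drop=True)
    for si, sample in enumerate(samples):
        ev = sample_events[sample]
        for chrom, sub in cons.groupby("chrom"):
            pos = np.sort(ev.loc[ev["chrom"] == chrom, "pos"].to_numpy())
            if len(pos) == 0:
                continue
            lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
            hi = np.searchsorted(pos, sub["end"].to_numpy(), side="left")
            counts[sub.index.to_numpy(), si] = hi - lo
    return RegionCountMatrix(
        regions=cons, samples=samples, groups=dict(groups), counts=counts
    )


def estimate_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors, rescaled to geometric
    mean 1.

    Each sample's factor is the median over all-positive regions of the
    sample count divided by the region's geometric mean across samples.
    Falls back to total-count ratios (with a warning) when no region is
    positive in every sample.
    """
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        warnings.warn("no region positive in all samples; using total-count ratios")
        totals = counts.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("sample with zero total count")
        sf = totals
    else:
        sub = counts[positive]
        log_gm = np.mean(np.log(sub), axis=1)
        ratios = sub / np.exp(log_gm)[:, None]
        sf = np.median(ratios, axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return sf


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_table(
    counts: np.ndarray,
    test_cols: np.ndarray,
    ref_cols: np.ndarray,
    size_factors: np.ndarray,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Core per-feature NB Wald computation shared by the accessibility
    and expression tests.  Returns base_mean, log2fc, dispersion, p."""
    norm = np.asarray(counts, dtype=float) / size_factors[None, :]
    c1, c0 = norm[:, test_cols], norm[:, ref_cols]
    n1, n0 = c1.shape[1], c0.shape[1]
    m1, m0 = c1.mean(axis=1), c0.mean(axis=1)
    v1 = c1.var(axis=1, ddof=1)
    v0 = c0.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(m1 > 0, (v1 - m1) / np.maximum(m1, 1e-12) ** 2, 0.0)
        a0 = np.where(m0 > 0, (v0 - m0) / np.maximum(m0, 1e-12) ** 2, 0.0)
    raw_disp = ((n1 - 1) * a1 + (n0 - 1) * a0) / (n1 + n0 - 2)
    # per-feature moment estimates at 2-3 replicates are too noisy to
    # stand alone: floor each at the experiment-wide mean dispersion
    # (information sharing across features, in the spirit of common-
    # dispersion moderation), which keeps the Wald normal reference
    # calibrated at small n while retaining per-feature adaptation above
    # the floor
    common = float(np.mean(np.maximum(raw_disp, 0.0))) if len(raw_disp) else 0.0
    disp = np.maximum(raw_disp, max(common, dispersion_floor))
    lfc = np.log2((m1 + LFC_PSEUDOCOUNT) / (m0 + LFC_PSEUDOCOUNT))
    ln2_sq = np.log(2.0) ** 2
    var1 = (1.0 / np.maximum(m1, LFC_PSEUDOCOUNT) + disp) / (n1 * ln2_sq)
    var0 = (1.0 / np.maximum(m0, LFC_PSEUDOCOUNT) + disp) / (n0 * ln2_sq)
    se = np.sqrt(var1 + var0)
    z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    allzero = (m1 == 0) & (m0 == 0)
    lfc[allzero] = 0.0
    p[allzero] = 1.0
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": lfc,
            "dispersion": disp,
            "p_value": p,
        }
    )


def nb_group_test(
    matrix: RegionCountMatrix,
    test_group: str = "cci",
    ref_group: str = "naive",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Differential accessibility per consensus region.

    ``log2fc`` is test (injured) over reference (naive); the call in
    ``direction`` uses the raw p-value threshold ``alpha`` while
    Benjamini-Hochberg ``q_value`` is reported alongside.
    """
    test_cols = matrix.group_columns(test_group)
    ref_cols = matrix.group_columns(ref_group)
    if len(test_cols) < 2 or len(ref_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    if matrix.size_factors is None:
        matrix.size_factors = estimate_size_factors(matrix.counts)
    res = nb_wald_table(matrix.counts, test_cols, ref_cols, matrix.size_factors)
    res = pd.concat(
        [matrix.regions[["chrom", "start", "end"]].reset_index(drop=True), res],
        axis=1,
    )
    res["q_value"] = bh_adjust(res["p_value"].to_numpy())
    sig = res["p_value"].to_numpy() < alpha
    direction = np.where(
        sig, np.where(res["log2fc"].to_numpy() > 0, "increased", "decreased"), "ns"
    )
    direction[sig & (res["log2fc"].to_numpy() == 0)] = "ns"
    res["direction"] = direction
    return res


def sample_qc(matrix: RegionCountMatrix) -> dict:
    """Sample-level QC on log2(normalized counts + 1).

    Returns PCA coordinates with variance-explained fractions, an
    average-linkage tree on 1 - Pearson correlation distances, and the
    sample correlation matrix.
    """
    if len(matrix.samples) < 3:
        raise ValueError("need at least 3 samples for QC")
    x = np.log2(matrix.normalized() + 1.0).T  # samples x regions
    centered = x - x.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("constant count matrix: QC is degenerate")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords = u * s
    var_frac = s**2 / np.sum(s**2)
    corr = np.corrcoef(x)
    dist = squareform(1.0 - corr, checks=False)
    linkage = hierarchy.linkage(dist, method="average")
    return {
        "pca": pd.DataFrame(
            coords[:, : min(3, coords.shape[1])],
            index=matrix.samples,
            columns=[f"PC{i+1}" for i in range(min(3, coords.shape[1]))],
        ),
        "variance_explained": var_frac,
        "linkage": linkage,
        "correlation": pd.DataFrame(
            corr, index=matrix.samples, columns=matrix.samples
        ),
    }
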