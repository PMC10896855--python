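"""Differential expression for the knockdown RNA-seq experiment.

Genes with any zero count are removed, counts are normalized by
median-of-ratios size factors and tested with the same negative-
binomial Wald procedure used for chromatin accessibility
(:func:`atacre.differential.nb_wald_table`).  Calls use the strict
thresholds adjusted p < 0.05 and |log2 fold change| > 0.5.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .differential import bh_adjust, estimate_size_factors, nb_wald_table

__all__ = ["filter_low_counts", "de_test", "classify_de"]

DEFAULT_Q_MAX = 0.05
DEFAULT_LFC_MIN = 0.5


def _count_parts(counts: pd.DataFrame) -> tuple[np.ndarray, list[str], np.ndarray]:
    samples = [c for c in counts.columns if c != "gene_id"]
    mat = counts[samples].to_numpy()
    genes = (
        counts["gene_id"].to_numpy()
        if "gene_id" in counts.columns
        else np.array([f"row{i}" for i in range(len(counts))])
    )
    return mat, samples, genes


def filter_low_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep genes with > 0 reads in every sample.

    Returns the filtered table and the number of genes removed.
    """
    mat, samples, _ = _count_parts(counts)
    if np.any(mat < 0) or not np.issubdtype(mat.dtype, np.integer):
        mat = mat.astype(int)
    keep = np.all(mat > 0, axis=1)
    removed = int((~keep).sum())
    out = counts.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("low-count filter removed every gene")
    return out, removed


def de_test(
    counts: pd.DataFrame,
    groups: dict[str, str],
    test_group: str,
    ref_group: str,
    size_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``test_group`` versus ``ref_group``.

    ``counts`` is a gene x sample table with a ``gene_id`` column;
    ``groups`` maps sample names to group labels.  Returns gene_id,
    base_mean, log2fc, dispersion, p_value, q_value.
    """
    mat, samples, genes = _count_parts(counts)
    test_cols = np.array([i for i, s in enumerate(samples) if groups[s] == test_group])
    ref_cols = np.array([i for i, s in enumerate(samples) if groups[s] == ref_group])
    if len(test_cols) < 2 or len(ref_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    if size_factors is None:
        size_factors = estimate_size_factors(mat)
    res = nb_wald_table(mat, test_cols, ref_cols, size_factors)
    res.insert(0, "gene_id", genes)
    res["q_value"] = bh_adjust(res["p_value"].to_numpy())
    return res


def classify_de(
    results: pd.DataFrame,
    q_max: float = DEFAULT_Q_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> pd.DataFrame:
    """Attach up/down/ns calls with strict thresholds
    (``q < q_max`` and ``|log2fc| > lfc_min``)."""
    out = results.reset_index(drop=True).copy()
    q = out["q_value"].to_numpy()
    lfc = out["log2fc"].to_numpy()
    call = np.full(len(out), "ns", dtype=object)
    call[(q < q_max) & (lfc > lfc_min)] = "up"
    call[(q < q_max) & (lfc < -lfc_min)] = "down"
    out["call"] = call
    return out
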