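"""Feature classification of regions and integration with expression.

Regions are classified by their midpoint with priority
promoter > exon > intron > intergenic (the promoter window is
strand-oriented around the TSS, default 1000 bp upstream / 100 bp
downstream), attached to their nearest gene by TSS distance, and merged
with a differential-expression table to flag direction-concordant
region/gene pairs — e.g. regions that gained accessibility after
injury whose nearest gene was also upregulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals as gi

__all__ = [
    "classify_feature",
    "annotate_regions",
    "integrate_expression",
    "summarize_counts",
    "pct",
]

FEATURE_CLASSES = ("promoter", "exon", "intron", "intergenic")
CONCORDANCE = ("acc_up_expr_up", "acc_down_expr_down", "discordant", "none")


def pct(part: float, total: float, digits: int = 1) -> float:
    """Percentage of ``part`` in ``total`` rounded to the printed
    precision used in summary reports."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round(100.0 * part / total, digits)


def _promoter_windows(genes: pd.DataFrame, upstream: int, downstream: int) -> pd.DataFrame:
    tss = genes["tss"].to_numpy()
    plus = genes["strand"].to_numpy() == "+"
    start = np.where(plus, tss - upstream, tss - downstream + 1)
    end = np.where(plus, tss + downstream, tss + upstream + 1)
    return pd.DataFrame(
        {"chrom": genes["chrom"].to_numpy(), "start": np.maximum(start, 0), "end": end}
    )


def classify_feature(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    exons: pd.DataFrame | None = None,
    promoter_window: tuple[int, int] = (1000, 100),
) -> np.ndarray:
    """Feature class per region, assigned by region midpoint.

    ``promoter_window = (upstream, downstream)`` bases around the TSS,
    oriented by gene strand.  A midpoint inside a gene body but not in
    an annotated exon is intronic; without an exon table the whole gene
    body counts as exonic.
    """
    regions = regions.reset_index(drop=True)
    mids = (regions["start"].to_numpy() + regions["end"].to_numpy()) // 2
    mid_iv = pd.DataFrame(
        {"chrom": regions["chrom"].to_numpy(), "start": mids, "end": mids + 1}
    )
    out = np.full(len(regions), "intergenic", dtype=object)
    if len(genes) == 0:
        return out

    def _hits(targets: pd.DataFrame) -> np.ndarray:
        mask = np.zeros(len(regions), dtype=bool)
        if len(targets):
            pairs = gi.overlap_pairs(mid_iv, targets)
            if len(pairs):
                mask[pairs["a_index"].unique()] = True
        return mask

    bodies = pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": genes["start"].to_numpy(),
            "end": genes["end"].to_numpy(),
        }
    )
    in_gene = _hits(bodies)
    in_exon = _hits(
        exons[["chrom", "start", "end"]] if exons is not None and len(exons) else bodies
    )
    in_promoter = _hits(_promoter_windows(genes, *promoter_window))
    out[in_gene] = "intron"
    out[in_exon & in_gene] = "exon"
    out[in_promoter] = "promoter"
    return out


def annotate_regions(
    results: pd.DataFrame,
    genes: pd.DataFrame,
    exons: pd.DataFrame | None = None,
    promoter_window: tuple[int, int] = (1000, 100),
) -> pd.DataFrame:
    """Attach feature class, nearest gene and TSS distance to a
    differential-result table."""
    out = gi.nearest_tss(results, genes)
    out["feature_class"] = classify_feature(
        results, genes, exons=exons, promoter_window=promoter_window
    )
    return out


def integrate_expression(dars: pd.DataFrame, de_table: pd.DataFrame) -> pd.DataFrame:
    """Join annotated regions with gene-level expression calls.

    ``de_table`` needs ``gene_id`` and ``call`` ({up, down, ns})
    columns.  Adds ``expression`` (up/down/ns/absent) and
    ``concordance``: a region counts as concordant only when its
    accessibility direction and its nearest gene's expression move the
    same way.
    """
    calls = dict(zip(de_table["gene_id"], de_table["call"]))
    out = dars.reset_index(drop=True).copy()
    expr = [
        calls.get(g, "absent") if g is not None else "absent"
        for g in out["nearest_gene"]
    ]
    out["expression"] = expr
    conc = []
    for d, e in zip(out["direction"], expr):
        if d == "increased" and e == "up":
            conc.append("acc_up_expr_up")
        elif d == "decreased" and e == "down":
            conc.append("acc_down_expr_down")
        elif d in ("increased", "decreased") and e in ("up", "down"):
            conc.append("discordant")
        else:
            conc.append("none")
    out["concordance"] = conc
    return out


def summarize_counts(annotated: pd.DataFrame) -> pd.DataFrame:
    """Region counts by feature class x direction, with concordant
    region and distinct-gene tallies.

    Distinct-gene counts deduplicate shared nearest genes, which is why
    a report can pair more regions than genes.
    """
    rows = []
    for fc in FEATURE_CLASSES:
        sub = annotated[annotated["feature_class"] == fc] if len(annotated) else annotated
        inc = int((sub["direction"] == "increased").sum()) if len(sub) else 0
        dec = int((sub["direction"] == "decreased").sum()) if len(sub) else 0
        up_pairs = sub[sub["concordance"] == "acc_up_expr_up"] if len(sub) else sub
        down_pairs = sub[sub["concordance"] == "acc_down_expr_down"] if len(sub) else sub
        rows.append(
            {
                "feature_class": fc,
                "n_regions": len(sub),
                "increased": inc,
                "decreased": dec,
                "significant": inc + dec,
                "concordant_up_regions": len(up_pairs),
                "concordant_up_genes": up_pairs["nearest_gene"].nunique() if len(up_pairs) else 0,
                "concordant_down_regions": len(down_pairs),
                "concordant_down_genes": down_pairs["nearest_gene"].nunique() if len(down_pairs) else 0,
            }
        )
    return pd.DataFrame(rows)
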