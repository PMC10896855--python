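"""End-to-end run of the accessibility pipeline on a synthetic study.

Glue only: every step is a public function of the corresponding
module.  The returned bundle carries all intermediates plus recovery
metrics against the planted truth (sensitivity of planted differential
regions, false-positive fraction among unplanted regions, recovery of
planted direction-concordant region/gene pairs, and protein-array hit
calls).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import annotate as ann
from . import atac
from . import differential as diff
from . import expression as expr
from . import intervals as gi
from . import synthetic as syn
from . import tfarray

__all__ = ["run_end_to_end", "recovery_metrics"]


def run_end_to_end(
    design: syn.SyntheticDesign | None = None,
    bundle: dict | None = None,
    alpha: float = diff.DEFAULT_ALPHA,
    min_support: int = 2,
) -> dict:
    """Generate (or reuse) a synthetic study and run every stage.

    Returns the input bundle extended with events, per-sample peaks,
    consensus regions, the count matrix, differential results,
    annotated/integrated regions, expression calls, array hits and
    truth-recovery metrics.
    """
    if bundle is None:
        if design is None:
            design = syn.SyntheticDesign()
        bundle = syn.generate_all(design)
    design = bundle["design"]
    chrom_sizes = design.chrom_sizes
    groups = design.sample_groups

    events: dict[str, pd.DataFrame] = {}
    dropped: dict[str, int] = {}
    peaks: dict[str, pd.DataFrame] = {}
    for sample, frags in bundle["fragments"].items():
        ev, n_drop = atac.fragments_to_insertions(frags, chrom_sizes)
        events[sample] = ev
        dropped[sample] = n_drop
        peaks[sample] = atac.call_peaks_simple(ev, chrom_sizes, sample_id=sample)

    consensus = diff.reproducible_consensus(peaks, groups, min_support_per_group=min_support)
    consensus_marked = diff.subset_by_mark(consensus, bundle["marks"])
    matrix = diff.count_matrix(consensus_marked, events, groups)
    matrix.size_factors = diff.estimate_size_factors(matrix.counts)
    results = diff.nb_group_test(matrix, alpha=alpha)

    annotated = ann.annotate_regions(results, bundle["genes"], exons=bundle["exons"])

    rna_filtered, n_removed = expr.filter_low_counts(bundle["rna_counts"])
    de = expr.classify_de(
        expr.de_test(rna_filtered, groups, test_group="cci", ref_group="naive")
    )
    integrated = ann.integrate_expression(annotated, de)
    summary = ann.summarize_counts(integrated)

    scored = tfarray.score_spots(bundle["array_spots"])
    hits, excluded = tfarray.call_hits(scored)

    out = dict(bundle)
    out.update(
        events=events,
        dropped_events=dropped,
        peaks=peaks,
        consensus=consensus,
        consensus_marked=consensus_marked,
        matrix=matrix,
        results=results,
        annotated=annotated,
        de=de,
        rna_removed=n_removed,
        integrated=integrated,
        summary=summary,
        array_scored=scored,
        array_hits=hits,
        array_excluded=excluded,
    )
    out["metrics"] = recovery_metrics(out)
    return out


def recovery_metrics(run: dict) -> dict:
    """Planted-truth recovery numbers for a completed run."""
    truth: syn.PlantedTruth = run["truth"]
    integrated: pd.DataFrame = run["integrated"]
    planted = truth.dar_regions
    metrics: dict[str, float | int] = {}

    # map tested regions onto planted differential regions
    pairs = gi.overlap_pairs(integrated, planted)
    planted_hit_dirs: dict[int, set[str]] = {}
    tested_is_planted = np.zeros(len(integrated), dtype=bool)
    for _, row in pairs.iterrows():
        ai, bi = int(row["a_index"]), int(row["b_index"])
        tested_is_planted[ai] = True
        planted_hit_dirs.setdefault(bi, set()).add(integrated.iloc[ai]["direction"])
    want = {1: "increased", -1: "decreased"}
    recovered = sum(
        1
        for bi, dirs in planted_hit_dirs.items()
        if want[int(planted.iloc[bi]["direction"])] in dirs
    )
    metrics["n_planted_dar"] = len(planted)
    metrics["n_planted_tested"] = len(planted_hit_dirs)
    metrics["dar_sensitivity"] = recovered / len(planted) if len(planted) else float("nan")
    null_tested = integrated.loc[~tested_is_planted]
    metrics["n_null_tested"] = len(null_tested)
    metrics["null_positive_fraction"] = (
        float((null_tested["direction"] != "ns").mean()) if len(null_tested) else float("nan")
    )

    # planted concordant region/gene pairs: a pair is recovered when a
    # significant tested region overlapping the planted region has the
    # planted direction and carries the planted gene with a matching call
    planted_pairs = truth.concordant_genes
    by_region = dict(zip(planted["region_id"], planted.index))
    n_rec = 0
    for _, pp in planted_pairs.iterrows():
        bi = by_region.get(pp["region_id"])
        if bi is None:
            continue
        sub = pairs[pairs["b_index"] == bi]
        ok = False
        for ai in sub["a_index"]:
            row = integrated.iloc[int(ai)]
            if (
                row["direction"] == want[int(pp["direction"])]
                and row["nearest_gene"] == pp["gene_id"]
                and row["concordance"] in ("acc_up_expr_up", "acc_down_expr_down")
            ):
                ok = True
        n_rec += ok
    metrics["n_planted_pairs"] = len(planted_pairs)
    metrics["planted_pairs_recovered"] = n_rec

    hits = run["array_hits"]
    binders = set(truth.array_binders["protein_id"])
    metrics["array_hits"] = len(hits)
    metrics["array_planted_binders"] = len(binders)
    metrics["array_binders_called"] = int(hits["protein_id"].isin(binders).sum()) if len(hits) else 0
    return metrics
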