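"""Deterministic calculators for reporter and ChIP-qPCR readouts.

Luciferase reporter activity is firefly luminescence normalized to the
co-transfected Renilla control, expressed as fold over the empty
vector (mean of replicate ratios, SEM from the construct replicates
only).  ChIP-qPCR is summarized as percent input with
dilution-adjusted input Ct and as fold enrichment over the IgG
control; amplification efficiency is fixed at 2 per cycle.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["relative_activity", "percent_input", "fold_enrichment", "fold_enrichment_ct"]


def relative_activity(
    wells: pd.DataFrame, empty_id: str = "empty"
) -> pd.DataFrame:
    """Mean fold activity of each construct over the empty vector, with
    SEM across the construct's replicate wells.

    ``wells`` columns: construct_id, firefly, renilla.  Wells with
    non-positive Renilla signal are excluded.  The empty-vector rows
    (``construct_id == empty_id``) define the denominator.
    """
    df = wells.copy()
    bad = df["renilla"] <= 0
    df = df[~bad]
    empty = df[df["construct_id"] == empty_id]
    if len(empty) == 0:
        raise ValueError(f"no usable wells for empty vector {empty_id!r}")
    ratio = df["firefly"] / df["renilla"]
    df = df.assign(ratio=ratio)
    denom = float(df.loc[df["construct_id"] == empty_id, "ratio"].mean())
    rows = []
    for cid, sub in df.groupby("construct_id", sort=False):
        r = sub["ratio"].to_numpy(dtype=float)
        fold = float(r.mean() / denom)
        sem = float(r.std(ddof=1) / math.sqrt(len(r)) / denom) if len(r) > 1 else float("nan")
        rows.append(
            {"construct_id": cid, "n_wells": len(r), "fold": fold, "sem": sem}
        )
    return pd.DataFrame(rows)


def percent_input(
    ct_ip: float, ct_input: float, input_dilution_fraction: float
) -> float:
    """Immunoprecipitated DNA as percent of (dilution-corrected) input.

    The input Ct is first adjusted by ``log2(1 / dilution)`` cycles to
    represent undiluted chromatin; percent input is then
    ``100 * 2 ** (adjusted input Ct - IP Ct)``.
    """
    if not 0.0 < input_dilution_fraction <= 1.0:
        raise ValueError("input_dilution_fraction must lie in (0, 1]")
    if ct_ip <= 0 or ct_input <= 0:
        raise ValueError("Ct values must be positive")
    ct_adj = ct_input - math.log2(1.0 / input_dilution_fraction)
    return 100.0 * 2.0 ** (ct_adj - ct_ip)


def fold_enrichment(ip_percent: float, igg_percent: float) -> float:
    """Target-antibody percent input over the IgG-control percent input."""
    if igg_percent <= 0:
        raise ValueError(
            "IgG percent input must be positive; check the IgG/no-template controls"
        )
    return ip_percent / igg_percent


def fold_enrichment_ct(
    ct_ip: np.ndarray,
    ct_igg: np.ndarray,
    ct_input: np.ndarray,
    input_dilution_fraction: float,
) -> dict:
    """Replicate-level fold enrichment (mean ± SEM) straight from Ct
    triplets.  Replicates are paired elementwise."""
    ct_ip = np.atleast_1d(np.asarray(ct_ip, float))
    ct_igg = np.atleast_1d(np.asarray(ct_igg, float))
    ct_input = np.atleast_1d(np.asarray(ct_input, float))
    if not len(ct_ip) == len(ct_igg) == len(ct_input):
        raise ValueError("replicate arrays must have equal length")
    folds = np.array(
        [
            fold_enrichment(
                percent_input(a, c, input_dilution_fraction),
                percent_input(b, c, input_dilution_fraction),
            )
            for a, b, c in zip(ct_ip, ct_igg, ct_input)
        ]
    )
    sem = float(folds.std(ddof=1) / math.sqrt(len(folds))) if len(folds) > 1 else float("nan")
    return {"fold": float(folds.mean()), "sem": sem, "n": len(folds)}
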