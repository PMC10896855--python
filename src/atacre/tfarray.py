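"""Protein-microarray binding scores and the all-4-spots hit rule.

Each printed protein occupies two spots per array and is assayed on a
dye-swap pair of arrays, so a protein has exactly four spots.  The raw
spot intensity is the ratio of foreground to background medians
(F/B); it is normalized by the median raw signal of the spot's
neighbouring probes (8-connected ring by default) to cancel spatial
gradients, and converted to a Z-score against the array's noise model —
the trimmed mean and standard deviation of all valid normalized
intensities, the top ``trim_fraction`` discarded because true binders
are rare bright outliers.  A protein is a hit only when all four of
its spots exceed the Z cutoff strictly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ArrayNoiseModel",
    "raw_intensity",
    "local_normalize",
    "fit_noise_model",
    "score_spots",
    "call_hits",
]

B_FLOOR = 1.0           # background median floor (intensity units)
DEFAULT_TRIM = 0.05
DEFAULT_Z_MIN = 3.0
MIN_MODEL_SPOTS = 30
CONTROL_PREFIX = "T7"   # labeled-primer control probes: never callable


class ModelError(ValueError):
    """Raised when the array noise model cannot be fit."""


@dataclass(frozen=True)
class ArrayNoiseModel:
    """Trimmed location/scale of an array's normalized intensities."""

    noise_mean: float
    noise_sd: float
    n_spots_used: int
    trim_fraction: float

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ModelError("degenerate noise model (sd <= 0)")
        if self.n_spots_used < MIN_MODEL_SPOTS:
            raise ModelError(
                f"noise model needs >= {MIN_MODEL_SPOTS} spots, "
                f"got {self.n_spots_used}"
            )

    def z(self, r_prime: np.ndarray) -> np.ndarray:
        return (np.asarray(r_prime, float) - self.noise_mean) / self.noise_sd


def raw_intensity(f: np.ndarray, b: np.ndarray, floor: float = B_FLOOR) -> np.ndarray:
    """Foreground over (floored) background medians, elementwise."""
    f = np.asarray(f, dtype=float)
    b = np.asarray(b, dtype=float)
    return f / np.maximum(b, floor)


def local_normalize(grid: np.ndarray, radius: int = 1) -> np.ndarray:
    """Normalize each grid cell by the median of its ring neighbourhood.

    ``radius = 1`` is the 8-connected ring; edge and corner cells use
    the neighbours that exist (5 or 3 for radius 1).  Cells whose
    neighbourhood median is <= 0 or undefined come back NaN (invalid).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or min(grid.shape) < 3:
        raise ValueError("grid must be at least 3x3")
    nrow, ncol = grid.shape
    # stack every ring offset as a NaN-padded shifted copy, then take
    # the nanmedian across the stack (edges see 5, corners 3 neighbours)
    offsets = [
        (di, dj)
        for di in range(-radius, radius + 1)
        for dj in range(-radius, radius + 1)
        if not (di == 0 and dj == 0)
    ]
    stack = np.full((len(offsets), nrow, ncol), np.nan)
    for k, (di, dj) in enumerate(offsets):
        src_i = slice(max(-di, 0), min(nrow - di, nrow))
        dst_i = slice(max(di, 0), min(nrow + di, nrow))
        src_j = slice(max(-dj, 0), min(ncol - dj, ncol))
        dst_j = slice(max(dj, 0), min(ncol + dj, ncol))
        stack[k][dst_i, dst_j] = grid[src_i, src_j]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(stack, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.isnan(med) | (med <= 0), np.nan, grid / med)
    return out


def fit_noise_model(
    r_prime: np.ndarray, trim_fraction: float = DEFAULT_TRIM
) -> ArrayNoiseModel:
    """Mean/sd of normalized intensities after discarding the brightest
    ``trim_fraction`` (``0`` means plain mean/sd)."""
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must lie in [0, 1)")
    vals = np.asarray(r_prime, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < MIN_MODEL_SPOTS:
        raise ModelError(f"need >= {MIN_MODEL_SPOTS} valid spots, got {len(vals)}")
    vals = np.sort(vals)
    n_drop = int(np.ceil(trim_fraction * len(vals))) if trim_fraction > 0 else 0
    kept = vals[: len(vals) - n_drop] if n_drop else vals
    sd = float(np.std(kept, ddof=1))
    if sd <= 0:
        raise ModelError("degenerate noise model (sd = 0)")
    return ArrayNoiseModel(
        noise_mean=float(np.mean(kept)),
        noise_sd=sd,
        n_spots_used=len(kept),
        trim_fraction=trim_fraction,
    )


def score_spots(
    spots: pd.DataFrame,
    trim_fraction: float = DEFAULT_TRIM,
    radius: int = 1,
    b_floor: float = B_FLOOR,
) -> pd.DataFrame:
    """Full per-spot scoring across a dye-swap pair of arrays.

    ``spots`` columns: array_id, row, col, protein_id, replicate, dye,
    F, B.  Adds ``raw``, ``r_prime`` and ``z`` (noise model fit per
    array; control probes — protein ids starting with ``T7`` — are
    excluded from the model but still scored).
    """
    required = {"array_id", "row", "col", "protein_id", "F", "B"}
    missing = required - set(spots.columns)
    if missing:
        raise ValueError(f"spot table missing columns {sorted(missing)}")
    out = spots.reset_index(drop=True).copy()
    out["raw"] = raw_intensity(out["F"].to_numpy(), out["B"].to_numpy(), floor=b_floor)
    out.loc[out["F"].isna(), "raw"] = np.nan
    out["r_prime"] = np.nan
    out["z"] = np.nan
    for array_id, sub in out.groupby("array_id"):
        nrow = int(sub["row"].max()) + 1
        ncol = int(sub["col"].max()) + 1
        grid = np.full((nrow, ncol), np.nan)
        grid[sub["row"].to_numpy(), sub["col"].to_numpy()] = sub["raw"].to_numpy()
        rp = local_normalize(grid, radius=radius)
        rp_vals = rp[sub["row"].to_numpy(), sub["col"].to_numpy()]
        out.loc[sub.index, "r_prime"] = rp_vals
        is_control = sub["protein_id"].astype(str).str.startswith(CONTROL_PREFIX)
        model = fit_noise_model(rp_vals[~is_control.to_numpy()], trim_fraction)
        out.loc[sub.index, "z"] = model.z(rp_vals)
    return out


def call_hits(
    scored: pd.DataFrame, z_min: float = DEFAULT_Z_MIN
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proteins whose four spots all exceed ``z_min`` strictly.

    Returns ``(hits, excluded)``: hits with the four z-values and their
    minimum, and proteins excluded for not having exactly 4 valid
    (non-NaN) spots.  Control probes are never callable.
    """
    hits = []
    excluded = []
    for pid, sub in scored.groupby("protein_id"):
        if str(pid).startswith(CONTROL_PREFIX):
            continue
        z = sub["z"].to_numpy()
        valid = z[~np.isnan(z)]
        if len(valid) != 4:
            excluded.append({"protein_id": pid, "n_valid_spots": len(valid)})
            continue
        if np.all(valid > z_min):
            hits.append(
                {
                    "protein_id": pid,
                    "z1": valid[0],
                    "z2": valid[1],
                    "z3": valid[2],
                    "z4": valid[3],
                    "z_min": float(valid.min()),
                }
            )
    hit_df = pd.DataFrame(
        hits, columns=["protein_id", "z1", "z2", "z3", "z4", "z_min"]
    )
    excl_df = pd.DataFrame(excluded, columns=["protein_id", "n_valid_spots"])
    return hit_df, excl_df
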