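"""Synthetic multi-omic inputs with planted ground truth.

Emulates the statistical structure of a two-condition (naive vs injured)
sensory-ganglion experiment on a toy genome: accessible chromatin
regions whose insertion rates differ between groups at a planted
minority of regions, H3K4me1 enhancer marks co-localized with them,
RNA counts whose planted shifts are direction-concordant with the
nearest differential region, and dye-swap protein-microarray grids with
rare strong binders.

Every generator is deterministic under the design seed; per-sample
streams are spawned from ``(seed, stream_index)`` so adding samples
never reshuffles earlier ones.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals as gi

__all__ = [
    "SyntheticDesign",
    "PlantedTruth",
    "generate_genome_and_genes",
    "generate_genome_sequence",
    "place_accessible_regions",
    "generate_atac_fragments",
    "generate_h3k4me1_regions",
    "generate_rna_counts",
    "generate_tf_array",
    "generate_all",
    "write_all",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the simulated study.

    Defaults mirror the real design's shape at desk scale: two
    chromosomes of 2.5 Mb, 200 genes, 300 accessible regions of which
    10% respond to injury with a 3-fold accessibility change, 3
    biological replicates per group and 2x10^5 Tn5 fragments per
    sample.
    """

    genome_length: int = 2_500_000
    n_chromosomes: int = 2
    n_genes: int = 200
    n_accessible_regions: int = 300
    frac_dar: float = 0.10
    dar_effect: float = 3.0
    n_samples_per_group: int = 3
    depth: int = 200_000
    h3k4me1_cover_frac: float = 0.8
    frac_concordant_genes: float = 0.5
    seed: int = 0
    # secondary knobs (kept stable across the package's own studies)
    peak_insertion_frac: float = 0.5
    rna_base_mean: float = 500.0
    rna_dispersion: float = 0.05
    rna_log2fc: float = 2.0
    array_n_proteins: int = 500
    array_n_cols: int = 25
    array_n_binders: int = 1
    array_binder_multiplier: float = 10.0

    def __post_init__(self) -> None:
        for name in ("frac_dar", "h3k4me1_cover_frac", "frac_concordant_genes",
                     "peak_insertion_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("genome_length", "n_chromosomes", "depth",
                     "n_samples_per_group", "array_n_proteins", "array_n_cols"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_accessible_regions", "array_n_binders"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dar_effect <= 0:
            raise ValueError("dar_effect must be > 0")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i+1}": self.genome_length for i in range(self.n_chromosomes)}

    @property
    def sample_groups(self) -> dict[str, str]:
        out = {}
        for g in ("naive", "cci"):
            for i in range(self.n_samples_per_group):
                out[f"{g}_{i+1}"] = g
        return out


@dataclass
class PlantedTruth:
    """What the generator planted, for downstream recovery checks."""

    dar_regions: pd.DataFrame       # region_id, chrom, start, end, direction
    concordant_genes: pd.DataFrame  # region_id, gene_id, direction
    array_binders: pd.DataFrame     # protein_id, multiplier

    def to_tsv(self, path) -> None:
        rows = []
        for _, r in self.dar_regions.iterrows():
            rows.append(("dar", r["region_id"], r["chrom"], r["start"], r["end"],
                         r["direction"], ""))
        for _, r in self.concordant_genes.iterrows():
            rows.append(("concordant_gene", r["gene_id"], "", "", "",
                         r["direction"], r["region_id"]))
        for _, r in self.array_binders.iterrows():
            rows.append(("array_binder", r["protein_id"], "", "", "", "",
                         r["multiplier"]))
        pd.DataFrame(
            rows, columns=["kind", "id", "chrom", "start", "end", "direction", "extra"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PlantedTruth":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        dar = df[df["kind"] == "dar"]
        con = df[df["kind"] == "concordant_gene"]
        bind = df[df["kind"] == "array_binder"]
        return cls(
            dar_regions=pd.DataFrame(
                {
                    "region_id": dar["id"].to_numpy(),
                    "chrom": dar["chrom"].to_numpy(),
                    "start": dar["start"].astype(int).to_numpy(),
                    "end": dar["end"].astype(int).to_numpy(),
                    "direction": dar["direction"].astype(int).to_numpy(),
                }
            ),
            concordant_genes=pd.DataFrame(
                {
                    "region_id": con["extra"].to_numpy(),
                    "gene_id": con["id"].to_numpy(),
                    "direction": con["direction"].astype(int).to_numpy(),
                }
            ),
            array_binders=pd.DataFrame(
                {
                    "protein_id": bind["id"].to_numpy(),
                    "multiplier": bind["extra"].astype(float).to_numpy(),
                }
            ),
        )


def _rng(design: SyntheticDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng([design.seed, stream])


# stream indices for independent generator stages
_S_GENES, _S_REGIONS, _S_SEQ, _S_MARKS, _S_RNA, _S_ARRAY, _S_FRAG0 = range(7)
_FRAG_STRIDE = 100


def generate_genome_and_genes(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Toy chromosome-size table plus non-overlapping gene models.

    Genes are laid out in evenly spaced slots with random offsets;
    each carries a strand, TSS/TES and 1-4 exons spanning the body.
    Returns (chrom_sizes, genes, exons).
    """
    rng = _rng(design, _S_GENES)
    sizes = pd.DataFrame(
        {"chrom": list(design.chrom_sizes), "length": list(design.chrom_sizes.values())}
    )
    if design.n_genes == 0:
        genes = pd.DataFrame(
            columns=["gene_id", "chrom", "tss", "tes", "strand", "start", "end"]
        )
        exons = pd.DataFrame(columns=["gene_id", "start", "end", "chrom"])
        return sizes, genes, exons
    per_chrom = _split_counts(design.n_genes, design.n_chromosomes)
    rows, exon_rows = [], []
    gene_idx = 0
    for ci, (chrom, n_here) in enumerate(zip(design.chrom_sizes, per_chrom)):
        if n_here == 0:
            continue
        slot = design.genome_length // n_here
        if slot < 3_000:
            raise ValueError(
                f"genome too small to place {design.n_genes} genes "
                f"({slot} bp per slot, need >= 3000)"
            )
        for k in range(n_here):
            gene_id = f"g{gene_idx + 1:04d}"
            gene_idx += 1
            length = int(rng.integers(2_000, min(10_000, int(slot * 0.8)) + 1))
            lo = k * slot
            start = int(rng.integers(lo + 100, lo + slot - length - 100))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (start, end) if strand == "+" else (end - 1, start)
            n_exons = int(rng.integers(1, 5))
            cuts = np.sort(rng.choice(
                np.arange(start + 50, end - 50), size=2 * (n_exons - 1), replace=False
            )) if n_exons > 1 else np.array([], dtype=int)
            bounds = np.concatenate([[start], cuts, [end]])
            for e in range(n_exons):
                exon_rows.append((gene_id, chrom, int(bounds[2 * e]), int(bounds[2 * e + 1])))
            rows.append((gene_id, chrom, tss, tes, strand, start, end))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "tes", "strand", "start", "end"]
    )
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    return sizes, genes, exons


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def generate_genome_sequence(design: SyntheticDesign) -> dict[str, str]:
    """Uniform-random nucleotide sequence per toy chromosome."""
    rng = _rng(design, _S_SEQ)
    return {
        chrom: _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        for chrom, length in design.chrom_sizes.items()
    }


def place_accessible_regions(design: SyntheticDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slot-placed, mutually disjoint accessible regions; a random
    ``frac_dar`` fraction becomes planted differential regions with a
    random sign.  Returns (regions, dar_truth_frame)."""
    rng = _rng(design, _S_REGIONS)
    n = design.n_accessible_regions
    per_chrom = _split_counts(n, design.n_chromosomes)
    rows = []
    idx = 0
    for chrom, n_here in zip(design.chrom_sizes, per_chrom):
        if n_here == 0:
            continue
        slot = design.genome_length // n_here
        if slot < 2_000:
            raise ValueError("genome too small for the requested region count")
        for k in range(n_here):
            width = int(np.clip(round(rng.normal(600, 100)), 300, 900))
            lo = k * slot
            start = int(rng.integers(lo + 500, lo + slot - width - 500))
            rows.append((f"r{idx + 1:04d}", chrom, start, start + width))
            idx += 1
    regions = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])
    n_dar = round(design.frac_dar * n)
    dar_idx = np.sort(rng.choice(n, size=n_dar, replace=False)) if n_dar else np.array([], dtype=int)
    direction = rng.choice([-1, 1], size=n_dar)
    regions["is_dar"] = False
    regions.loc[dar_idx, "is_dar"] = True
    regions["dar_direction"] = 0
    regions.loc[dar_idx, "dar_direction"] = direction
    dar_truth = regions.loc[dar_idx, ["region_id", "chrom", "start", "end"]].copy()
    dar_truth["direction"] = direction
    return regions, dar_truth.reset_index(drop=True)


# fragment-length mixture: nucleosome-free (~80 bp) and mono-nucleosome
# (~200 bp) modes; only the corrected ends matter downstream
_FRAG_MODES = ((80.0, 15.0, 0.6), (200.0, 25.0, 0.4))
_MIN_FRAG = 40


def generate_atac_fragments(
    design: SyntheticDesign,
    regions: pd.DataFrame,
    sample: str,
    stream: int,
) -> pd.DataFrame:
    """One sample's Tn5 fragments: a mixture of uniform background
    insertions and Gaussian-shaped insertion clusters at accessible
    regions (sd = width / 4 around the center).

    Injured-group samples multiply the insertion weight of each planted
    region by ``dar_effect ** direction``.  The fragment left end is
    placed so that its corrected plus-strand insertion (+4) lands at the
    drawn insertion position; fragment count equals ``design.depth``.
    """
    rng = _rng(design, _S_FRAG0 + _FRAG_STRIDE + stream)
    group = design.sample_groups[sample]
    chrom_sizes = design.chrom_sizes
    n_regions = len(regions)
    if design.depth < n_regions:
        import warnings

        warnings.warn("depth below region count; peaks will be sparse")
    n_peak = round(design.depth * design.peak_insertion_frac) if n_regions else 0
    n_bg = design.depth - n_peak
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    if n_peak:
        w = np.ones(n_regions)
        if group == "cci":
            d = regions["dar_direction"].to_numpy()
            w[d != 0] = design.dar_effect ** d[d != 0].astype(float)
        counts = rng.multinomial(n_peak, w / w.sum())
        centers = ((regions["start"] + regions["end"]) // 2).to_numpy()
        widths = (regions["end"] - regions["start"]).to_numpy()
        rchrom = regions["chrom"].to_numpy()
        for i in np.flatnonzero(counts):
            c = counts[i]
            pos = np.rint(rng.normal(centers[i], widths[i] / 4.0, size=c)).astype(int)
            pos = np.clip(pos, 0, chrom_sizes[rchrom[i]] - 1)
            positions.append(pos)
            chroms.append(np.full(c, rchrom[i]))
    if n_bg:
        names = list(chrom_sizes)
        lengths = np.array([chrom_sizes[c] for c in names], dtype=float)
        which = rng.choice(len(names), size=n_bg, p=lengths / lengths.sum())
        pos = (rng.random(n_bg) * lengths[which]).astype(int)
        positions.append(pos)
        chroms.append(np.array(names, dtype=object)[which])
    pos = np.concatenate(positions) if positions else np.array([], dtype=int)
    chrom = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    n = len(pos)
    mode = rng.random(n) < _FRAG_MODES[0][2]
    length = np.where(
        mode,
        rng.normal(_FRAG_MODES[0][0], _FRAG_MODES[0][1], n),
        rng.normal(_FRAG_MODES[1][0], _FRAG_MODES[1][1], n),
    )
    length = np.maximum(np.rint(length).astype(int), _MIN_FRAG)
    start = pos - 4  # corrected +strand insertion lands at pos
    end = start + length
    lengths_by_chrom = np.array([chrom_sizes[c] for c in chrom])
    start = np.clip(start, 0, None)
    end = np.minimum(end, lengths_by_chrom)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    frags = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "name": [f"{sample}_f{i}" for i in range(n)],
            "score": 0,
            "strand": strand,
        }
    )
    order = np.lexsort((frags["start"].to_numpy(), frags["chrom"].to_numpy()))
    return frags.iloc[order].reset_index(drop=True)


def generate_h3k4me1_regions(
    design: SyntheticDesign, regions: pd.DataFrame
) -> pd.DataFrame:
    """Enhancer-mark regions covering exactly
    ``round(h3k4me1_cover_frac * n_accessible_regions)`` accessible
    regions.

    Planted differential regions are covered first (injury-responsive
    CREs are modelled as marked enhancers); remaining coverage is
    random.  Mark regions are wider than the accessible region but
    padded only as far as they can reach without touching an uncovered
    neighbour, so the planted coverage count is exact.
    """
    rng = _rng(design, _S_MARKS)
    n = len(regions)
    n_cover = round(design.h3k4me1_cover_frac * n)
    dar_idx = np.flatnonzero(regions["is_dar"].to_numpy())
    others = np.setdiff1d(np.arange(n), dar_idx)
    if n_cover <= len(dar_idx):
        covered = rng.choice(dar_idx, size=n_cover, replace=False)
    else:
        extra = rng.choice(others, size=n_cover - len(dar_idx), replace=False)
        covered = np.concatenate([dar_idx, extra])
    covered = np.sort(covered)
    cov_mask = np.zeros(n, dtype=bool)
    cov_mask[covered] = True
    df = regions.sort_values(["chrom", "start"]).reset_index()
    rows = []
    for chrom, sub in df.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        orig = sub["index"].to_numpy()
        length = design.chrom_sizes[chrom]
        for k in range(len(sub)):
            if not cov_mask[orig[k]]:
                continue
            max_pad = 400
            left_gap = starts[k] - (ends[k - 1] if k > 0 else 0)
            right_gap = (starts[k + 1] if k + 1 < len(sub) else length) - ends[k]
            # never reach an uncovered neighbour
            pad_l = max_pad if (k == 0 or cov_mask[orig[k - 1]]) else min(max_pad, max(left_gap - 1, 0))
            pad_r = max_pad if (k + 1 == len(sub) or cov_mask[orig[k + 1]]) else min(max_pad, max(right_gap - 1, 0))
            rows.append((chrom, max(starts[k] - pad_l, 0), min(ends[k] + pad_r, length)))
    marks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return gi.merge_overlapping(marks) if len(marks) else marks


def simulate_nb_counts(
    means: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion * mu^2
    (Poisson when dispersion is ~0)."""
    means = np.asarray(means, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(means)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + means))


def _unambiguous_nearest(
    regions: pd.DataFrame, genes: pd.DataFrame, margin: int = 2_000
) -> np.ndarray:
    """Positional indices of regions whose nearest-TSS assignment has at
    least ``margin`` bases of slack over the second-nearest TSS."""
    out = []
    for i, (_, r) in enumerate(regions.iterrows()):
        g = genes[genes["chrom"] == r["chrom"]]
        if len(g) == 0:
            continue
        mid = (int(r["start"]) + int(r["end"])) // 2
        d = np.sort(np.abs(g["tss"].to_numpy() - mid))
        if len(d) == 1 or d[1] - d[0] >= margin:
            out.append(i)
    return np.array(out, dtype=int)


def generate_rna_counts(
    design: SyntheticDesign,
    genes: pd.DataFrame,
    dar_truth: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample RNA count matrix plus the planted concordant pairs.

    A ``frac_concordant_genes`` fraction of planted differential
    regions passes a same-direction log2 shift of ``rna_log2fc`` to its
    nearest gene in the injured group.  Returns (counts, concordant)
    where ``concordant`` has region_id, gene_id, direction.
    """
    rng = _rng(design, _S_RNA)
    samples = list(design.sample_groups)
    base = rng.lognormal(math.log(design.rna_base_mean), 1.0, size=len(genes))
    concordant = pd.DataFrame(columns=["region_id", "gene_id", "direction"])
    shift = np.zeros(len(genes))
    if len(dar_truth) and len(genes) and design.frac_concordant_genes > 0:
        n_pick = round(design.frac_concordant_genes * len(dar_truth))
        # plant only where the nearest gene is unambiguous (second-
        # nearest TSS at least 2 kb further), so the region/gene pairing
        # survives the peak caller's bin-level boundary jitter
        eligible = _unambiguous_nearest(dar_truth, genes, margin=2_000)
        if len(eligible) < n_pick:
            n_pick = len(eligible)
        pick = np.sort(rng.choice(eligible, size=n_pick, replace=False))
        nearest = gi.nearest_tss(dar_truth.iloc[pick], genes)
        gene_dir: dict[str, int] = {}
        rows = []
        for _, r in nearest.iterrows():
            g = r["nearest_gene"]
            d = int(r["direction"])
            if g is None or gene_dir.get(g, d) != d:
                continue  # unassignable or conflicting directions
            if g not in gene_dir:
                gene_dir[g] = d
            rows.append((r["region_id"], g, d))
        concordant = pd.DataFrame(rows, columns=["region_id", "gene_id", "direction"])
        gene_pos = {g: i for i, g in enumerate(genes["gene_id"])}
        for g, d in gene_dir.items():
            shift[gene_pos[g]] = d * design.rna_log2fc
    counts = np.zeros((len(genes), len(samples)), dtype=int)
    for j, s in enumerate(samples):
        mu = base * (2.0 ** shift if design.sample_groups[s] == "cci" else 1.0)
        counts[:, j] = simulate_nb_counts(mu, design.rna_dispersion, rng)
    out = pd.DataFrame(counts, columns=samples)
    out.insert(0, "gene_id", genes["gene_id"].to_numpy())
    return out, concordant


def generate_tf_array(
    design: SyntheticDesign, include_t7_control: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dye-swap pair of protein-microarray grids.

    Every protein occupies 2 spots per array x 2 arrays = 4 spots;
    foreground and background medians are lognormal, and planted binder
    proteins have their foreground multiplied on all 4 spots.  A
    labeled-T7 control probe can be included (never callable
    downstream).  Returns (spots, binder_truth).
    """
    rng = _rng(design, _S_ARRAY)
    n = design.array_n_proteins
    proteins = [f"p{i+1:04d}" for i in range(n)]
    n_bind = min(design.array_n_binders, n)
    binder_idx = np.sort(rng.choice(n, size=n_bind, replace=False)) if n_bind else np.array([], dtype=int)
    mult = np.ones(n)
    mult[binder_idx] = design.array_binder_multiplier
    truth = pd.DataFrame(
        {
            "protein_id": [proteins[i] for i in binder_idx],
            "multiplier": mult[binder_idx],
        }
    )
    ids = list(proteins)
    if include_t7_control:
        ids.append("T7_control")
    ncol = design.array_n_cols
    half_rows = math.ceil(len(ids) / ncol)
    rows = []
    for array_i, dye in enumerate(["Cy3", "Cy5"]):
        array_id = f"array_{dye}"
        for rep in (1, 2):
            for k, pid in enumerate(ids):
                r = k // ncol + (rep - 1) * half_rows
                c = k % ncol
                b = rng.lognormal(math.log(500.0), 0.3)
                signal = rng.lognormal(math.log(1.2), 0.25)
                m = mult[k] if k < n else 1.0
                rows.append((array_id, r, c, pid, rep, dye, b * signal * m, b))
    spots = pd.DataFrame(
        rows, columns=["array_id", "row", "col", "protein_id", "replicate", "dye", "F", "B"]
    )
    return spots, truth


def generate_all(design: SyntheticDesign, sequence: bool = False) -> dict:
    """Run every generator and return the full in-memory bundle."""
    chrom_sizes, genes, exons = generate_genome_and_genes(design)
    regions, dar_truth = place_accessible_regions(design)
    marks = generate_h3k4me1_regions(design, regions)
    fragments = {
        s: generate_atac_fragments(design, regions, s, i)
        for i, s in enumerate(design.sample_groups)
    }
    rna, concordant = generate_rna_counts(design, genes, dar_truth)
    spots, binders = generate_tf_array(design)
    truth = PlantedTruth(
        dar_regions=dar_truth, concordant_genes=concordant, array_binders=binders
    )
    bundle = {
        "design": design,
        "chrom_sizes": chrom_sizes,
        "genes": genes,
        "exons": exons,
        "regions": regions,
        "marks": marks,
        "fragments": fragments,
        "rna_counts": rna,
        "array_spots": spots,
        "truth": truth,
    }
    if sequence:
        bundle["sequence"] = generate_genome_sequence(design)
    return bundle


def write_all(design: SyntheticDesign, outdir, sequence: bool = False) -> dict:
    """Generate and serialize every input to ``outdir`` (BED/TSV/FASTA);
    returns the in-memory bundle as well."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_all(design, sequence=sequence)
    bundle["chrom_sizes"].to_csv(outdir / "chrom_sizes.tsv", sep="\t", index=False)
    gi.write_gene_models(bundle["genes"], outdir / "genes.tsv")
    bundle["exons"].to_csv(outdir / "exons.tsv", sep="\t", index=False)
    bundle["regions"].to_csv(outdir / "accessible_regions.tsv", sep="\t", index=False)
    gi.write_bed(bundle["marks"], outdir / "h3k4me1.bed")
    frag_dir = outdir / "fragments"
    frag_dir.mkdir(exist_ok=True)
    for sample, frags in bundle["fragments"].items():
        gi.write_bed(frags, frag_dir / f"{sample}.bed")
    bundle["rna_counts"].to_csv(outdir / "rna_counts.tsv", sep="\t", index=False)
    bundle["array_spots"].to_csv(outdir / "tf_array.tsv", sep="\t", index=False)
    bundle["truth"].to_tsv(outdir / "truth.tsv")
    if sequence:
        gi.write_fasta(bundle["sequence"], outdir / "genome.fa")
    with open(outdir / "design.yaml", "w") as fh:
        import yaml

        yaml.safe_dump(dataclasses.asdict(design), fh, sort_keys=False)
    return bundle
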