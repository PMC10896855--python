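"""Generators: determinism, planted structure, conservation."""

import numpy as np
import pandas as pd
import pytest

from atacre import atac
from atacre.synthetic import (
    PlantedTruth,
    SyntheticDesign,
    generate_all,
    generate_atac_fragments,
    generate_genome_and_genes,
    generate_genome_sequence,
    generate_h3k4me1_regions,
    generate_rna_counts,
    generate_tf_array,
    place_accessible_regions,
    write_all,
)

import _oracles as orc


class TestDesignValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"frac_dar": 1.5},
            {"h3k4me1_cover_frac": -0.1},
            {"depth": 0},
            {"dar_effect": 0.0},
            {"n_chromosomes": 0},
        ],
    )
    def test_rejects_bad_fields(self, kw):
        with pytest.raises(ValueError):
            SyntheticDesign(**kw)


class TestGenomeAndGenes:
    def test_deterministic(self):
        d = SyntheticDesign(seed=1)
        a = generate_genome_and_genes(d)
        b = generate_genome_and_genes(d)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_no_genes(self):
        sizes, genes, exons = generate_genome_and_genes(SyntheticDesign(n_genes=0))
        assert len(genes) == 0 and len(sizes) == 2

    def test_200_genes_within_bounds_non_overlapping(self):
        d = SyntheticDesign()
        _, genes, exons = generate_genome_and_genes(d)
        assert len(genes) == 200
        for _, g in genes.iterrows():
            assert 0 <= g["start"] < g["end"] <= d.genome_length
        for (chrom, strand), sub in genes.groupby(["chrom", "strand"]):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()
        # every gene has at least one exon inside its body
        per_gene = exons.groupby("gene_id").size()
        assert (per_gene >= 1).all() and set(per_gene.index) == set(genes["gene_id"])

    def test_genome_too_small(self):
        with pytest.raises(ValueError):
            generate_genome_and_genes(
                SyntheticDesign(genome_length=50_000, n_genes=200)
            )

    def test_sequence_deterministic_and_composition(self):
        d = SyntheticDesign(genome_length=50_000, n_genes=4)
        s1 = generate_genome_sequence(d)
        s2 = generate_genome_sequence(d)
        assert s1 == s2
        assert set(s1["chr1"]) <= set("ACGT")
        assert len(s1["chr1"]) == 50_000


class TestFragments:
    def _region_counts(self, design, regions, sample, stream):
        frags = generate_atac_fragments(design, regions, sample, stream)
        events, _ = atac.fragments_to_insertions(frags, design.chrom_sizes)
        counts = np.zeros(len(regions))
        for i, (_, r) in enumerate(regions.iterrows()):
            sel = (
                (events["chrom"] == r["chrom"])
                & (events["pos"] >= r["start"])
                & (events["pos"] < r["end"])
            )
            counts[i] = sel.sum()
        return frags, counts

    def test_fragment_total_equals_depth(self):
        d = SyntheticDesign(depth=5_000, n_accessible_regions=50, genome_length=500_000)
        regions, _ = place_accessible_regions(d)
        frags = generate_atac_fragments(d, regions, "naive_1", 0)
        assert len(frags) == d.depth

    def test_seed_reproducible(self):
        d = SyntheticDesign(depth=5_000, n_accessible_regions=50, genome_length=500_000)
        regions, _ = place_accessible_regions(d)
        a = generate_atac_fragments(d, regions, "cci_1", 3)
        b = generate_atac_fragments(d, regions, "cci_1", 3)
        pd.testing.assert_frame_equal(a, b)

    def test_no_effect_means_equal_rates(self):
        d = SyntheticDesign(dar_effect=1.0, frac_dar=0.2, depth=200_000)
        regions, _ = place_accessible_regions(d)
        _, naive = self._region_counts(d, regions, "naive_1", 0)
        _, cci = self._region_counts(d, regions, "cci_1", 3)
        dar = regions["is_dar"].to_numpy()
        ratio = cci[dar].sum() / naive[dar].sum()
        assert abs(ratio - 1.0) < 0.05

    def test_effect_ratio_within_ten_percent(self):
        # >= 50 planted regions averaged, effect 2x
        d = SyntheticDesign(dar_effect=2.0, frac_dar=0.2, depth=200_000)
        regions, _ = place_accessible_regions(d)
        up = (regions["dar_direction"] == 1).to_numpy()
        assert up.sum() >= 25
        _, naive = self._region_counts(d, regions, "naive_1", 0)
        _, cci = self._region_counts(d, regions, "cci_1", 3)
        ratio = cci[up].sum() / naive[up].sum()
        assert abs(ratio - 2.0) < 0.2


class TestH3K4me1:
    def _overlap_count(self, regions, marks):
        return sum(
            bool(
                len(
                    orc.quadratic_overlap_pairs(
                        regions.iloc[[i]][["chrom", "start", "end"]], marks
                    )
                )
            )
            for i in range(len(regions))
        )

    @pytest.mark.parametrize("frac,expected", [(1.0, 100), (0.0, 0), (0.5, 50)])
    def test_exact_coverage_counts(self, frac, expected):
        d = SyntheticDesign(
            n_accessible_regions=100, h3k4me1_cover_frac=frac, genome_length=1_000_000
        )
        regions, _ = place_accessible_regions(d)
        marks = generate_h3k4me1_regions(d, regions)
        assert self._overlap_count(regions, marks) == expected

    def test_marks_wider_than_regions(self):
        d = SyntheticDesign(n_accessible_regions=50, genome_length=1_000_000)
        regions, _ = place_accessible_regions(d)
        marks = generate_h3k4me1_regions(d, regions)
        assert (marks["end"] - marks["start"]).mean() > (
            regions["end"] - regions["start"]
        ).mean()


class TestRnaCounts:
    def test_no_concordance_no_shift(self):
        d = SyntheticDesign(frac_concordant_genes=0.0)
        _, genes, _ = generate_genome_and_genes(d)
        _, dar = place_accessible_regions(d)
        counts, concordant = generate_rna_counts(d, genes, dar)
        assert len(concordant) == 0

    def test_matrix_dimensions(self):
        d = SyntheticDesign()
        _, genes, _ = generate_genome_and_genes(d)
        _, dar = place_accessible_regions(d)
        counts, _ = generate_rna_counts(d, genes, dar)
        assert counts.shape == (d.n_genes, 2 * d.n_samples_per_group + 1)
        mat = counts.drop(columns="gene_id").to_numpy()
        assert (mat >= 0).all() and np.issubdtype(mat.dtype, np.integer)

    def test_planted_shift_recovered(self):
        # +1 log2 shift at ~500 mean, dispersion 0.05: sample log2 ratio
        # averaged over >= 30 planted genes lands within +-0.3 of 1
        d = SyntheticDesign(
            frac_dar=0.3, frac_concordant_genes=0.9, rna_log2fc=1.0, rna_base_mean=500.0
        )
        _, genes, _ = generate_genome_and_genes(d)
        _, dar = place_accessible_regions(d)
        counts, concordant = generate_rna_counts(d, genes, dar)
        assert len(concordant) >= 30
        groups = d.sample_groups
        cci = [s for s, g in groups.items() if g == "cci"]
        naive = [s for s, g in groups.items() if g == "naive"]
        sub = counts.set_index("gene_id").loc[concordant["gene_id"].unique()]
        ratios = np.log2(sub[cci].mean(axis=1) / sub[naive].mean(axis=1))
        signed = ratios * concordant.drop_duplicates("gene_id").set_index("gene_id")["direction"]
        assert abs(signed.mean() - 1.0) < 0.3


class TestTfArray:
    def test_spot_counts(self):
        d = SyntheticDesign(array_n_proteins=100)
        spots, _ = generate_tf_array(d, include_t7_control=False)
        assert len(spots) == 2 * 2 * 100
        per_array = spots.groupby("array_id").size()
        assert (per_array == 200).all()
        assert (spots.groupby("protein_id").size() == 4).all()

    def test_binder_multiplier_applied_on_all_four_spots(self):
        d = SyntheticDesign(array_n_proteins=50, array_binder_multiplier=10.0)
        spots, truth = generate_tf_array(d)
        binder = truth["protein_id"].iloc[0]
        ratio = spots.loc[spots["protein_id"] == binder, "F"] / spots.loc[
            spots["protein_id"] == binder, "B"
        ]
        others = spots[~spots["protein_id"].isin([binder, "T7_control"])]
        assert (ratio > 3).all()
        assert ratio.min() > (others["F"] / others["B"]).median() * 4


class TestBundleAndSerialization:
    def test_generate_all_deterministic(self):
        d = SyntheticDesign(
            genome_length=400_000, n_genes=30, n_accessible_regions=40, depth=20_000
        )
        a = generate_all(d)
        b = generate_all(d)
        pd.testing.assert_frame_equal(a["regions"], b["regions"])
        pd.testing.assert_frame_equal(
            a["fragments"]["cci_2"], b["fragments"]["cci_2"]
        )
        pd.testing.assert_frame_equal(a["rna_counts"], b["rna_counts"])
        pd.testing.assert_frame_equal(a["array_spots"], b["array_spots"])

    def test_write_all_byte_identical_and_truth_round_trip(self, tmp_path):
        d = SyntheticDesign(
            genome_length=400_000, n_genes=30, n_accessible_regions=40, depth=10_000
        )
        b1 = write_all(d, tmp_path / "a")
        write_all(d, tmp_path / "b")
        for rel in ("h3k4me1.bed", "rna_counts.tsv", "truth.tsv", "fragments/naive_1.bed"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()
        back = PlantedTruth.from_tsv(tmp_path / "a" / "truth.tsv")
        truth = b1["truth"]
        pd.testing.assert_frame_equal(
            back.dar_regions.astype({"start": int, "end": int}),
            truth.dar_regions[["region_id", "chrom", "start", "end", "direction"]].astype(
                {"start": int, "end": int, "direction": int}
            ),
            check_dtype=False,
        )
        assert list(back.concordant_genes["gene_id"]) == list(
            truth.concordant_genes["gene_id"]
        )
        assert list(back.array_binders["protein_id"]) == list(
            truth.array_binders["protein_id"]
        )
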