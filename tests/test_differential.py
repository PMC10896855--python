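"""Consensus regions, counting, normalization and the NB group test."""

import numpy as np
import pandas as pd
import pytest

from atacre import differential as diff
from atacre.synthetic import SyntheticDesign, generate_h3k4me1_regions, place_accessible_regions, simulate_nb_counts

import _oracles as orc


def _df(triples):
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])


def _peak(start, end):
    return _df([("chr1", start, end)])


class TestReproducibleConsensus:
    def _sets(self):
        # one locus around 100-200 seen in naive 1+2 and both cci
        # samples; a second locus only in naive_1
        return {
            "naive_1": _df([("chr1", 100, 200), ("chr1", 5000, 5100)]),
            "naive_2": _peak(120, 210),
            "naive_3": _peak(9000, 9100),
            "cci_1": _peak(90, 190),
            "cci_2": _peak(150, 260),
        }

    def _groups(self):
        return {
            "naive_1": "naive",
            "naive_2": "naive",
            "naive_3": "naive",
            "cci_1": "cci",
            "cci_2": "cci",
        }

    def test_two_of_each_group_kept(self):
        out = diff.reproducible_consensus(self._sets(), self._groups())
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (90, 260)
        assert out.iloc[0]["support_naive"] == 2 and out.iloc[0]["support_cci"] == 2

    def test_single_sample_locus_dropped(self):
        out = diff.reproducible_consensus(self._sets(), self._groups())
        assert not ((out["start"] <= 5000) & (out["end"] >= 5100)).any()

    def test_any_group_mode_keeps_one_group_support(self):
        sets = self._sets()
        sets["naive_3"] = _peak(5010, 5110)  # second naive sample at locus 2
        out = diff.reproducible_consensus(sets, self._groups(), mode="any_group")
        assert len(out) == 2

    def test_too_few_samples_is_config_error(self):
        with pytest.raises(ValueError):
            diff.reproducible_consensus(
                {"naive_1": _peak(0, 10), "cci_1": _peak(0, 10), "cci_2": _peak(0, 10)},
                {"naive_1": "naive", "cci_1": "cci", "cci_2": "cci"},
            )

    def test_matches_brute_force_support(self, rng):
        samples = [f"s{i}" for i in range(6)]
        groups = {s: ("naive" if i < 3 else "cci") for i, s in enumerate(samples)}
        sets = {s: orc.random_regions(rng, 40, 20_000) for s in samples}
        out = diff.reproducible_consensus(sets, groups)
        from atacre.intervals import merge_overlapping

        loci = merge_overlapping(pd.concat(sets.values()))
        for _, locus in loci.iterrows():
            sup = {"naive": 0, "cci": 0}
            for s in samples:
                hit = any(
                    r["chrom"] == locus["chrom"]
                    and min(r["end"], locus["end"]) > max(r["start"], locus["start"])
                    for _, r in sets[s].iterrows()
                )
                sup[groups[s]] += hit
            kept = (
                (out["chrom"] == locus["chrom"])
                & (out["start"] == locus["start"])
                & (out["end"] == locus["end"])
            ).any()
            assert kept == (sup["naive"] >= 2 and sup["cci"] >= 2)


class TestSubsetByMark:
    def test_inside_kept_and_nearby_dropped(self):
        cons = _df([("chr1", 100, 200), ("chr1", 300, 400)])
        marks = _df([("chr1", 50, 250), ("chr1", 401, 500)])
        out = diff.subset_by_mark(cons, marks)
        assert len(out) == 1 and out.iloc[0]["start"] == 100
        assert out.iloc[0]["mark_overlap_frac"] == 1.0

    def test_empty_marks_warns_empty_result(self):
        with pytest.warns(UserWarning):
            out = diff.subset_by_mark(_df([("chr1", 0, 10)]), _df([]))
        assert len(out) == 0

    def test_synthetic_cover_fraction_exact(self):
        d = SyntheticDesign(n_accessible_regions=100, h3k4me1_cover_frac=0.5)
        regions, _ = place_accessible_regions(d)
        marks = generate_h3k4me1_regions(d, regions)
        kept = diff.subset_by_mark(regions[["chrom", "start", "end"]], marks)
        assert len(kept) == 50


class TestCountMatrix:
    def test_half_open_boundaries(self):
        cons = _df([("chr1", 100, 200)])
        events = {
            "s1": pd.DataFrame({"chrom": "chr1", "pos": [99, 100, 199, 200]})
        }
        m = diff.count_matrix(cons, events, {"s1": "naive"})
        assert m.counts[0, 0] == 2

    def test_column_sums_bounded_by_totals(self, rng):
        cons = diff.subset_by_mark  # noqa: F841  (no-op reference)
        regions = orc.random_regions(rng, 30, 50_000)
        events = {
            "a": pd.DataFrame(
                {"chrom": "chr1", "pos": rng.integers(0, 50_000, 2000)}
            ),
            "b": pd.DataFrame(
                {"chrom": "chr1", "pos": rng.integers(0, 50_000, 1000)}
            ),
        }
        from atacre.intervals import merge_overlapping

        merged = merge_overlapping(regions)
        m = diff.count_matrix(merged, events, {"a": "naive", "b": "cci"})
        assert m.counts[:, 0].sum() <= 2000 and m.counts[:, 1].sum() <= 1000

    def test_matches_per_event_scan(self, rng):
        regions = orc.random_regions(rng, 25, 20_000)
        pos = rng.integers(0, 20_000, 3000)
        events = {"s": pd.DataFrame({"chrom": "chr1", "pos": pos})}
        m = diff.count_matrix(regions, events, {"s": "naive"})
        for i, (_, r) in enumerate(regions.iterrows()):
            assert m.counts[i, 0] == int(((pos >= r["start"]) & (pos < r["end"])).sum())


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = np.tile(np.arange(1, 51)[:, None], (1, 4))
        assert np.allclose(diff.estimate_size_factors(counts), 1.0)

    def test_doubled_sample_factor_doubles(self, rng):
        base = rng.integers(10, 200, size=(50, 1))
        counts = np.hstack([base, base, base * 2])
        sf = diff.estimate_size_factors(counts)
        assert np.isclose(sf[2] / sf[0], 2.0)
        assert np.isclose(np.exp(np.mean(np.log(sf))), 1.0)

    def test_fallback_on_sparse_matrix(self):
        counts = np.array([[0, 5], [3, 0]])
        with pytest.warns(UserWarning):
            sf = diff.estimate_size_factors(counts)
        assert np.all(sf > 0)


def _matrix(counts, n_naive, n_cci):
    samples = [f"n{i}" for i in range(n_naive)] + [f"c{i}" for i in range(n_cci)]
    groups = {s: ("naive" if s.startswith("n") else "cci") for s in samples}
    regions = _df([("chr1", 100 * i, 100 * i + 50) for i in range(len(counts))])
    return diff.RegionCountMatrix(regions, samples, groups, np.asarray(counts))


class TestNbGroupTest:
    def test_identical_group_means_zero_lfc(self):
        m = _matrix([[10, 10, 10, 10, 10, 10]] * 5, 3, 3)
        res = diff.nb_group_test(m)
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["direction"] == "ns").all()

    def test_all_zero_region(self):
        m = _matrix([[0, 0, 0, 0], [5, 6, 7, 8]], 2, 2)
        res = diff.nb_group_test(m)
        assert res.loc[0, "p_value"] == 1.0 and res.loc[0, "log2fc"] == 0.0

    def test_label_symmetry(self, rng):
        counts = rng.poisson(50, size=(200, 6))
        m = _matrix(counts, 3, 3)
        a = diff.nb_group_test(m, test_group="cci", ref_group="naive")
        b = diff.nb_group_test(m, test_group="naive", ref_group="cci")
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_requires_two_samples_per_group(self):
        m = _matrix([[1, 2, 3]], 1, 2)
        with pytest.raises(ValueError):
            diff.nb_group_test(m)

    def test_null_calibration(self):
        # NB null, 2000 regions, 3 vs 3: raw rejections near nominal
        rng = np.random.default_rng(2024)
        counts = simulate_nb_counts(np.full((2000, 6), 100.0), 0.1, rng)
        m = _matrix(counts, 3, 3)
        res = diff.nb_group_test(m)
        rate = (res["p_value"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_power_on_planted_threefold(self):
        rng = np.random.default_rng(7)
        null = simulate_nb_counts(np.full((1500, 6), 100.0), 0.1, rng)
        mu = np.full((500, 6), 100.0)
        mu[:, 3:] *= 3.0
        planted = simulate_nb_counts(mu, 0.1, rng)
        m = _matrix(np.vstack([null, planted]), 3, 3)
        res = diff.nb_group_test(m)
        power = (res["p_value"].to_numpy()[1500:] < 0.05).mean()
        assert power >= 0.8


class TestBhAdjust:
    def test_closed_form_triplet(self):
        assert np.allclose(diff.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert diff.bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_matches_stepup_oracle(self, rng):
        p = rng.random(1000)
        assert np.allclose(diff.bh_adjust(p), orc.stepup_bh(p))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            diff.bh_adjust([0.5, 1.5])


class TestSampleQc:
    def test_duplicated_sample_zero_distance(self, rng):
        counts = rng.poisson(40, size=(100, 3))
        counts = np.hstack([counts, counts[:, [0]]])
        m = _matrix(counts, 2, 2)
        qc = diff.sample_qc(m)
        assert qc["correlation"].iloc[0, 3] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, default_run):
        qc = diff.sample_qc(default_run["matrix"])
        assert qc["variance_explained"].sum() <= 1.0 + 1e-9

    def test_pc1_separates_groups_on_default_run(self, default_run):
        qc = diff.sample_qc(default_run["matrix"])
        pc1 = qc["pca"]["PC1"]
        groups = default_run["design"].sample_groups
        naive = [pc1[s] for s in pc1.index if groups[s] == "naive"]
        cci = [pc1[s] for s in pc1.index if groups[s] == "cci"]
        assert max(naive) < min(cci) or min(naive) > max(cci)

    def test_constant_matrix_degenerate(self):
        m = _matrix(np.full((50, 4), 7), 2, 2)
        with pytest.raises(ValueError):
            diff.sample_qc(m)


class TestFilterOrderStability:
    def test_mark_subset_commutes_with_consensus(self, default_run):
        """Reproducibility filtering and H3K4me1 subsetting are both
        intersections; either order yields the same region set on the
        synthetic study."""
        peaks = default_run["peaks"]
        groups = default_run["design"].sample_groups
        marks = default_run["marks"]
        route_a = diff.subset_by_mark(
            diff.reproducible_consensus(peaks, groups), marks
        )
        subset_first = {
            s: diff.subset_by_mark(p, marks) for s, p in peaks.items()
        }
        route_b = diff.reproducible_consensus(subset_first, groups)
        a = set(map(tuple, route_a[["chrom", "start", "end"]].to_numpy()))
        b = set(map(tuple, route_b[["chrom", "start", "end"]].to_numpy()))
        assert a == b
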