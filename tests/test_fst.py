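import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alfadiv import fst, geno, synthetic


def _brute_bh(p):
    """Independent step-up implementation: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = np.inf
    for rank_from_top in range(m, 0, -1):
        j = order[rank_from_top - 1]
        prev = min(prev, m * p[j] / rank_from_top)
        q[j] = min(prev, 1.0)
    return q


class TestNeiFst:
    def test_printed_examples(self):
        assert fst.nei_fst(0.5, 0.5) == (0.5, 0.5, 0.0)
        ht, hs, f = fst.nei_fst(0.0, 1.0)
        assert (ht, hs, f) == (0.5, 0.0, 1.0)
        ht, hs, f = fst.nei_fst(0.2, 0.4)
        assert ht == pytest.approx(0.42)
        assert hs == pytest.approx(0.40)
        assert f == pytest.approx(0.02 / 0.42)
        assert f == pytest.approx((0.2 - 0.4) ** 2 / (2 * ht))

    def test_monomorphic_flagged(self):
        _, _, f = fst.nei_fst(0.0, 0.0)
        assert np.isnan(f)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_algebraic_identity_and_symmetries(self, p1, p2):
        ht, hs, f = fst.nei_fst(p1, p2)
        assert ht - hs == pytest.approx((p1 - p2) ** 2 / 2, abs=1e-12)
        if ht > 0:
            assert f >= -1e-15
            assert f == pytest.approx(fst.nei_fst(p2, p1)[2], abs=1e-12)
            ht2, _, f2 = fst.nei_fst(1 - p1, 1 - p2)
            # near-monomorphic flips lose the identity to float cancellation
            if min(ht, ht2) > 1e-6:
                assert f == pytest.approx(f2, abs=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fst.nei_fst(-0.1, 0.5)


class TestGroupFrequencies:
    def _panel(self):
        values = np.array([
            [0.2, 0.0], [0.4, 1.0],          # G1
            [0.6, 0.5], [0.8, 0.5], [1.0, 0.5],  # G2
        ])
        ids = ["m1", "m2"]
        afm = geno.AlleleFrequencyMatrix(
            values, np.zeros_like(values, bool),
            [f"a{i}" for i in range(5)], ids, geno._empty_map(ids))
        grouping = {"a0": "G1", "a1": "G1", "a2": "G2", "a3": "G2",
                    "a4": "G2"}
        return afm, grouping

    def test_unweighted_mean(self):
        afm, grouping = self._panel()
        gf = fst.group_frequencies(afm, grouping, min_group_size=2)
        assert gf.freq[gf.group_labels.index("G1"), 0] == pytest.approx(0.3)
        assert gf.freq[gf.group_labels.index("G2"), 0] == pytest.approx(0.8)

    def test_small_group_excluded(self):
        afm, grouping = self._panel()
        with pytest.raises(ValueError, match="fewer than 2"):
            fst.group_frequencies(afm, grouping, min_group_size=3)
        grouping["a0"] = "G2"
        grouping["a1"] = "G2"
        afm2, _ = self._panel()
        gf_err = pytest.raises(ValueError, fst.group_frequencies, afm2,
                               grouping, 3)
        assert gf_err is not None

    def test_matches_brute_force_groupby(self, small_panel):
        afm, group_of, _ = small_panel
        gf = fst.group_frequencies(afm, group_of)
        df = afm.to_frame()
        brute = df.groupby(pd.Series(group_of)).mean()
        np.testing.assert_allclose(
            gf.freq, brute.loc[gf.group_labels].to_numpy(), atol=1e-12)
        assert gf.excluded == {}


class TestAllPairs:
    @pytest.mark.parametrize("g", [2, 3, 4, 6, 8])
    def test_comparison_count(self, g):
        freq = np.random.default_rng(g).uniform(size=(g, 5))
        gf = fst.GroupFrequencies(
            group_labels=[f"G{i}" for i in range(g)], freq=freq,
            group_sizes={f"G{i}": 5 for i in range(g)},
            marker_ids=[f"m{j}" for j in range(5)],
        )
        assert len(fst.fst_all_pairs(gf)) == g * (g - 1) // 2


class TestEmpiricalNull:
    def test_full_set_null(self):
        vals = np.array([0.1, 0.2, 0.3, np.nan])
        null = fst.build_empirical_null(vals, np.arange(4))
        np.testing.assert_array_equal(np.sort(null), [0.1, 0.2, 0.3])

    def test_explicit_selection(self):
        vals = np.linspace(0, 1, 10)
        null = fst.build_empirical_null(vals, np.array([2, 5]))
        np.testing.assert_array_equal(null, vals[[2, 5]])

    def test_single_shared_sample(self):
        idx1 = fst.sample_neutral_markers(1000, 100, seed=5)
        idx2 = fst.sample_neutral_markers(1000, 100, seed=5)
        np.testing.assert_array_equal(idx1, idx2)
        assert len(np.unique(idx1)) == 100

    def test_null_mean_matches_truth_neutral(self):
        truth = synthetic.simulate_group_frequencies(
            2, 2000, 0.05, outlier_fraction=0.02, fst_outlier=0.6, seed=0)
        _, _, f = fst.nei_fst(truth.group_freq[0], truth.group_freq[1])
        null = fst.build_empirical_null(f, truth.neutral_index())
        assert null.mean() == pytest.approx(
            np.nanmean(f[truth.neutral_index()]), abs=1e-12)


class TestPvaluesAndFdr:
    def test_counting_formula(self):
        null = np.array([0.1, 0.2, 0.3])
        assert fst.empirical_pvalues(np.array([0.25]), null)[0] == 0.5
        assert fst.empirical_pvalues(np.array([0.05]), null)[0] == 1.0
        assert fst.empirical_pvalues(np.array([0.9]), null)[0] == 0.25

    def test_floor_with_999_nulls(self):
        null = np.linspace(0.0, 0.5, 999)
        p = fst.empirical_pvalues(np.array([0.9]), null)
        assert p[0] == pytest.approx(1 / 1000)

    def test_monotone_in_fst(self):
        null = np.random.default_rng(0).uniform(size=500)
        xs = np.sort(np.random.default_rng(1).uniform(size=50))
        ps = fst.empirical_pvalues(xs, null)
        assert (np.diff(ps) <= 1e-15).all()

    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            fst.bh_fdr(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(fst.bh_fdr(np.array([1.0, 1.0])), 1.0)
        assert fst.bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_bh_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 200))
            np.testing.assert_allclose(fst.bh_fdr(p), _brute_bh(p),
                                       atol=1e-12)

    def test_nan_propagation(self):
        q = fst.bh_fdr(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and np.isfinite(q[0])

    def test_neutral_pvalues_approximately_uniform(self):
        """Markers exchangeable with the null get ~Uniform(0,1] empirical
        p-values (Kolmogorov-Smirnov)."""
        from scipy.stats import kstest

        truth = synthetic.simulate_group_frequencies(2, 4000, 0.05, seed=3)
        _, _, f = fst.nei_fst(truth.group_freq[0], truth.group_freq[1])
        null_idx = np.arange(0, 4000, 2)       # half the markers as null
        null = fst.build_empirical_null(f, null_idx)
        p = fst.empirical_pvalues(f[1::2], null)   # the other half
        stat = kstest(p[np.isfinite(p)], "uniform").statistic
        assert stat < 0.05

    def test_outlier_boundary(self):
        flags = fst.call_outliers(np.array([0.049, 0.05, np.nan, 1.0]), 0.05)
        np.testing.assert_array_equal(flags, [True, False, False, False])


class TestAnnotation:
    GFF = """\
##gff-version 3
chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=gene1
chr1\tsrc\tgene\t5000\t6000\t.\t-\t.\tID=gene2
chr2\tsrc\tgene\t100\t400\t.\t+\t.\tID=gene3
"""

    @pytest.fixture
    def genes(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(self.GFF)
        return fst.read_gene_models(p)

    def test_gff_parsing(self, genes):
        assert list(genes["gene_id"]) == ["gene1", "gene2", "gene3"]
        assert genes.loc[0, "start"] == 1000 and genes.loc[0, "end"] == 2000

    def test_inside_and_window_boundaries(self, genes):
        snps = pd.DataFrame({
            "marker": ["s_mid", "s_500", "s_499", "s_down"],
            "chrom": ["chr1"] * 4,
            "pos": [1500, 500, 499, 2400],
        })
        hits = fst.annotate_outliers(snps, genes, window=500)
        by = hits.set_index("marker")
        assert by.loc["s_mid", "relation"] == "inside"
        assert by.loc["s_mid", "distance"] == 0
        assert by.loc["s_500", "relation"] == "upstream_within_window"
        assert by.loc["s_500", "distance"] == 500
        assert "s_499" not in by.index
        assert by.loc["s_down", "relation"] == "downstream_within_window"
        assert by.loc["s_down", "distance"] == 400

    def test_matches_brute_force_interval_scan(self, genes):
        rng = np.random.default_rng(0)
        snps = pd.DataFrame({
            "marker": [f"s{i}" for i in range(40)],
            "chrom": rng.choice(["chr1", "chr2", "chr3"], size=40),
            "pos": rng.integers(1, 8000, size=40),
        })
        with pytest.warns(UserWarning, match="absent"):
            hits = fst.annotate_outliers(snps, genes, window=500)
        got = {(h.marker, h.gene_id) for h in hits.itertuples()}
        expect = set()
        for s in snps.itertuples():
            for g in genes.itertuples():
                if (str(s.chrom) == g.chrom
                        and g.start - 500 <= s.pos <= g.end + 500):
                    expect.add((s.marker, g.gene_id))
        assert got == expect

    def test_bed_conversion(self, tmp_path):
        tab = pd.DataFrame({"marker": ["s1"], "chrom": ["chr1"],
                            "pos": [1500]})
        out = tmp_path / "o.bed"
        fst.write_outlier_bed(tab, out)
        assert out.read_text() == "chr1\t1499\t1500\ts1\n"


class TestScan:
    def test_six_groups_fifteen_tables_and_determinism(self):
        truth = synthetic.simulate_group_frequencies(6, 150, 0.1, seed=1)
        afm, group_of = synthetic.simulate_panel(
            {g: 4 for g in truth.group_labels}, truth, seed=2)
        out1 = fst.scan(afm, group_of, neutral=100, seed=9)
        out2 = fst.scan(afm, group_of, neutral=100, seed=9)
        assert len(out1["pairs"]) == 15
        for a, b in zip(out1["pairs"], out2["pairs"]):
            pd.testing.assert_frame_equal(a.table, b.table)

    def test_detected_outliers_are_true_outliers(self):
        """With strongly divergent loci, any empirical-null detection is a
        true outlier locus (false-discovery proportion bound)."""
        fdp = []
        detected = 0
        for s in range(10):
            truth = synthetic.simulate_group_frequencies(
                2, 2050, 0.05, outlier_fraction=50 / 2050, fst_outlier=0.5,
                seed=s)
            afm, group_of = synthetic.simulate_panel(
                {"G1": 30, "G2": 30}, truth, pool_chromosomes=400,
                seed=100 + s)
            out = fst.scan(afm, group_of,
                           neutral=truth.neutral_index(), seed=s)
            tab = out["pairs"][0].table
            flags = tab["outlier"].to_numpy()
            is_true = np.zeros(2050, bool)
            is_true[truth.outlier_index] = True
            n_called = flags.sum()
            detected += n_called
            if n_called:
                fdp.append((flags & ~is_true).sum() / n_called)
        assert np.mean(fdp) <= 0.10 if fdp else True
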