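"""Effect sizes, group contrasts, pair selection and age asymmetry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exprvar import dupstats as ds
from exprvar.io import ParalogTable


def brute_force_delta(x, y):
    """O(n·m) double-loop oracle for Cliff's delta."""
    gt = sum(1 for a in x for b in y if a > b)
    lt = sum(1 for a in x for b in y if a < b)
    return (gt - lt) / (len(x) * len(y))


def make_pairs(rows):
    return ParalogTable(pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "mode"]))


class TestCliffsDelta:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n, m = rng.integers(2, 40, size=2)
            x = rng.integers(0, 15, size=n).astype(float)  # many ties
            y = rng.integers(0, 15, size=m).astype(float)
            assert ds.cliffs_delta(x, y) == pytest.approx(
                brute_force_delta(x, y), abs=1e-12)

    def test_complete_separation(self):
        assert ds.cliffs_delta([10, 11, 12], [1, 2, 3]) == 1.0
        assert ds.cliffs_delta([1, 2, 3], [10, 11, 12]) == -1.0

    def test_identical_samples_zero(self):
        x = np.arange(20.0)
        d, lo, hi = ds.cliffs_delta_ci(x, x.copy())
        assert d == 0.0
        assert lo <= 0.0 <= hi

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30),
           st.lists(st.floats(-100, 100), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_and_bounds(self, x, y):
        d = ds.cliffs_delta(x, y)
        assert -1.0 <= d <= 1.0
        assert d == pytest.approx(-ds.cliffs_delta(y, x), abs=1e-12)

    def test_ci_contains_delta(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.normal(0.3, 1, size=rng.integers(5, 50))
            y = rng.normal(0, 1, size=rng.integers(5, 50))
            d, lo, hi = ds.cliffs_delta_ci(x, y)
            assert lo - 1e-12 <= d <= hi + 1e-12

    def test_degenerate_separation_point_ci(self):
        d, lo, hi = ds.cliffs_delta_ci([10.0, 11.0], [1.0, 2.0])
        assert (d, lo, hi) == (1.0, 1.0, 1.0)


class TestCompareGroups:
    def test_identical_groups(self):
        scores = pd.Series(np.arange(40.0))
        groups = pd.Series(["a"] * 20 + ["b"] * 20)
        groups[:] = np.where(scores % 2 == 0, "a", "b")
        scores[groups == "b"] = scores[groups == "a"].to_numpy()
        res = ds.compare_groups(scores, groups, [("a", "b")])[0]
        assert res.delta == 0.0
        assert res.p > 0.9

    def test_empty_group_named(self):
        scores = pd.Series([1.0, 2.0], index=["g1", "g2"])
        groups = pd.Series(["a", "a"], index=["g1", "g2"])
        with pytest.raises(ValueError, match="'b'"):
            ds.compare_groups(scores, groups, [("a", "b")])

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(np.concatenate([
            rng.normal(0, 1, 50), rng.normal(1.2, 1, 50),
            rng.normal(0.1, 1, 50)]))
        groups = pd.Series(["a"] * 50 + ["b"] * 50 + ["c"] * 50)
        res = ds.compare_groups(scores, groups,
                                [("a", "b"), ("a", "c"), ("b", "c")])
        for r in res:
            assert r.p_adjusted >= r.p - 1e-15
        order = np.argsort([r.p for r in res])
        adj = np.array([r.p_adjusted for r in res])[order]
        assert (np.diff(adj) >= -1e-15).all()

    def test_planted_shift_ci_coverage(self):
        """CI covers the true delta in ≥ 90% of replicates.

        A normal shift of √2·Φ⁻¹((1+δ)/2) gives true Cliff's delta δ.
        """
        from scipy.stats import norm
        true_delta = 0.3
        shift = np.sqrt(2) * norm.ppf((1 + true_delta) / 2)
        rng = np.random.default_rng(7)
        covered = 0
        for _ in range(100):
            x = rng.normal(shift, 1, size=1000)
            y = rng.normal(0, 1, size=1000)
            _, lo, hi = ds.cliffs_delta_ci(x, y)
            covered += lo <= true_delta <= hi
        assert covered >= 90


class TestPairMinMax:
    def test_ordering_and_conservation(self):
        scores = pd.Series({"a": 1.0, "b": -0.5, "c": 2.0, "d": 2.0})
        pairs = make_pairs([("a", "b", "tandem"), ("c", "d", "wgd")])
        table, low, high = ds.pair_min_max(scores, pairs)
        assert list(low) == [-0.5, 2.0]
        assert list(high) == [1.0, 2.0]  # tie: min == max
        assert len(low) == len(high) == len(pairs.pairs)

    def test_missing_member_excluded_and_counted(self):
        scores = pd.Series({"a": 1.0, "b": -0.5, "c": 2.0})
        pairs = make_pairs([("a", "b", "tandem"), ("c", "zz", "wgd")])
        table, low, high = ds.pair_min_max(scores, pairs)
        assert len(table) == 1
        assert table.attrs["n_excluded"] == 1


class TestSelectTopDivergent:
    def make_table(self, n, mode="tandem"):
        rows = [(f"a{i}", f"b{i}", mode) for i in range(n)]
        pairs = make_pairs(rows)
        scores = pd.Series({f"a{i}": float(i) for i in range(n)}
                           | {f"b{i}": 0.0 for i in range(n)})
        return ds.pair_scores(scores, pairs)

    def test_counting(self):
        table = self.make_table(100)
        top = ds.select_top_divergent(table, fraction=0.05)
        assert len(top) == 5

    def test_dedup_drops_repeated_gene(self):
        pairs = make_pairs([("g1", "g2", "tandem"), ("g1", "g3", "tandem"),
                            ("g4", "g5", "tandem")] +
                           [(f"x{i}", f"y{i}", "tandem") for i in range(37)])
        scores = pd.Series({"g1": 10.0, "g2": 0.0, "g3": 5.0, "g4": 3.0,
                            "g5": 0.0} | {f"x{i}": 0.1 for i in range(37)}
                           | {f"y{i}": 0.0 for i in range(37)})
        table = ds.pair_scores(scores, pairs)
        top = ds.select_top_divergent(table, fraction=0.1)  # k = 4
        ids = list(top["pair_id"])
        assert "g1|g2" in ids and "g1|g3" not in ids
        genes = list(top["gene_a"]) + list(top["gene_b"])
        assert len(genes) == len(set(genes))

    def test_all_ties_deterministic_prefix(self):
        pairs = make_pairs([(f"a{i}", f"b{i}", "tandem") for i in range(40)])
        scores = pd.Series({f"a{i}": 1.0 for i in range(40)}
                           | {f"b{i}": 0.0 for i in range(40)})
        table = ds.pair_scores(scores, pairs)
        t1 = ds.select_top_divergent(table, fraction=0.1)
        t2 = ds.select_top_divergent(table.sample(frac=1, random_state=1),
                                     fraction=0.1)
        assert list(t1["pair_id"]) == list(t2["pair_id"])
        assert list(t1["pair_id"]) == sorted(t1["pair_id"])

    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="fraction"):
            ds.select_top_divergent(self.make_table(10), fraction=0.0)

    def test_selection_within_each_class(self):
        scores = pd.Series({f"a{i}": float(i) for i in range(40)}
                           | {f"b{i}": 0.0 for i in range(40)})
        rows = [(f"a{i}", f"b{i}", "tandem") for i in range(20)] + \
               [(f"a{i}", f"b{i}", "wgd") for i in range(20, 40)]
        table = ds.pair_scores(scores, make_pairs(rows))
        top = ds.select_top_divergent(table, fraction=0.1)
        assert (top["dup_class"] == "ssd").sum() == 2
        assert (top["dup_class"] == "wgd").sum() == 2


class TestTFContingency:
    def make_meta(self, tf_genes, all_genes):
        return pd.DataFrame({
            "status": "ssd", "clade": 1,
            "is_tf": [g in tf_genes for g in all_genes],
            "go_terms": [frozenset()] * len(all_genes),
            "mean_expression": 1.0,
        }, index=all_genes)

    def test_chi2_matches_hand_oracle(self):
        # table [[10, 90], [50, 50]]: chi2 = Σ (O−E)²/E
        rows, genes = [], []
        k = 0
        counts = {("tandem", True): 10, ("tandem", False): 90,
                  ("wgd", True): 50, ("wgd", False): 50}
        tf_genes = set()
        for (mode, tf), c in counts.items():
            for _ in range(c):
                a, b = f"p{k}a", f"p{k}b"
                rows.append((a, b, mode))
                genes += [a, b]
                if tf:
                    tf_genes |= {a, b}
                k += 1
        meta = self.make_meta(tf_genes, genes)
        table, chi2, p, n_mixed = ds.tf_contingency(make_pairs(rows), meta)
        obs = np.array([[10, 50], [90, 50]], dtype=float)
        col = obs.sum(0)
        row = obs.sum(1)
        exp = np.outer(row, col) / obs.sum()
        assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum())
        assert n_mixed == 0

    def test_mixed_pairs_excluded_and_counted(self):
        rows = [("a1", "b1", "tandem"), ("a2", "b2", "wgd"),
                ("a3", "b3", "wgd"), ("a4", "b4", "tandem")]
        genes = [g for r in rows for g in r[:2]]
        meta = self.make_meta({"a1", "a2", "b2"}, genes)  # a1 mixed
        table, _, _, n_mixed = ds.tf_contingency(make_pairs(rows), meta)
        assert n_mixed == 1
        assert table.to_numpy().sum() == 3

    def test_single_class_errors(self):
        rows = [("a1", "b1", "tandem"), ("a2", "b2", "tandem")]
        genes = [g for r in rows for g in r[:2]]
        meta = self.make_meta({"a1", "b1"}, genes)
        with pytest.raises(ValueError, match="two duplication classes"):
            ds.tf_contingency(make_pairs(rows), meta)


def planted_divergence(n, derived_shift, rng, mode="transposed"):
    """Pair table with A ancestral (older clade) and B derived."""
    rows = []
    for i in range(n):
        anc_clade = rng.integers(1, 11)
        der_clade = anc_clade + rng.integers(1, 6)
        nev_a = rng.normal(0, 1)
        nev_b = rng.normal(derived_shift, 1)
        rows.append((f"a{i}", f"b{i}", mode, nev_a, nev_b,
                     float(anc_clade), float(der_clade)))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "mode", "score_a",
                                     "score_b", "clade_a", "clade_b"])
    df["dscore"] = df["score_a"] - df["score_b"]
    df["abs_dscore"] = df["dscore"].abs()
    df["dclade"] = df["clade_a"] - df["clade_b"]
    df["pair_id"] = df["gene_a"] + "|" + df["gene_b"]
    return df


class TestAgeAsymmetry:
    def test_planted_derived_elevation_detected(self):
        rng = np.random.default_rng(11)
        div = planted_divergence(300, derived_shift=0.5, rng=rng)
        res = ds.age_asymmetry(div)
        assert res["median_paired_diff"] > 0
        assert res["wilcoxon_p"] < 0.05
        assert res["spearman_rho"] > 0

    def test_null_design(self):
        rng = np.random.default_rng(12)
        div = planted_divergence(300, derived_shift=0.0, rng=rng)
        res = ds.age_asymmetry(div)
        assert abs(res["median_paired_diff"]) < 0.2
        assert res["wilcoxon_p"] > 0.05

    def test_orientation_invariance(self):
        rng = np.random.default_rng(13)
        div = planted_divergence(120, derived_shift=0.4, rng=rng)
        flipped = div.copy()
        for a, b in (("score_a", "score_b"), ("clade_a", "clade_b"),
                     ("gene_a", "gene_b")):
            flipped[[a, b]] = flipped[[b, a]].to_numpy()
        flipped["dscore"] *= -1
        flipped["dclade"] *= -1
        r1 = ds.age_asymmetry(div)
        r2 = ds.age_asymmetry(flipped)
        for key in ("median_paired_diff", "wilcoxon_p", "spearman_rho"):
            assert r1[key] == pytest.approx(r2[key], abs=1e-12)

    def test_tied_clades_excluded(self):
        rng = np.random.default_rng(14)
        div = planted_divergence(50, derived_shift=0.5, rng=rng)
        div.loc[:9, "dclade"] = 0.0
        res = ds.age_asymmetry(div)
        assert res["n_pairs"] == 40
        assert res["n_excluded_tied_or_missing"] == 10

    def test_low_power_flag(self):
        rng = np.random.default_rng(15)
        div = planted_divergence(5, derived_shift=0.5, rng=rng)
        assert ds.age_asymmetry(div)["low_power"]


class TestSyntenyValidation:
    def test_full_consistency_minimal_p(self):
        n = 100
        rows = [(f"a{i}", f"b{i}", "transposed", "A_is_parent", np.nan)
                for i in range(n)]
        pairs = ParalogTable(pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "mode", "orientation", "ks"]))
        clades = pd.Series(
            {f"a{i}": 2.0 for i in range(n)} | {f"b{i}": 8.0 for i in range(n)})
        res = ds.validate_synteny_orientation(pairs, clades)
        assert res["n_used"] == n
        assert res["p"] < 1e-10
        assert res["median_diff"] == 6.0

    def test_shuffled_orientation_null(self):
        rng = np.random.default_rng(17)
        n = 200
        orient = np.where(rng.random(n) < 0.5, "A_is_parent", "B_is_parent")
        rows = [(f"a{i}", f"b{i}", "transposed", orient[i], np.nan)
                for i in range(n)]
        pairs = ParalogTable(pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "mode", "orientation", "ks"]))
        clades = pd.Series({f"a{i}": float(rng.integers(1, 16))
                            for i in range(n)}
                           | {f"b{i}": float(rng.integers(1, 16))
                              for i in range(n)})
        res = ds.validate_synteny_orientation(pairs, clades)
        assert res["p"] > 0.01

    def test_ties_dropped_and_n_adjusted(self):
        rows = [("a0", "b0", "transposed", "A_is_parent", np.nan),
                ("a1", "b1", "transposed", "A_is_parent", np.nan)]
        pairs = ParalogTable(pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "mode", "orientation", "ks"]))
        clades = pd.Series({"a0": 3.0, "b0": 3.0, "a1": 2.0, "b1": 7.0})
        res = ds.validate_synteny_orientation(pairs, clades)
        assert res["n_pairs"] == 2 and res["n_used"] == 1

    def test_no_labels_errors(self):
        pairs = make_pairs([("a", "b", "transposed")])
        with pytest.raises(ValueError, match="orientation"):
            ds.validate_synteny_orientation(pairs, pd.Series({"a": 1.0,
                                                              "b": 2.0}))
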