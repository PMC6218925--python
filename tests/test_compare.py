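import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subsetsig import (
    AnalysisConfig,
    IntensityMatrix,
    OrthologMap,
    RankedSignature,
    build_ranked_signature,
    collapse_probes,
    exclude_middle,
    harmonize_universe,
    max_self_similarity,
    permutation_test,
    similarity_matrix,
    similarity_score,
)

from conftest import brute_force_similarity


def _sig(*genes):
    return RankedSignature("s", "sp", tuple(genes))


class TestCollapseProbes:
    def _im(self, intensities, genes_of, n_samples=4):
        cols = [f"s{i}" for i in range(n_samples)]
        df = pd.DataFrame(intensities, index=list(genes_of), columns=cols)
        return IntensityMatrix(df, {p: frozenset(g) for p, g in genes_of.items()},
                               {c: "X" for c in cols})

    def test_multi_gene_probe_dropped(self):
        im = self._im(np.ones((2, 4)), {"P1": {"fA", "fB"}, "P2": {"fA"}})
        om = OrthologMap(frozenset({("fA", "bA"), ("fB", "bB")}))
        gm, audit = collapse_probes(im, om)
        assert gm.gene_ids == ["bA"]
        assert set(audit.loc[audit.rule == "multi_gene_or_unannotated", "probe"]) == {"P1"}

    def test_unannotated_probe_dropped(self):
        im = self._im(np.ones((2, 4)), {"P1": set(), "P2": {"fA"}})
        om = OrthologMap(frozenset({("fA", "bA")}))
        gm, audit = collapse_probes(im, om)
        assert gm.gene_ids == ["bA"]
        assert "P1" in set(audit["probe"])

    def test_ambiguous_ortholog_drops_all_probes_of_gene(self):
        im = self._im(np.ones((3, 4)), {"P1": {"fA"}, "P2": {"fA"}, "P3": {"fB"}})
        om = OrthologMap(frozenset({("fA", "bA"), ("fA", "bA2"), ("fB", "bB")}))
        gm, audit = collapse_probes(im, om)
        assert gm.gene_ids == ["bB"]
        dropped = audit.loc[audit.rule == "ambiguous_ortholog", "probe"]
        assert set(dropped) == {"P1", "P2"}

    def test_highest_mean_probe_retained(self):
        im = self._im(
            np.array([[5.2] * 4, [7.8] * 4]), {"P_low": {"fA"}, "P_high": {"fA"}}
        )
        om = OrthologMap(frozenset({("fA", "bA")}))
        gm, audit = collapse_probes(im, om)
        assert gm.log2_intensity.loc["bA"].iloc[0] == 7.8
        assert set(audit.loc[audit.rule == "lower_mean_duplicate", "probe"]) == {"P_low"}

    def test_empty_result_warns(self):
        im = self._im(np.ones((1, 4)), {"P1": set()})
        om = OrthologMap(frozenset())
        with pytest.warns(UserWarning, match="every probe"):
            gm, _ = collapse_probes(im, om)
        assert gm.gene_ids == []


class TestBuildRankedSignature:
    def _de(self, rows):
        return pd.DataFrame(
            {g: {"log2fc": fc, "adj_p": p} for g, (fc, p) in rows.items()}
        ).T[["log2fc", "adj_p"]]

    def test_hand_ordered_example(self):
        de = self._de({"a": (2, 0.001), "b": (1, 0.01), "c": (-1, 0.02), "d": (-3, 0.0001)})
        sig = build_ranked_signature(de, "x", "sp")
        assert list(sig.ordered_genes) == ["a", "b", "c", "d"]

    def test_all_zero_fc_lexicographic(self):
        de = self._de({"b": (0, 0.5), "a": (0, 0.1), "c": (0, 0.9)})
        sig = build_ranked_signature(de, "x", "sp")
        assert list(sig.ordered_genes) == ["a", "b", "c"]

    def test_sign_flip_reverses_list(self):
        de = self._de({"a": (2, 0.001), "b": (1, 0.01), "c": (-1, 0.02), "d": (-3, 0.0001)})
        flipped = de.assign(log2fc=-de["log2fc"])
        s1 = build_ranked_signature(de, "x", "sp")
        s2 = build_ranked_signature(flipped, "x", "sp")
        assert list(s2.ordered_genes) == list(reversed(s1.ordered_genes))

    def test_tie_break_larger_fc_more_extreme(self):
        de = self._de({"a": (1, 0.01), "b": (3, 0.01), "c": (-1, 0.01), "d": (-3, 0.01)})
        sig = build_ranked_signature(de, "x", "sp")
        assert list(sig.ordered_genes) == ["b", "a", "c", "d"]

    def test_duplicate_gene_rejected(self):
        de = pd.DataFrame(
            {"log2fc": [1, 2], "adj_p": [0.1, 0.2]}, index=["a", "a"]
        )
        with pytest.raises(ValueError, match="duplicate gene"):
            build_ranked_signature(de, "x", "sp")


class TestHarmonizeUniverse:
    def test_identical_universes_unchanged(self):
        a, b = _sig(*"abcd"), _sig(*"dcba")
        ha, hb = harmonize_universe(a, b)
        assert ha.ordered_genes == a.ordered_genes
        assert hb.ordered_genes == b.ordered_genes

    def test_missing_gene_removed_order_kept(self):
        a = _sig(*"abcxd")
        b = _sig(*"dcba")
        ha, hb = harmonize_universe(a, b)
        assert list(ha.ordered_genes) == list("abcd")
        assert ha.universe == hb.universe

    def test_subsequence_property_random_lists(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(5000)]
        shared = genes[:4000]
        a = RankedSignature("a", "x", tuple(rng.permutation(shared + genes[4000:4500])))
        b = RankedSignature("b", "y", tuple(rng.permutation(shared + genes[4500:5000])))
        ha, hb = harmonize_universe(a, b)
        assert len(ha) == len(hb) == 4000
        for orig, harm in ((a, ha), (b, hb)):
            pos = {g: i for i, g in enumerate(orig.ordered_genes)}
            idx = [pos[g] for g in harm.ordered_genes]
            assert idx == sorted(idx)  # a subsequence of its input

    def test_too_small_intersection_rejected(self):
        a, b = _sig(*"abcd"), _sig(*"abxy")
        with pytest.raises(ValueError, match="reduce n_tail"):
            harmonize_universe(a, b, min_size=4)


class TestExcludeMiddle:
    def test_zero_middle_frac_identity(self):
        a, b = _sig(*"abcdef"), _sig(*"fedcba")
        ra, rb = exclude_middle(a, b, 0.0)
        assert ra.ordered_genes == a.ordered_genes

    def test_identical_lists_keep_exact_tails(self):
        genes = [f"g{i}" for i in range(10)]
        a = RankedSignature("a", "x", tuple(genes))
        b = RankedSignature("b", "y", tuple(genes))
        ra, rb = exclude_middle(a, b, 0.6)
        # 20% tails of 10 positions = 2 genes each end
        assert set(ra.ordered_genes) == set(genes[:2] + genes[-2:])

    def test_gene_extreme_in_one_list_retained(self):
        genes = [f"g{i}" for i in range(10)]
        a = RankedSignature("a", "x", tuple(genes))
        # g5 is middle in a but top-ranked in b
        reordered = ["g5"] + [g for g in genes if g != "g5"]
        b = RankedSignature("b", "y", tuple(reordered))
        ra, _ = exclude_middle(a, b, 0.6)
        assert "g5" in ra.ordered_genes

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="harmonized"):
            exclude_middle(_sig(*"abc"), _sig(*"abd"), 0.5)


class TestSimilarityScore:
    def test_identical_lists_closed_form(self):
        l1 = _sig(*"abcdef")
        assert similarity_score(l1, l1, 2, 0.0) == pytest.approx(6.0)

    def test_disjoint_tails_score_zero(self):
        l1 = _sig(*"abcdef")
        l2 = _sig(*"cdefab")
        assert similarity_score(l1, l2, 2, 0.37) == 0.0

    @pytest.mark.parametrize("alpha,expected", [(0.0, 4.0), (np.log(2), 1.0)])
    def test_swapped_pairs_example(self, alpha, expected):
        l1 = _sig(*"abcdef")
        l2 = _sig(*"bacdfe")
        assert similarity_score(l1, l2, 2, alpha) == pytest.approx(expected)

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical universes"):
            similarity_score(_sig(*"abcd"), _sig(*"abce"), 1, 0.0)

    @pytest.mark.parametrize("alpha", [0.0, np.log(2)])
    def test_matches_brute_force_on_random_pairs(self, alpha):
        """Oracle equivalence on small universes, exact."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            u = int(rng.integers(4, 13))
            n_tail = int(rng.integers(1, min(4, u // 2) + 1))
            genes = [f"g{i}" for i in range(u)]
            a = RankedSignature("a", "x", tuple(rng.permutation(genes)))
            b = RankedSignature("b", "y", tuple(rng.permutation(genes)))
            ours = similarity_score(a, b, n_tail, alpha)
            oracle = brute_force_similarity(
                list(a.ordered_genes), list(b.ordered_genes), n_tail, alpha
            )
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        for _ in range(20):
            a = RankedSignature("a", "x", tuple(rng.permutation(genes)))
            b = RankedSignature("b", "y", tuple(rng.permutation(genes)))
            assert similarity_score(a, b, 10, 0.05) == pytest.approx(
                similarity_score(b, a, 10, 0.05)
            )

    def test_adding_shared_top_gene_never_decreases_score(self):
        """Swapping a non-shared top gene of b for a's top gene adds overlap."""
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        for _ in range(20):
            a = RankedSignature("a", "x", tuple(rng.permutation(genes)))
            b_list = list(rng.permutation(genes))
            base = RankedSignature("b", "y", tuple(b_list))
            s0 = similarity_score(a, base, 8, 0.1)
            top_a = [g for g in a.ordered_genes[:8] if g not in b_list[:8]]
            if not top_a:
                continue
            g_new = top_a[0]
            swap_out = next(g for g in b_list[:8] if g not in a.ordered_genes[:8])
            i, j = b_list.index(g_new), b_list.index(swap_out)
            b_list[i], b_list[j] = b_list[j], b_list[i]
            s1 = similarity_score(a, RankedSignature("b", "y", tuple(b_list)), 8, 0.1)
            assert s1 >= s0 - 1e-12

    def test_self_similarity_bound_attained_only_by_identical_lists(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        a = RankedSignature("a", "x", tuple(rng.permutation(genes)))
        bound = max_self_similarity(10, 0.2)
        assert similarity_score(a, a, 10, 0.2) == pytest.approx(bound)
        b = RankedSignature("b", "y", tuple(rng.permutation(genes)))
        if b.ordered_genes != a.ordered_genes:
            assert similarity_score(a, b, 10, 0.2) < bound


class TestPermutationTest:
    def test_identical_lists_minimum_p(self):
        genes = [f"g{i}" for i in range(200)]
        a = RankedSignature("a", "x", tuple(genes))
        b = RankedSignature("b", "y", tuple(genes))
        cfg = AnalysisConfig(n_tail=20, n_perm=99, rng_seed=1)
        res = permutation_test(a, b, cfg, seed=5)
        assert res.empirical_p == pytest.approx(1 / 100)
        assert res.score_observed == pytest.approx(
            max_self_similarity(20, cfg.alpha)
        )

    def test_score_bounded_by_self_similarity(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(300)]
        a = RankedSignature("a", "x", tuple(rng.permutation(genes)))
        b = RankedSignature("b", "y", tuple(rng.permutation(genes)))
        cfg = AnalysisConfig(n_tail=30, n_perm=50, rng_seed=2)
        res = permutation_test(a, b, cfg, seed=3)
        bound = max_self_similarity(cfg.n_tail, cfg.alpha)
        assert res.score_observed <= bound + 1e-9
        assert np.all(res.null_scores <= bound + 1e-9)

    def test_null_p_values_approximately_uniform(self):
        """Empirical p over independent random list pairs ~ U(0,1)."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(500)]
        cfg = AnalysisConfig(n_tail=25, n_perm=100, middle_frac=0.6, rng_seed=0)
        ps = []
        for rep in range(100):
            a = RankedSignature("a", "x", tuple(rng.permutation(genes)))
            b = RankedSignature("b", "y", tuple(rng.permutation(genes)))
            ps.append(permutation_test(a, b, cfg, seed=1000 + rep).empirical_p)
        _, p = stats.kstest(ps, "uniform")
        assert p > 0.01

    def test_full_list_scoring_flag(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(300)]
        a = RankedSignature("a", "x", tuple(rng.permutation(genes)))
        b = RankedSignature("b", "y", tuple(rng.permutation(genes)))
        cfg_r = AnalysisConfig(n_tail=20, n_perm=50, rng_seed=3, score_on_restricted=True)
        cfg_f = AnalysisConfig(n_tail=20, n_perm=50, rng_seed=3, score_on_restricted=False)
        res_r = permutation_test(a, b, cfg_r, seed=4)
        res_f = permutation_test(a, b, cfg_f, seed=4)
        full = similarity_score(a, b, 20, cfg_f.alpha)
        assert res_f.score_observed == pytest.approx(full)
        assert res_r.score_observed >= res_f.score_observed - 1e-12


class TestSimilarityMatrix:
    @pytest.fixture(scope="class")
    def sig_set(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(400)]
        sigs = []
        for lbl in ["pDC", "cDC1", "cM"]:
            sigs.append(RankedSignature(lbl, "bovine", tuple(rng.permutation(genes))))
        return sigs

    def test_self_comparison_diagonal_is_maximal(self, sig_set):
        cfg = AnalysisConfig(n_tail=30, n_perm=50, rng_seed=5)
        foreign = [RankedSignature(s.subset_label, "mirror", s.ordered_genes) for s in sig_set]
        cells, results = similarity_matrix(sig_set, foreign, cfg)
        for s in sig_set:
            row = {c: results[(s.subset_label, c)] for c in cells.columns}
            diag = row[f"mirror:{s.subset_label}"]
            assert diag.score_observed == max(r.score_observed for r in row.values())
            assert diag.empirical_p == min(r.empirical_p for r in row.values())

    def test_column_order_permutation_only_permutes_columns(self, sig_set):
        cfg = AnalysisConfig(n_tail=30, n_perm=50, rng_seed=5)
        foreign = [RankedSignature(s.subset_label, "mirror", s.ordered_genes) for s in sig_set]
        c1, _ = similarity_matrix(sig_set, foreign, cfg)
        c2, _ = similarity_matrix(sig_set, foreign[::-1], cfg)
        assert list(c2.columns) == list(c1.columns)[::-1]
        pd.testing.assert_frame_equal(c1, c2[c1.columns])
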