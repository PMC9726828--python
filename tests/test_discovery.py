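import itertools

import numpy as np
import pandas as pd
import pytest

from crmscreen.discovery import (
    ScreenConfig,
    ddm_score,
    derive_replicate_seed,
    fdr_adjust,
    rank_product,
    rank_product_pvalues,
    replicate_screen,
    run_screen,
    sample_background_sets,
    select_top_regulators,
)
from crmscreen.io import GeneAnnotation
from crmscreen.potential import TargetMatrix


def make_targets(matrix, genes=None, tfs=None, cutoff=0.05) -> TargetMatrix:
    m = np.asarray(matrix)
    genes = genes or [f"g{i + 1}" for i in range(m.shape[0])]
    tfs = tfs or [f"t{j + 1}" for j in range(m.shape[1])]
    return TargetMatrix(
        values=pd.DataFrame(m, index=pd.Index(genes, name="gene_id"), columns=tfs),
        cutoff=cutoff,
    )


def brute_force_ddm(m, fg_idx, bg_idx):
    """Independent oracle: materialize every gene pair explicitly."""
    scores = []
    for t in range(m.shape[1]):
        col = m[:, t]
        between = np.mean(
            [abs(col[f] - col[b]) for f in fg_idx for b in bg_idx]
        )
        within = np.mean(
            [abs(col[f] - col[g]) for f, g in itertools.combinations(fg_idx, 2)]
        )
        pf = np.mean([col[f] for f in fg_idx])
        pb = np.mean([col[b] for b in bg_idx])
        scores.append((between - within) * np.sign(pf - pb))
    return np.array(scores)


class TestDdmScore:
    def test_perfect_discriminator_scores_one(self):
        tm = make_targets([[1], [1], [0], [0]])
        s = ddm_score(tm, ["g1", "g2"], ["g3", "g4"])
        assert s["t1"] == 1.0

    def test_constant_column_scores_zero(self):
        tm = make_targets([[1], [1], [1], [1]])
        assert ddm_score(tm, ["g1", "g2"], ["g3", "g4"])["t1"] == 0.0

    def test_equal_fractions_get_sign_zero(self):
        # raw = 0.5 - 1 = -0.5 but frac_fg == frac_bg == 0.5 -> score 0
        tm = make_targets([[1], [0], [1], [0]])
        assert ddm_score(tm, ["g1", "g2"], ["g3", "g4"])["t1"] == 0.0

    def test_unknown_gene_is_error(self):
        tm = make_targets([[1], [0], [1], [0]])
        with pytest.raises(KeyError, match="nope"):
            ddm_score(tm, ["g1", "nope"], ["g3", "g4"])

    def test_matches_brute_force_oracle_on_random_matrices(self):
        """Exact equality with explicit pair enumeration, many random shapes."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n_genes = rng.integers(4, 7)
            n_tfs = rng.integers(1, 5)
            m = rng.integers(0, 2, size=(n_genes, n_tfs))
            tm = make_targets(m)
            genes = list(tm.values.index)
            fg_size = int(rng.integers(2, n_genes - 1))
            fg = genes[:fg_size]
            bg = genes[fg_size:]
            got = ddm_score(tm, fg, bg).to_numpy()
            want = brute_force_ddm(m.astype(float), range(fg_size), range(fg_size, n_genes))
            np.testing.assert_array_equal(got, want)

    def test_sign_negates_when_groups_swap(self):
        """Group-constant columns: swapping foreground and background flips
        the enrichment direction, so the score negates exactly."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            fg_val, bg_val = rng.integers(0, 2, size=2)
            m = np.array([[fg_val]] * 4 + [[bg_val]] * 4)
            tm = make_targets(m)
            genes = list(tm.values.index)
            fwd = ddm_score(tm, genes[:4], genes[4:])["t1"]
            rev = ddm_score(tm, genes[4:], genes[:4])["t1"]
            assert rev == -fwd


class TestBackgroundSampling:
    def _annotation(self, n):
        return GeneAnnotation.from_records(
            [(f"g{i}", "chr1", 1000 * i, "+") for i in range(n)]
        )

    def test_same_seed_gives_identical_sets(self):
        ann = self._annotation(30)
        cfg = ScreenConfig(n_background_sets=5, background_set_size=8)
        a = sample_background_sets(ann, ["g0", "g1"], cfg, replicate_seed=42)
        b = sample_background_sets(ann, ["g0", "g1"], cfg, replicate_seed=42)
        assert a == b

    def test_foreground_never_sampled(self):
        ann = self._annotation(20)
        cfg = ScreenConfig(n_background_sets=50, background_set_size=8)
        fg = {"g0", "g5", "g9"}
        for s in sample_background_sets(ann, list(fg), cfg, replicate_seed=1):
            assert not fg & set(s)
            assert len(set(s)) == 8

    def test_forced_sample_when_universe_equals_set_size(self):
        ann = self._annotation(10)
        cfg = ScreenConfig(n_background_sets=3, background_set_size=8)
        fg = ["g0", "g1"]
        for s in sample_background_sets(ann, fg, cfg, replicate_seed=1):
            assert sorted(s) == [f"g{i}" for i in range(2, 10)]

    def test_insufficient_universe_is_error_with_counts(self):
        ann = self._annotation(8)
        cfg = ScreenConfig(n_background_sets=1, background_set_size=8)
        with pytest.raises(ValueError, match="7"):
            sample_background_sets(ann, ["g0"], cfg, replicate_seed=1)


class TestReplicateScreen:
    def test_single_background_set_equals_its_ddm_score(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 2, size=(12, 3))
        tm = make_targets(m)
        ann = GeneAnnotation.from_records(
            [(g, "chr1", 100 * i, "+") for i, g in enumerate(tm.values.index)]
        )
        fg = list(tm.values.index[:4])
        cfg = ScreenConfig(n_background_sets=1, background_set_size=8, seed=9)
        scores, _ = replicate_screen(tm, ann, fg, cfg, replicate_index=0)
        seed = derive_replicate_seed(9, 0)
        (bg,) = sample_background_sets(ann, fg, cfg, seed)
        pd.testing.assert_series_equal(
            scores, ddm_score(tm, fg, bg), check_names=False
        )

    def test_ranks_descend_by_score_with_midranks(self):
        # three TFs engineered to score (high, low, high) -> ranks (1.5, 3, 1.5)
        m = np.array([[1, 0, 1], [1, 0, 1], [1, 0, 1], [1, 0, 1]] + [[0, 0, 0]] * 8)
        tm = make_targets(m)
        ann = GeneAnnotation.from_records(
            [(g, "chr1", 100 * i, "+") for i, g in enumerate(tm.values.index)]
        )
        fg = list(tm.values.index[:4])
        cfg = ScreenConfig(n_background_sets=4, background_set_size=8, seed=0)
        scores, ranks = replicate_screen(tm, ann, fg, cfg, 0)
        assert scores["t1"] == scores["t3"] > scores["t2"]
        assert ranks.tolist() == [1.5, 3.0, 1.5]


class TestRankProduct:
    def test_all_ones_gives_one(self):
        ranks = pd.DataFrame({"r1": [1.0], "r2": [1.0]}, index=["t"])
        assert rank_product(ranks)["t"] == 1.0

    def test_two_and_eight_gives_four(self):
        ranks = pd.DataFrame({"r1": [2.0], "r2": [8.0]}, index=["t"])
        assert rank_product(ranks)["t"] == pytest.approx(4.0)

    def test_one_two_three_gives_cube_root_of_six(self):
        ranks = pd.DataFrame({"r1": [1.0], "r2": [2.0], "r3": [3.0]}, index=["t"])
        assert rank_product(ranks)["t"] == pytest.approx(6 ** (1 / 3))

    def test_missing_rank_is_error(self):
        ranks = pd.DataFrame({"r1": [1.0], "r2": [np.nan]}, index=["t"])
        with pytest.raises(ValueError):
            rank_product(ranks)


def exhaustive_rank_product_null(n_tfs, n_replicates):
    """Oracle: enumerate every combination of per-replicate permutations and
    pool all TF slots' rank products."""
    perms = list(itertools.permutations(range(1, n_tfs + 1)))
    pool = []
    for combo in itertools.product(perms, repeat=n_replicates):
        for t in range(n_tfs):
            ranks = [combo[r][t] for r in range(n_replicates)]
            pool.append(np.exp(np.mean(np.log(ranks))))
    return np.array(pool)


class TestRankProductPvalues:
    def test_best_possible_rank_product_matches_exact_quarter(self):
        """n_tfs=2, 2 replicates, observed ranks (1,1): the exact null gives
        P(RP <= 1) = 1/4; the Monte-Carlo estimate must land within 3 SE."""
        rp = pd.Series([1.0], index=["t"])
        n_perm = 10_000
        p = rank_product_pvalues(rp, n_tfs=2, n_replicates=2, n_permutations=n_perm, seed=1)
        se = np.sqrt(0.25 * 0.75 / (2 * n_perm))
        assert abs(p["t"] - 0.25) <= 3 * se

    @pytest.mark.parametrize("n_tfs", [2, 3])
    def test_matches_exhaustive_enumeration(self, n_tfs):
        pool = exhaustive_rank_product_null(n_tfs, n_replicates=2)
        observed = np.unique(pool)
        rp = pd.Series(observed, index=[f"t{i}" for i in range(len(observed))])
        n_perm = 10_000
        p = rank_product_pvalues(rp, n_tfs, 2, n_perm, seed=2)
        for i, v in enumerate(observed):
            exact = np.mean(pool <= v + 1e-12)
            se = np.sqrt(max(exact * (1 - exact), 1e-9) / (n_tfs * n_perm))
            assert abs(p.iloc[i] - exact) <= 3 * se + 2 / (n_tfs * n_perm)

    def test_worst_rank_product_gets_p_one(self):
        rp = pd.Series([3.0], index=["t"])
        p = rank_product_pvalues(rp, n_tfs=3, n_replicates=2, n_permutations=500, seed=0)
        assert p["t"] == 1.0

    def test_doubling_permutations_is_consistent(self):
        rp = pd.Series([1.0, 2.0], index=["a", "b"])
        p1 = rank_product_pvalues(rp, 4, 3, 5_000, seed=3)
        p2 = rank_product_pvalues(rp, 4, 3, 10_000, seed=3)
        se = np.sqrt(0.25 / (4 * 5_000))
        assert (np.abs(p1 - p2) <= 3 * se).all()

    def test_invalid_permutation_count_is_error(self):
        with pytest.raises(ValueError):
            rank_product_pvalues(pd.Series([1.0]), 2, 2, 0, seed=0)


class TestFdrAdjust:
    def test_step_up_hand_example(self):
        p = pd.Series([0.01, 0.02, 0.04, 0.8])
        q = fdr_adjust(p)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.05333333333333334, 0.8])

    def test_all_equal_pvalues_unchanged(self):
        q = fdr_adjust(pd.Series([0.3, 0.3, 0.3]))
        np.testing.assert_allclose(q, [0.3, 0.3, 0.3])

    def test_single_pvalue_unchanged(self):
        assert fdr_adjust(pd.Series([0.07])).iloc[0] == pytest.approx(0.07)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_out_of_range_pvalue_rejected(self, bad):
        with pytest.raises(ValueError):
            fdr_adjust(pd.Series([0.5, bad]))


class TestSelectTopRegulators:
    def _ranking(self, tfs, rps, qs):
        return pd.DataFrame({"tf": tfs, "rank_product": rps, "q_value": qs})

    def test_none_below_cutoff_gives_empty_list(self):
        r = self._ranking(["a", "b"], [1.0, 2.0], [0.2, 0.9])
        assert select_top_regulators(r, 0.05) == []

    def test_only_significant_tf_selected(self):
        r = self._ranking(["a", "b"], [1.0, 2.0], [0.01, 0.2])
        assert select_top_regulators(r, 0.05) == ["a"]

    def test_rank_product_tie_broken_alphabetically(self):
        r = self._ranking(["zz", "aa"], [1.5, 1.5], [0.01, 0.01])
        assert select_top_regulators(r, 0.05) == ["aa", "zz"]


def test_screen_is_pure_function_of_inputs_and_seed():
    rng = np.random.default_rng(21)
    m = rng.integers(0, 2, size=(30, 5))
    tm = make_targets(m)
    ann = GeneAnnotation.from_records(
        [(g, "chr1", 500 * i, "+") for i, g in enumerate(tm.values.index)]
    )
    fg = list(tm.values.index[:4])
    cfg = ScreenConfig(n_background_sets=20, n_replicates=3, n_permutations=500, seed=17)
    r1 = run_screen(tm, ann, fg, cfg)
    r2 = run_screen(tm, ann, fg, cfg)
    pd.testing.assert_frame_equal(r1, r2)
    cfg2 = ScreenConfig(n_background_sets=20, n_replicates=3, n_permutations=500, seed=18)
    r3 = run_screen(tm, ann, fg, cfg2)
    assert not r1[[c for c in r1 if c.startswith("score_")]].equals(
        r3[[c for c in r3 if c.startswith("score_")]]
    )
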