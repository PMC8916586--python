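import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lncpairs as lp
from lncpairs import pairs as pm
from lncpairs.io import ValidationError
from lncpairs.pairs import A_GT_B, A_LT_B, OrientedPair, RankMatrix


def _rank_matrix(data: dict, samples=None) -> RankMatrix:
    df = pd.DataFrame(data).T
    if samples is not None:
        df.columns = samples
    return RankMatrix(df)


class TestRankTransform:
    def test_basic_column(self, tiny_cohort):
        cohort = tiny_cohort
        cohort.values.loc[["LNC_A", "LNC_B", "LNC_C"], "T0"] = [2.0, 5.0, 3.0]
        rm = lp.rank_transform(cohort, ["LNC_A", "LNC_B", "LNC_C"])
        assert list(rm.ranks["T0"]) == [1.0, 3.0, 2.0]

    def test_average_tie_convention(self, tiny_cohort):
        cohort = tiny_cohort
        cohort.values.loc[["LNC_A", "LNC_B", "LNC_C"], "T1"] = [4.0, 4.0, 1.0]
        rm = lp.rank_transform(cohort, ["LNC_A", "LNC_B", "LNC_C"])
        assert list(rm.ranks["T1"]) == [2.5, 2.5, 1.0]

    def test_monotone_invariance_exp(self, tiny_cohort):
        genes = list(tiny_cohort.gene_ids)
        before = lp.rank_transform(tiny_cohort, genes)
        transformed = lp.ExpressionCohort(
            "t",
            np.exp(tiny_cohort.values / 4.0),
            tiny_cohort.gene_type,
            tiny_cohort.sample_group,
        )
        after = lp.rank_transform(transformed, genes)
        pd.testing.assert_frame_equal(before.ranks, after.ranks)

    def test_column_sums_preserved_under_ties(self, tiny_cohort):
        genes = list(tiny_cohort.gene_ids)
        tiny_cohort.values.iloc[0, :] = tiny_cohort.values.iloc[1, :]  # force ties
        rm = lp.rank_transform(tiny_cohort, genes)
        G = len(genes)
        assert np.allclose(rm.ranks.sum(axis=0), G * (G + 1) / 2)

    def test_unknown_gene_rejected(self, tiny_cohort):
        with pytest.raises(ValidationError):
            lp.rank_transform(tiny_cohort, ["NOPE"])


class TestStablePairs:
    def _two_gene_ranks(self, n_a_lt_b, n_total):
        # gene A below B in the first n_a_lt_b samples, above in the rest
        a = np.where(np.arange(n_total) < n_a_lt_b, 1.0, 2.0)
        return _rank_matrix({"A": a, "B": 3.0 - a})

    def test_full_support(self):
        rm = self._two_gene_ranks(100, 100)
        (pair,) = lp.find_stable_pairs(rm, 0.85)
        assert pair.orientation == A_LT_B
        assert pair.support_normal == 1.0

    def test_threshold_is_inclusive(self):
        rm = self._two_gene_ranks(85, 100)
        (pair,) = lp.find_stable_pairs(rm, 0.85)
        assert pair.support_normal == pytest.approx(0.85)

    def test_below_threshold_excluded(self):
        rm = self._two_gene_ranks(60, 100)
        assert lp.find_stable_pairs(rm, 0.85) == []

    def test_too_few_normals(self):
        rm = self._two_gene_ranks(4, 4)
        with pytest.raises(ValidationError, match="normal samples"):
            lp.find_stable_pairs(rm, 0.85)

    def test_ties_count_toward_neither(self):
        rm = _rank_matrix({"A": [1.5] * 10, "B": [1.5] * 10})
        assert lp.find_stable_pairs(rm, 0.5) == []


class TestReversalPairs:
    def test_reversal_detected_with_tumor_orientation(self):
        stable = [OrientedPair("A", "B", A_LT_B, support_normal=0.95)]
        a = np.where(np.arange(100) < 90, 2.0, 1.0)
        tum = _rank_matrix({"A": a, "B": 3.0 - a})
        (rev,) = lp.find_reversal_pairs(tum, stable, 0.85)
        assert rev.orientation == A_GT_B
        assert rev.support_tumor == pytest.approx(0.90)
        assert rev.support_normal == pytest.approx(0.95)

    def test_insufficient_flip_excluded(self):
        stable = [OrientedPair("A", "B", A_LT_B)]
        a = np.where(np.arange(100) < 50, 2.0, 1.0)
        tum = _rank_matrix({"A": a, "B": 3.0 - a})
        assert lp.find_reversal_pairs(tum, stable, 0.85) == []

    def test_reversal_subset_of_stable(self, small_sim):
        cohorts, _, truth = small_sim
        c = cohorts[0]
        rn = lp.rank_transform(c, truth.true_pdl_ids, sample_group="normal")
        rt = lp.rank_transform(c, truth.true_pdl_ids, sample_group="tumor")
        stable = lp.find_stable_pairs(rn, 0.85)
        rev = lp.find_reversal_pairs(rt, stable, 0.85)
        stable_genes = {frozenset(p.genes) for p in stable}
        assert all(frozenset(p.genes) in stable_genes for p in rev)


class TestDirections:
    def test_up_down_unchanged(self):
        tum = _rank_matrix({"A": [40.0] * 5, "B": [10.0] * 5, "C": [5.0] * 5})
        norm = _rank_matrix({"A": [10.0] * 4, "B": [30.0] * 4, "C": [5.0] * 4})
        dirs = {d.gene_id: d.direction for d in lp.deregulation_directions(tum, norm)}
        assert dirs == {"A": "up", "B": "down", "C": "unchanged"}

    def test_median_agrees_with_numpy(self, small_sim):
        cohorts, _, _ = small_sim
        c = cohorts[0]
        genes = list(c.lncrna_ids)
        rt = lp.rank_transform(c, genes, sample_group="tumor")
        rn = lp.rank_transform(c, genes, sample_group="normal")
        for d in lp.deregulation_directions(rt, rn):
            assert d.median_rank_tumor == np.median(rt.ranks.loc[d.gene_id])
            assert d.median_rank_normal == np.median(rn.ranks.loc[d.gene_id])

    def test_universe_mismatch_rejected(self):
        tum = _rank_matrix({"A": [1.0], "B": [2.0]})
        norm = _rank_matrix({"A": [1.0], "C": [2.0]})
        with pytest.raises(ValidationError):
            lp.deregulation_directions(tum, norm)

    def test_same_direction_filter(self):
        from lncpairs.pairs import DeregulationDirection as DD

        pairs = [
            OrientedPair("A", "B", A_GT_B),
            OrientedPair("A", "D", A_GT_B),
            OrientedPair("A", "U", A_GT_B),
        ]
        dirs = [
            DD("A", "up", 2, 1),
            DD("B", "up", 2, 1),
            DD("D", "down", 1, 2),
            DD("U", "unchanged", 1, 1),
        ]
        kept = lp.filter_same_direction(pairs, dirs)
        assert [p.gene_b for p in kept] == ["B"]


class TestPartnerCV:
    def test_cv_matches_brute_force(self, small_sim):
        cohorts, _, truth = small_sim
        c = cohorts[0]
        rt = lp.rank_transform(c, list(c.lncrna_ids), sample_group="tumor")
        a, b = truth.true_pdl_ids[0], truth.true_pdl_ids[1]
        d = rt.ranks.loc[a].to_numpy() - rt.ranks.loc[b].to_numpy()
        expected = np.std(d, ddof=1) / abs(np.mean(d))
        assert lp.partner_cv(rt, a, b) == pytest.approx(expected, rel=1e-12)

    def test_zero_mean_gives_infinity(self):
        rt = _rank_matrix({"A": [1.0, 2.0], "B": [2.0, 1.0]})
        assert lp.partner_cv(rt, "A", "B") == np.inf

    def test_top_k_limits_partners(self):
        rng = np.random.default_rng(0)
        genes = ["A"] + [f"P{i}" for i in range(5)]
        ranks = {g: rng.permutation(6).astype(float) + 1 for g in genes}
        rt = _rank_matrix(ranks)
        pairs = [OrientedPair(*sorted(("A", f"P{i}")), orientation=A_GT_B) for i in range(5)]
        kept = lp.partner_cv_prune(pairs, rt, top_k=3)
        # anchor A keeps <= 3, but each partner keeps A as its only partner
        anchored_via_a = {p.genes for p in kept}
        assert len(anchored_via_a) == 5  # single-partner anchors retain their pair

    def test_single_partner_always_retained(self):
        rt = _rank_matrix({"A": [1.0, 1.0, 2.0], "B": [2.0, 2.0, 1.0]})
        pairs = [OrientedPair("A", "B", A_GT_B)]
        assert lp.partner_cv_prune(pairs, rt, top_k=1) == pairs


class TestQualification:
    def _tum_ranks(self, frac, n=100):
        a = np.where(np.arange(n) < int(frac * n), 2.0, 1.0)
        return _rank_matrix({"A": a, "B": 3.0 - a})

    def test_strictly_above_retained(self):
        (kept,) = lp.qualify_pairs(
            [OrientedPair("A", "B", A_GT_B)], self._tum_ranks(0.61), 0.60
        )
        assert kept.support_tumor == pytest.approx(0.61)

    def test_exact_boundary_excluded(self):
        assert (
            lp.qualify_pairs([OrientedPair("A", "B", A_GT_B)], self._tum_ranks(0.60), 0.60)
            == []
        )

    def test_full_support_retained(self):
        assert len(
            lp.qualify_pairs([OrientedPair("A", "B", A_GT_B)], self._tum_ranks(1.0), 0.60)
        ) == 1


class TestEncoding:
    def test_greater_encodes_one(self, tiny_cohort):
        tiny_cohort.values.loc["LNC_A", "T0"] = 7.1
        tiny_cohort.values.loc["LNC_B", "T0"] = 3.2
        ind = lp.encode_pairs(tiny_cohort, [OrientedPair("LNC_A", "LNC_B", A_GT_B)])
        assert ind.indicators.loc["LNC_A|LNC_B", "T0"] == 1

    def test_tie_encodes_zero(self, tiny_cohort):
        tiny_cohort.values.loc["LNC_A", "T1"] = 5.0
        tiny_cohort.values.loc["LNC_B", "T1"] = 5.0
        ind = lp.encode_pairs(tiny_cohort, [OrientedPair("LNC_A", "LNC_B", A_GT_B)])
        assert ind.indicators.loc["LNC_A|LNC_B", "T1"] == 0

    def test_orientation_flag_flips_meaning(self, tiny_cohort):
        tiny_cohort.values.loc["LNC_A", "T0"] = 1.0
        tiny_cohort.values.loc["LNC_B", "T0"] = 2.0
        ind = lp.encode_pairs(tiny_cohort, [OrientedPair("LNC_A", "LNC_B", A_LT_B)])
        assert ind.indicators.loc["LNC_A|LNC_B", "T0"] == 1

    def test_per_sample_monotone_invariance(self, tiny_cohort):
        pairs = [OrientedPair("LNC_A", "LNC_B", A_GT_B), OrientedPair("MR_X", "MR_Y", A_LT_B)]
        before = lp.encode_pairs(tiny_cohort, pairs)
        vals = tiny_cohort.values.copy()
        rng = np.random.default_rng(3)
        for j, s in enumerate(vals.columns):  # a different monotone map per sample
            a, b = rng.uniform(0.5, 3.0), rng.uniform(-1, 1)
            vals[s] = a * vals[s] ** 1.5 + b
        transformed = lp.ExpressionCohort(
            "t", vals - vals.min().min() + 0.01, tiny_cohort.gene_type, tiny_cohort.sample_group
        )
        after = lp.encode_pairs(transformed, pairs)
        pd.testing.assert_frame_equal(before.indicators, after.indicators)

    def test_missing_gene_rejected(self, tiny_cohort):
        with pytest.raises(ValidationError, match="ZZZ"):
            lp.encode_pairs(tiny_cohort, [OrientedPair("LNC_A", "ZZZ", A_GT_B)])


class TestEnumerate:
    @pytest.mark.parametrize("n,expected", [(2, 1), (5, 10), (350, 61075), (500, 124750)])
    def test_pair_counts(self, n, expected):
        ids = [f"G{i:04d}" for i in range(n)]
        assert len(lp.enumerate_pairs(ids)) == expected

    @given(st.integers(min_value=2, max_value=120))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_count_formula(self, n):
        ids = [f"G{i}" for i in range(n)]
        pairs = lp.enumerate_pairs(ids)
        assert len(pairs) == n * (n - 1) // 2
        assert len(set(pairs)) == len(pairs)
        assert all(a < b for a, b in pairs)

    def test_errors(self):
        with pytest.raises(ValidationError):
            lp.enumerate_pairs(["A"])
        with pytest.raises(ValidationError):
            lp.enumerate_pairs(["A", "A", "B"])


class TestIntersection:
    def test_identical_sets(self):
        s = [OrientedPair("A", "B", A_GT_B), OrientedPair("C", "D", A_LT_B)]
        assert lp.intersect_pair_sets([s, list(s)]) == s

    def test_opposite_orientation_excluded(self):
        s1 = [OrientedPair("A", "B", A_GT_B)]
        s2 = [OrientedPair("A", "B", A_LT_B)]
        assert lp.intersect_pair_sets([s1, s2]) == []

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(12)]

        def random_set():
            out = []
            for a, b in lp.enumerate_pairs(genes):
                if rng.random() < 0.4:
                    out.append(OrientedPair(a, b, rng.choice([A_GT_B, A_LT_B])))
            return out

        sets = [random_set() for _ in range(3)]
        got = {p.key for p in lp.intersect_pair_sets(sets)}
        brute = {
            p.key
            for p in sets[0]
            if all(any(q.key == p.key for q in s) for s in sets[1:])
        }
        assert got == brute

    def test_needs_two_sets(self):
        with pytest.raises(ValidationError):
            lp.intersect_pair_sets([[OrientedPair("A", "B", A_GT_B)]])


class TestPairInvariants:
    def test_canonical_storage_enforced(self):
        with pytest.raises(ValidationError):
            OrientedPair("B", "A", A_GT_B)
        with pytest.raises(ValidationError):
            OrientedPair("A", "A", A_GT_B)

    def test_filter_chain_is_nested(self, small_sim):
        cohorts, _, truth = small_sim
        c = cohorts[0]
        all_lnc = list(c.lncrna_ids)
        rn_all = lp.rank_transform(c, all_lnc, sample_group="normal")
        rt_all = lp.rank_transform(c, all_lnc, sample_group="tumor")
        rn = RankMatrix(rn_all.ranks.loc[truth.true_pdl_ids])
        rt = RankMatrix(rt_all.ranks.loc[truth.true_pdl_ids])
        stable = lp.find_stable_pairs(rn, 0.85)
        rev = lp.find_reversal_pairs(rt, stable, 0.85)
        dirs = lp.deregulation_directions(rt_all, rn_all)
        same = lp.filter_same_direction(rev, dirs)
        pruned = lp.partner_cv_prune(same, rt_all, 3)
        qual = lp.qualify_pairs(pruned, rt, 0.60)
        as_keys = lambda ps: {p.key for p in ps}
        assert as_keys(qual) <= as_keys(pruned) <= as_keys(same) <= as_keys(rev)
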