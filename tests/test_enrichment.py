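"""Weighted-KS statistic, permutation null, NES/FDR and Welch t contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from subtypescreen.enrichment import (
    EnrichmentResult,
    RankedList,
    enrichment_score,
    nejm_stars,
    normalize_and_fdr,
    permutation_null,
    welch_t,
)


def brute_force_ks(n: int, member_positions: set[int]) -> float:
    """Unweighted KS running-sum extremum by direct cumulative scan."""
    n_hit = len(member_positions)
    best = 0.0
    running = 0.0
    for i in range(n):
        running += 1.0 / n_hit if i in member_positions else -1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def make_ranking(n: int) -> RankedList:
    return RankedList([f"i{k}" for k in range(n)], np.arange(n, 0, -1, dtype=float))


class TestEnrichmentScore:
    def test_single_member_at_top_is_one(self):
        es, _, edge = enrichment_score(make_ranking(10), {"i0"}, 1.0)
        assert es == pytest.approx(1.0)
        assert edge == ["i0"]

    def test_single_member_at_bottom(self):
        # four misses of -1/4 reach -1 before the hit returns the sum to 0
        es, _, _ = enrichment_score(make_ranking(5), {"i4"}, 0.0)
        assert es == pytest.approx(-1.0)

    def test_odd_ranks_match_brute_force(self):
        members = {f"i{k}" for k in range(0, 10, 2)}
        es, _, _ = enrichment_score(make_ranking(10), members, 0.0)
        assert es == pytest.approx(brute_force_ks(10, set(range(0, 10, 2))))

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_exponent_zero_equals_brute_force(self, data):
        n = data.draw(st.integers(3, 50))
        size = data.draw(st.integers(1, n - 1))
        positions = set(
            data.draw(
                st.lists(st.integers(0, n - 1), min_size=size, max_size=size, unique=True)
            )
        )
        ranking = make_ranking(n)
        members = {f"i{k}" for k in positions}
        es, _, _ = enrichment_score(ranking, members, 0.0)
        assert es == pytest.approx(brute_force_ks(n, positions))

    @pytest.mark.parametrize("seed", range(50))
    def test_reversing_ranking_negates_es_exponent_zero(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        size = int(rng.integers(1, n - 1))
        positions = rng.choice(n, size=size, replace=False)
        forward = make_ranking(n)
        members = {f"i{k}" for k in positions}
        rev_members = {f"i{n - 1 - k}" for k in positions}
        es_f, running, _ = enrichment_score(forward, members, 0.0)
        es_r, _, _ = enrichment_score(forward, rev_members, 0.0)
        assert abs(es_f) == pytest.approx(abs(es_r))
        # when the positive peak exactly ties the negative trough no tie-break
        # can be antisymmetric; only the magnitude is pinned down there
        if abs(running.max() + running.min()) > 1e-9:
            assert es_f == pytest.approx(-es_r)

    def test_empty_and_full_overlap_rejected(self):
        ranking = make_ranking(5)
        with pytest.raises(ValueError, match="overlap"):
            enrichment_score(ranking, {"zzz"}, 1.0)
        with pytest.raises(ValueError, match="whole ranking"):
            enrichment_score(ranking, {f"i{k}" for k in range(5)}, 1.0)

    def test_leading_edge_negative_es(self):
        es, _, edge = enrichment_score(make_ranking(6), {"i4", "i5"}, 0.0)
        assert es < 0
        assert edge == ["i4", "i5"]

    def test_all_zero_hit_weights_fall_back_to_unweighted(self):
        metric = np.array([5.0, 4.0, 3.0, 0.0, 0.0])
        ranking = RankedList([f"i{k}" for k in range(5)], metric)
        es, _, _ = enrichment_score(ranking, {"i3", "i4"}, 1.0)
        es0, _, _ = enrichment_score(ranking, {"i3", "i4"}, 0.0)
        assert es == pytest.approx(es0)


class TestPermutationNull:
    def test_null_mean_near_zero(self):
        ranking = make_ranking(100)
        null = permutation_null(ranking, 10, 1000, 0.0, seed=1)
        se = null.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.mean()) < 3 * se

    def test_seed_determinism(self):
        ranking = make_ranking(50)
        a = permutation_null(ranking, 5, 200, 1.0, seed=9)
        b = permutation_null(ranking, 5, 200, 1.0, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_set_size_must_be_smaller_than_universe(self):
        with pytest.raises(ValueError, match="set_size"):
            permutation_null(make_ranking(10), 10, 200, 1.0, seed=0)


def brute_force_q(obs_nes, pooled_null_nes):
    """Two-fraction GSEA FDR ratio, exhaustively, without monotonization."""
    out = []
    obs = np.asarray(obs_nes)
    pool = np.asarray(pooled_null_nes)
    for nes in obs:
        sign = np.sign(nes)
        pool_same = pool[np.sign(pool) == sign]
        obs_same = obs[np.sign(obs) == sign]
        null_frac = np.mean(np.abs(pool_same) >= abs(nes)) if pool_same.size else 0.0
        obs_frac = np.mean(np.abs(obs_same) >= abs(nes))
        out.append(min(1.0, null_frac / obs_frac))
    return out


class TestNormalizeAndFdr:
    def test_zero_es_gives_zero_nes_p_one(self):
        nulls = {"A": np.concatenate([np.full(50, 0.5), np.full(50, -0.5)])}
        res = normalize_and_fdr([EnrichmentResult("A", 0.0, 5)], nulls)[0]
        assert res.nes == 0.0 and res.p_value == 1.0 and res.fdr_q == 1.0

    def test_identical_sets_share_q(self):
        rng = np.random.default_rng(0)
        null = rng.normal(0, 0.3, 500)
        observed = [EnrichmentResult(n, 0.6, 5) for n in "ABC"]
        res = normalize_and_fdr(observed, {n: null for n in "ABC"})
        qs = {r.fdr_q for r in res}
        assert len(qs) == 1

    def test_q_matches_two_fraction_oracle(self):
        rng = np.random.default_rng(3)
        names = ["S1", "S2", "S3", "S4", "S5"]
        es_values = [0.8, 0.5, -0.6, -0.3, 0.2]
        nulls = {n: rng.normal(0, 0.3, 100) for n in names}
        observed = [EnrichmentResult(n, e, 5) for n, e in zip(names, es_values)]
        res = normalize_and_fdr(observed, nulls)
        # rebuild pooled null NES exactly as the implementation defines it
        pooled = []
        for n in names:
            null = nulls[n]
            pos_mean = null[null > 0].mean()
            neg_mean = np.abs(null[null < 0]).mean()
            scaled = np.where(null > 0, null / pos_mean, null / neg_mean)
            pooled.append(scaled)
        raw_q = brute_force_q([r.nes for r in res], np.concatenate(pooled))
        for r, q in zip(res, raw_q):
            assert r.fdr_q <= q + 1e-12  # monotonization can only lower q
        # the most extreme NES per sign is untouched by monotonization
        for sign in (1, -1):
            idx = [i for i, r in enumerate(res) if np.sign(r.nes) == sign]
            top = max(idx, key=lambda i: abs(res[i].nes))
            assert res[top].fdr_q == pytest.approx(raw_q[top])

    def test_small_null_sample_rejected(self):
        with pytest.raises(ValueError, match="100"):
            normalize_and_fdr([EnrichmentResult("A", 0.5, 5)], {"A": np.ones(50)})


class TestWelchT:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_antisymmetry(self):
        t1, _, p1 = welch_t([1, 2, 3], [2, 4, 9])
        t2, _, p2 = welch_t([2, 4, 9], [1, 2, 3])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_contracts(self):
        t, _, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0
        t, _, p = welch_t([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and p == np.finfo(float).tiny

    def test_group_size_minimum(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])


@pytest.mark.parametrize(
    "p,stars",
    [(0.5, "ns"), (0.033, "ns"), (0.0329, "*"), (0.002, "*"), (0.0019, "**"),
     (0.001, "**"), (0.0009, "***")],
)
def test_nejm_star_thresholds(p, stars):
    assert nejm_stars(p) == stars
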