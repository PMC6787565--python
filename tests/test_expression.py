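"""Expression-profile similarity: Spearman and connectivity statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabolink import (
    PerturbationSignature,
    connectivity_similarity,
    spearman_similarity,
    to_unit_interval,
)
from metabolink.expression import _ks_enrichment, extreme_gene_sets, rank_genes


def sig(values, cid="x", genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return PerturbationSignature(cid, pd.Series(list(values), index=genes, dtype=float))


def spearman_oracle(x, y):
    """Rank both vectors explicitly (average ranks), then Pearson on ranks."""
    rx = pd.Series(x).rank(method="average").to_numpy()
    ry = pd.Series(y).rank(method="average").to_numpy()
    rx, ry = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom) if denom else None


class TestSpearman:
    def test_self_similarity_is_one(self):
        s = sig([3.0, -1.0, 2.0, 0.5])
        assert spearman_similarity(s, s) == pytest.approx(1.0)

    def test_sign_flip_is_minus_one(self):
        s = sig([3.0, -1.0, 2.0, 0.5])
        t = sig([-3.0, 1.0, -2.0, -0.5], cid="y")
        assert spearman_similarity(s, t) == pytest.approx(-1.0)

    def test_hand_computed_three_genes(self):
        # ranks (1,2,3) vs (1,3,2): 1 - 6*2/(3*8) = 0.5
        assert spearman_similarity(sig([1, 2, 3]), sig([1, 3, 2], cid="y")) == pytest.approx(0.5)

    def test_too_few_shared_genes_is_missing(self):
        a = sig([1, 2, 3], genes=["g1", "g2", "g3"])
        b = sig([1, 2, 3], cid="y", genes=["g3", "g4", "g5"])
        assert spearman_similarity(a, b) is None

    def test_constant_vector_is_missing(self):
        assert spearman_similarity(sig([1, 1, 1, 1]), sig([1, 2, 3, 4], cid="y")) is None

    @settings(derandomize=True, max_examples=150)
    @given(
        st.lists(st.integers(min_value=-5, max_value=5), min_size=3, max_size=10),
        st.data(),
    )
    def test_matches_rank_pearson_oracle_with_ties(self, x, data):
        y = data.draw(st.lists(st.integers(min_value=-5, max_value=5),
                               min_size=len(x), max_size=len(x)))
        got = spearman_similarity(sig(x), sig(y, cid="y"))
        expected = spearman_oracle(x, y) if (len(set(x)) > 1 and len(set(y)) > 1) else None
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        assert spearman_similarity(sig(x), sig(y, cid="y")) == pytest.approx(
            spearman_similarity(sig(y, cid="y"), sig(x))
        )


def es_running_sum_oracle(hit_ranks, n):
    """Direct running-sum walk down the ranked list: +1/t on a hit, tracking
    both one-sided deviations of the hit ECDF from the list position CDF."""
    t = len(hit_ranks)
    hits = set(hit_ranks)
    best_pos, best_neg = -np.inf, -np.inf
    j = 0
    for pos in range(1, n + 1):
        if pos in hits:
            before = j / t  # ECDF just before this hit
            j += 1
            best_pos = max(best_pos, j / t - pos / n)
            best_neg = max(best_neg, pos / n - before)
    return best_pos if best_pos > best_neg else -best_neg


class TestConnectivity:
    def test_single_hit_rank_one_n_ten(self):
        assert _ks_enrichment([1], 10) == pytest.approx(0.9)

    @pytest.mark.parametrize("n", [5, 10, 20])
    def test_all_single_hit_placements_match_oracle(self, n):
        for rank in range(1, n + 1):
            assert _ks_enrichment([rank], n) == pytest.approx(
                es_running_sum_oracle([rank], n), abs=1e-12
            )

    def test_random_hit_sets_match_running_sum_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 21))
            t = int(rng.integers(1, n // 2 + 1))
            ranks = sorted(rng.choice(np.arange(1, n + 1), size=t, replace=False).tolist())
            assert _ks_enrichment(ranks, n) == pytest.approx(
                es_running_sum_oracle(ranks, n), abs=1e-12
            )

    def test_self_concordant_query_is_positive(self):
        rng = np.random.default_rng(3)
        b = sig(rng.standard_normal(20), cid="ref")
        assert connectivity_similarity(b, b, top_n=4) > 0

    def test_swapping_up_and_down_sets_negates(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal(20)
        a = sig(vals, cid="a")
        a_flipped = sig(-vals, cid="a_flipped")
        b = sig(rng.standard_normal(20), cid="b")
        assert connectivity_similarity(a, b, top_n=4) == pytest.approx(
            -connectivity_similarity(a_flipped, b, top_n=4)
        )

    def test_symmetrized_score_matches_hand_computation(self):
        # 10 genes; direction-averaging equals the mean of the two directional calls
        rng = np.random.default_rng(5)
        a = sig(rng.standard_normal(10), cid="a")
        b = sig(rng.standard_normal(10), cid="b")
        ab = connectivity_similarity(a, b, top_n=2)
        ba = connectivity_similarity(b, a, top_n=2)
        # recompute ab by hand from the definition
        ranked = rank_genes(b)
        pos = {g: i + 1 for i, g in enumerate(ranked)}
        up, down = extreme_gene_sets(a, 2)
        es_up = es_running_sum_oracle(sorted(pos[g] for g in up), 10)
        es_down = es_running_sum_oracle(sorted(pos[g] for g in down), 10)
        assert ab == pytest.approx((es_up - es_down) / 2)
        # and the same hand computation for the reverse direction
        ranked_a = rank_genes(a)
        pos_a = {g: i + 1 for i, g in enumerate(ranked_a)}
        up_b, down_b = extreme_gene_sets(b, 2)
        es_up_b = es_running_sum_oracle(sorted(pos_a[g] for g in up_b), 10)
        es_down_b = es_running_sum_oracle(sorted(pos_a[g] for g in down_b), 10)
        assert ba == pytest.approx((es_up_b - es_down_b) / 2)

    def test_tie_break_by_gene_id_is_deterministic(self):
        a = sig([1.0, 1.0, 0.0, -1.0, -1.0, 0.5], genes=list("fedcba"), cid="a")
        b = sig([0.2, 0.2, 0.2, 0.1, 0.1, 0.3], genes=list("abcdef"), cid="b")
        assert connectivity_similarity(a, b, top_n=2) == connectivity_similarity(
            a, b, top_n=2
        )

    def test_top_n_validation(self):
        s = sig(range(10))
        with pytest.raises(ValueError):
            connectivity_similarity(s, s, top_n=0)
        with pytest.raises(ValueError):
            connectivity_similarity(s, s, top_n=6)  # > half the shared genes


class TestUnitInterval:
    @pytest.mark.parametrize("s,expected", [(1.0, 1.0), (-1.0, 0.0), (0.5, 0.75), (0.0, 0.5)])
    def test_values(self, s, expected):
        assert to_unit_interval(s) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            to_unit_interval(1.5)
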