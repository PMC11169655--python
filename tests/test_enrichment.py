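"""Median-shift tests, BH adjustment, and the enrichment table."""

import itertools

import numpy as np
import pytest

from leukattr import (
    RANK_SUM,
    SIGNED_RANK,
    EnrichmentConfig,
    bh_adjust,
    enrichment_table,
    median_shift_test,
)
from leukattr.enrichment import stars_for
from leukattr import compute_attribution, ExpressionAtlas


def signed_rank_enumeration_p(diffs):
    """Independent oracle: exact two-sided signed-rank p by enumerating
    all 2^n sign assignments (no ties, no zeros)."""
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0) and len(np.unique(np.abs(d))) == len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mean = n * (n + 1) / 4
    dev_obs = abs(w_obs - mean)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean) >= dev_obs - 1e-12:
            count += 1
    return count / 2**n


class TestSignedRank:
    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        cfg = EnrichmentConfig(test_variant=SIGNED_RANK)
        for _ in range(25):
            n = int(rng.integers(2, 11))
            vals = rng.normal(0.3, 1.0, size=n)
            # center on 0 background median, avoid zeros/ties
            while len(np.unique(np.abs(vals))) < n or np.any(vals == 0):
                vals = rng.normal(0.3, 1.0, size=n)
            p, _ = median_shift_test(vals, [0.0], cfg)
            assert p == pytest.approx(signed_rank_enumeration_p(vals), abs=1e-12)

    def test_n8_fixed_fixture_against_enumeration(self):
        vals = [0.9, -0.2, 0.35, 1.4, -0.75, 0.11, 0.6, 0.27]
        p, _ = median_shift_test(vals, [0.0], EnrichmentConfig(test_variant=SIGNED_RANK))
        assert p == pytest.approx(signed_rank_enumeration_p(vals), abs=1e-12)

    def test_all_zero_differences_give_p_one_direction_none(self):
        p, direction = median_shift_test(
            [0.5, 0.5, 0.5], [0.5, 0.1, 0.9], EnrichmentConfig(test_variant=SIGNED_RANK)
        )
        assert p == 1.0 and direction == "none"

    def test_symmetric_sample_is_nonsignificant(self):
        # values symmetric about the background median
        vals = [0.5 + d for d in (-0.4, -0.3, -0.2, -0.1, 0.1, 0.2, 0.3, 0.4)]
        p, _ = median_shift_test(vals, [0.5], EnrichmentConfig(test_variant=SIGNED_RANK))
        assert p > 0.9

    def test_ties_fall_back_to_normal_approximation(self):
        # tied absolute differences: still returns a valid p
        vals = [0.6, 0.6, 0.4, 0.4, 0.7, 0.3, 0.8, 0.9]
        p, direction = median_shift_test(
            vals, [0.5], EnrichmentConfig(test_variant=SIGNED_RANK)
        )
        assert 0.0 < p <= 1.0 and direction == "elevated"


def test_signed_rank_anticonservative_on_skewed_background():
    """Known property: the signed-rank variant tests symmetry about the
    background median, so on a skewed (Beta-like) background its
    rejection rate on random gene sets exceeds alpha, while the
    rank-sum variant stays near it."""
    rng = np.random.default_rng(77)
    bg = rng.beta(1, 17, size=2000)
    sr = EnrichmentConfig(test_variant=SIGNED_RANK)
    rs = EnrichmentConfig(test_variant=RANK_SUM)
    rej_sr = rej_rs = 0
    n_draws = 200
    for _ in range(n_draws):
        s = bg[rng.choice(2000, 20, replace=False)]
        rej_sr += median_shift_test(s, bg, sr)[0] <= 0.05
        rej_rs += median_shift_test(s, bg, rs)[0] <= 0.05
    assert rej_sr / n_draws > 0.07  # inflated well above alpha
    assert rej_rs / n_draws < 0.09  # near alpha


class TestRankSum:
    def test_swap_flips_direction_preserves_p(self):
        rng = np.random.default_rng(1)
        a = rng.beta(2, 8, size=30)
        b = rng.beta(5, 5, size=200)
        cfg = EnrichmentConfig(test_variant=RANK_SUM)
        p1, d1 = median_shift_test(a, b, cfg)
        p2, d2 = median_shift_test(b, a, cfg)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert {d1, d2} == {"elevated", "depleted"}

    def test_strong_shift_reaches_tiny_p(self):
        rng = np.random.default_rng(2)
        bg = rng.beta(1, 17, size=2000)
        high = rng.beta(40, 10, size=20)
        p, d = median_shift_test(high, bg, EnrichmentConfig(test_variant=RANK_SUM))
        assert d == "elevated" and p < 1e-10  # beyond any n=20 signed-rank floor


class TestBHAdjust:
    # expected values frozen from a hand application of the step-up rule
    CASES = [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.5], [0.5]),
        ([0.2, 0.2, 0.2, 0.2], [0.2, 0.2, 0.2, 0.2]),
        ([0.001, 0.5, 0.9], [0.003, 0.75, 0.9]),
        ([0.04, 0.01, 0.03, 0.005], [0.04, 0.02, 0.04, 0.02]),
        ([0.9, 0.8, 0.7, 0.6, 0.5], [0.9, 0.9, 0.9, 0.9, 0.9]),
        ([0.0, 0.05, 1.0], [0.0, 0.075, 1.0]),
        ([0.03, 0.003, 0.0003, 0.3], [0.04, 0.006, 0.0012, 0.3]),
        (
            [0.02, 0.04, 0.06, 0.08, 0.1, 0.12],
            [0.12, 0.12, 0.12, 0.12, 0.12, 0.12],
        ),
        ([0.05, 0.05, 0.049, 0.051], [0.051, 0.051, 0.051, 0.051]),
    ]

    @pytest.mark.parametrize("p, expected", CASES)
    def test_step_up_fixtures(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=12)
        perm = rng.permutation(12)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-15)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=30)
        assert np.all(bh_adjust(p) >= p - 1e-15)


@pytest.mark.parametrize(
    "p, expected",
    [(0.0005, "***"), (0.001, "***"), (0.005, "**"), (0.03, "*"), (0.2, "")],
)
def test_significance_stars(p, expected):
    assert stars_for(p) == expected


class TestEnrichmentTable:
    def _attr(self, seed=0, n=300, m=5):
        rng = np.random.default_rng(seed)
        values = rng.dirichlet(np.ones(m), size=n) * rng.lognormal(3, 1, n)[:, None]
        atlas = ExpressionAtlas(
            gene_ids=[f"G{i}" for i in range(n)],
            gene_symbols=[f"S{i}" for i in range(n)],
            cell_types=[f"C{j}" for j in range(m)],
            values=values,
        )
        return compute_attribution(atlas)

    def test_whole_genome_set_is_null(self):
        # set == background: identical samples, so the two-sample
        # variant must be maximally nonsignificant
        attr = self._attr()
        cfg = EnrichmentConfig(test_variant=RANK_SUM)
        table = enrichment_table(attr, range(attr.n_genes), cfg)
        for row in table.rows:
            assert row.set_median_pct == pytest.approx(row.background_median_pct)
            assert row.p_raw > 0.9
            assert row.direction == "none"

    def test_one_row_per_cell_type_and_padj_monotone(self):
        attr = self._attr(seed=1)
        table = enrichment_table(attr, range(0, 40))
        assert sorted(r.cell_type for r in table.rows) == sorted(attr.cell_types)
        for row in table.rows:
            assert row.p_adjusted >= row.p_raw - 1e-15
            assert row.stars == stars_for(row.p_adjusted)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enrichment_table(self._attr(), [])

    def test_out_of_range_indices_rejected(self):
        with pytest.raises(ValueError):
            enrichment_table(self._attr(), [10**6])
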