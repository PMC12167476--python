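"""Normalization, fold change, Mann-Whitney, NTC null, and gene scoring."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lncscreen.library_model import GuideRecord, LibraryDesign
from lncscreen.quantify import CountTable
from lncscreen.score import (
    GeneScore,
    NormalizationError,
    NtcNull,
    NullModelError,
    build_ntc_null,
    guide_lfc,
    mann_whitney_gene,
    median_normalize,
    rank_hits,
    score_gene,
    score_screen,
)


def _table(counts, samples, reference, guide_ids=None):
    counts = np.asarray(counts)
    gids = guide_ids or [f"g{i}" for i in range(counts.shape[0])]
    return CountTable(gids, list(samples), counts, reference)


class TestMedianNormalize:
    def test_forced_example(self):
        # sample median 30, reference median 60 -> scale 2
        t = _table(np.column_stack([[10, 20, 30, 40, 100], [40, 50, 60, 70, 80]]),
                   ["day21", "plasmid"], "plasmid")
        norm = median_normalize(t)
        assert norm.normalized_column("day21").tolist() == [20, 40, 60, 80, 200]
        assert norm.normalized_column("plasmid").tolist() == [40, 50, 60, 70, 80]

    def test_sample_identical_to_reference_unchanged(self):
        col = [5, 10, 15, 20, 25]
        t = _table(np.column_stack([col, col]), ["day21", "plasmid"], "plasmid")
        norm = median_normalize(t)
        assert norm.normalized_column("day21").tolist() == col

    def test_zero_median_names_sample(self):
        t = _table(np.column_stack([[0, 0, 0, 5, 9], [1, 2, 3, 4, 5]]),
                   ["day21", "plasmid"], "plasmid")
        with pytest.raises(NormalizationError, match="day21"):
            median_normalize(t)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(counts=st.lists(st.integers(1, 500), min_size=3, max_size=20),
           factor=st.sampled_from([2, 10, 1000]))
    def test_scale_invariance_bitwise(self, counts, factor):
        """Scaling a sample's raw counts leaves its normalized values
        bit-identical."""
        ref = list(range(1, len(counts) + 1))
        t1 = _table(np.column_stack([counts, ref]), ["day21", "plasmid"], "plasmid")
        t2 = _table(np.column_stack([np.array(counts) * factor, ref]),
                    ["day21", "plasmid"], "plasmid")
        a = median_normalize(t1).normalized_column("day21")
        b = median_normalize(t2).normalized_column("day21")
        assert (a == b).all()


class TestGuideLfc:
    def _norm(self, end, ref_norm, ref_raw=None):
        raw = np.column_stack([end, ref_norm if ref_raw is None else ref_raw]).astype(int)
        t = _table(raw, ["day21", "plasmid"], "plasmid")
        return median_normalize(t)

    def test_forced_values(self):
        # medians of both columns are 10 -> normalization is the identity,
        # so the lfc formula is exercised directly
        end = [63, 9, 0, 10, 1000]
        ref = [15, 9, 1023, 10, 2]
        norm = self._norm(end, ref)
        phen = guide_lfc(norm, "day21", pseudocount=1.0, min_reference_count=0)
        lfcs = [p.lfc for p in phen]
        assert lfcs[0] == pytest.approx(2.0)  # log2(64/16)
        assert lfcs[1] == 0.0
        assert lfcs[2] == -10.0  # log2(1/1024)

    def test_reference_count_filter(self):
        norm = self._norm([50, 50], [100, 5])
        phen = guide_lfc(norm, "day21", min_reference_count=10)
        assert [p.passed_filter for p in phen] == [True, False]

    def test_unknown_endpoint_and_endpoint_equals_reference(self):
        norm = self._norm([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="unknown endpoint"):
            guide_lfc(norm, "day99")
        with pytest.raises(ValueError, match="differ"):
            guide_lfc(norm, "plasmid")


# ---------------------------------------------------------------------------
# Mann-Whitney: frozen examples + independent brute-force oracle
# ---------------------------------------------------------------------------


def oracle_mann_whitney(x, y):
    """Brute-force permutation Mann-Whitney: U by pairwise comparison,
    two-sided p by enumerating every assignment of pooled values."""
    pooled = np.concatenate([x, y])
    n, N = len(x), len(pooled)
    m = N - n
    gt = (pooled[:, None] > pooled[None, :]).astype(float)
    gt += 0.5 * (pooled[:, None] == pooled[None, :])

    def u_of(idx):
        rest = tuple(i for i in range(N) if i not in idx)
        return gt[np.ix_(idx, rest)].sum()

    u_obs = u_of(tuple(range(n)))
    d_obs = abs(u_obs - n * m / 2) - 1e-9
    hits = total = 0
    for idx in itertools.combinations(range(N), n):
        total += 1
        if abs(u_of(idx) - n * m / 2) >= d_obs:
            hits += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_disjoint_groups_exact(self):
        u, p = mann_whitney_gene([1, 2, 3], [4, 5, 6])
        assert u == 0.0 and p == pytest.approx(2 / 20)

    def test_three_vs_five_all_below(self):
        u, p = mann_whitney_gene([-2.0, -1.8, -1.5], [0.1, -0.1, 0.2, 0.0, -0.05])
        assert u == 0.0 and p == pytest.approx(2 / 56)

    def test_label_swap_symmetry(self):
        x = [0.3, -1.2, 0.8, 0.1]
        y = [0.0, 0.5, -0.4, 0.9, 1.1]
        _, p1 = mann_whitney_gene(x, y)
        _, p2 = mann_whitney_gene(y, x)
        assert p1 == pytest.approx(p2)

    def test_exact_matches_oracle_with_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 7))
            m = int(rng.integers(2, 7))
            # one decimal place forces ties regularly
            x = np.round(rng.normal(size=n), 1)
            y = np.round(rng.normal(size=m), 1)
            u, p = mann_whitney_gene(x, y)
            u_o, p_o = oracle_mann_whitney(x, y)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            u, p = mann_whitney_gene(x, y)
            u_s, p_s = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(float(u_s))
            assert p == pytest.approx(float(p_s))

    def test_large_groups_use_normal_approximation(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=200)
        u, p = mann_whitney_gene(x, y)
        u_s, p_s = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(float(u_s)) and p == pytest.approx(float(p_s))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_gene([1.0], [1, 2, 3])


# ---------------------------------------------------------------------------
# NTC pseudo-gene null
# ---------------------------------------------------------------------------


class TestBuildNtcNull:
    def test_degenerate_ntcs_error(self):
        with pytest.raises(NullModelError, match="sigma"):
            build_ntc_null([0.5] * 50, pseudo_gene_size=10, k=3, n_resamples=200, seed=1)

    def test_seeded_determinism(self):
        ntc = np.random.default_rng(0).normal(size=300)
        a = build_ntc_null(ntc, seed=42)
        b = build_ntc_null(ntc, seed=42)
        assert a.mu == b.mu and a.sigma == b.sigma
        assert (a.pseudo_gene_scores == b.pseudo_gene_scores).all()

    def test_preconditions(self):
        with pytest.raises(ValueError, match="pseudo_gene_size"):
            build_ntc_null([0.1, 0.2], pseudo_gene_size=10)
        with pytest.raises(ValueError, match="n_resamples"):
            build_ntc_null(np.arange(50.0), n_resamples=10)
        with pytest.raises(ValueError, match="k"):
            build_ntc_null(np.arange(50.0), pseudo_gene_size=5, k=6)

    def test_mu_matches_monte_carlo_oracle(self):
        """mu of the implementation (1e4 resamples) agrees with a large
        independent Monte-Carlo re-derivation on the same NTC pool."""
        ntc = np.random.default_rng(7).normal(size=700)
        null = build_ntc_null(ntc, pseudo_gene_size=10, k=3, n_resamples=10_000, seed=5)
        oracle_rng = np.random.default_rng(987_654)
        scores = []
        remaining = 200_000
        while remaining > 0:
            chunk = min(20_000, remaining)
            order = np.argsort(oracle_rng.random((chunk, ntc.size)), axis=1)[:, :10]
            draws = np.sort(ntc[order], axis=1)
            med = 0.5 * (draws[:, 4] + draws[:, 5])
            s = np.where(med > 0, draws[:, -3:].mean(axis=1), draws[:, :3].mean(axis=1))
            scores.append(s)
            remaining -= chunk
        oracle_mu = float(np.concatenate(scores).mean())
        assert null.mu == pytest.approx(oracle_mu, abs=0.05)


# ---------------------------------------------------------------------------
# gene scoring and ranking
# ---------------------------------------------------------------------------


def _null(mu=0.0, sigma=0.5, k=3):
    return NtcNull(pseudo_gene_scores=np.zeros(100), mu=mu, sigma=sigma, k=k,
                   pseudo_gene_size=10, n_resamples=100, seed=0)


NTC = [0.1, -0.1, 0.2, 0.0, -0.05, 0.15, -0.2, 0.05]


class TestScoreGene:
    def test_z_from_topk_and_null(self):
        s = score_gene([-1.5, -1.5, -1.5, 0.0], _null(mu=0.0, sigma=0.5), NTC, gene_id="G")
        assert s.topk_mean_lfc == pytest.approx(-1.5)
        assert s.z == pytest.approx(-3.0)
        assert s.hit_class == "none"  # threshold is strict: z < -3

    @pytest.mark.parametrize(
    "lfcs,expected",
        [
            ([-1.75, -1.75, -1.75, 0.0], "positive_regulator"),  # z = -3.5
            ([1.6, 1.6, 1.6, 0.0], "negative_regulator"),        # z = +3.2
            ([-1.45, -1.45, -1.45, 0.0], "none"),                # z = -2.9
        ],
    )
    def test_hit_classes_at_z_boundaries(self, lfcs, expected):
        s = score_gene(lfcs, _null(mu=0.0, sigma=0.5), NTC)
        assert s.hit_class == expected

    def test_direction_tie_defaults_to_dropout(self):
        # median exactly 0: the dropout direction is scored
        s = score_gene([-2.0, -1.0, 0.0, 0.0, 1.0, 2.0], _null(), NTC)
        assert s.direction == -1
        assert s.topk_mean_lfc == pytest.approx((-2.0 - 1.0 + 0.0) / 3)

    def test_topk_uses_dominant_direction_not_abs(self):
        # median positive: top-3 are the largest, the -5 outlier is ignored
        s = score_gene([-5.0, 1.0, 1.2, 1.4, 1.6], _null(), NTC)
        assert s.direction == 1
        assert s.topk_mean_lfc == pytest.approx(np.mean([1.2, 1.4, 1.6]))
        assert s.topk_guide_lfcs == (1.6, 1.4, 1.2)

    def test_too_few_guides_rejected(self):
        with pytest.raises(ValueError, match="usable guides"):
            score_gene([-1.0, -2.0], _null(k=3), NTC)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(lfcs=st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=12),
           delta=st.floats(0.01, 2.0))
    def test_monotonicity_in_guide_lfcs(self, lfcs, delta):
        """Decreasing every guide lfc strictly decreases topk_mean_lfc and z."""
        null = _null()
        a = score_gene(lfcs, null, NTC)
        b = score_gene([v - delta for v in lfcs], null, NTC)
        assert b.topk_mean_lfc < a.topk_mean_lfc
        assert b.z < a.z


class TestRankHits:
    def _score(self, gene, z, p=0.01, hit="positive_regulator"):
        return GeneScore(gene_id=gene, n_guides_used=10, direction=-1 if z < 0 else 1,
                         topk_mean_lfc=z, z=z, u_stat=0.0, p_value=p, hit_class=hit)

    def test_threshold_and_sort(self):
        scores = [self._score("a", -5.0), self._score("b", -3.5),
                  self._score("c", -2.0, hit="none")]
        ranked = rank_hits(scores, "dropout")
        assert [s.gene_id for s in ranked] == ["a", "b"]

    def test_empty(self):
        assert rank_hits([], "dropout") == []

    def test_tie_break_by_p_then_gene_id(self):
        scores = [self._score("b", -4.0, p=0.02), self._score("a", -4.0, p=0.01),
                  self._score("c", -4.0, p=0.01)]
        assert [s.gene_id for s in rank_hits(scores, "dropout")] == ["a", "c", "b"]

    def test_enrichment_direction(self):
        scores = [self._score("up1", 4.0, hit="negative_regulator"),
                  self._score("up2", 5.0, hit="negative_regulator"),
                  self._score("dn", -4.0)]
        assert [s.gene_id for s in rank_hits(scores, "enrichment")] == ["up2", "up1"]


class TestScoreScreen:
    def test_deterministic_and_unscored_bookkeeping(self, small_library, neutral_screen):
        table, _, _ = neutral_screen
        r1 = score_screen(table, small_library, "day21", n_resamples=500, seed=9)
        r2 = score_screen(table, small_library, "day21", n_resamples=500, seed=9)
        assert r1.scores_frame().equals(r2.scores_frame())
        # 12 lnc genes + 1 positive-control gene scored or unscored, nothing lost
        assert len(r1.gene_scores) + len(r1.unscored_genes) == 13
        assert all(s.bh_q >= s.p_value or math.isclose(s.bh_q, s.p_value)
                   for s in r1.gene_scores)

    def test_guide_set_mismatch_rejected(self, small_library, neutral_screen):
        table, _, _ = neutral_screen
        other = LibraryDesign([GuideRecord("x", "A" * 19 + "C", "non_targeting")])
        with pytest.raises(ValueError, match="match the library"):
            score_screen(table, other, "day21")
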