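import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import esdeg
from esdeg.calibration import calibrate_thresholds, err_grid
from esdeg.enrichment import (
    EnrichmentResult,
    bh_adjust,
    enrich_collection,
    hartung_combine,
    level_stats_from_frequencies,
    mc_enrichment,
    rank_motifs,
    results_table,
    site_frequency,
)
from esdeg.motifs import pcm_to_pwm
from esdeg.synthetic import (
    SimulationConfig,
    plant_sites,
    random_pcm,
    simulate_promoters,
    simulate_study,
)


def hartung_oracle(p, kappa=0.2):
    """Straight-from-the-formula transliteration, independent of the library path."""
    t = [norm.ppf(min(max(pi, 1e-300), 1 - 1e-16)) for pi in p]
    L = len(t)
    tbar = sum(t) / L
    rho = 1 - sum((ti - tbar) ** 2 for ti in t) / (L - 1)
    rho_star = max(-1 / (L - 1), rho)
    q = rho_star + kappa * math.sqrt(2 / (L + 1)) * (1 - rho_star)
    return float(norm.cdf(sum(t) / math.sqrt(L + (L * L - L) * q)))


class TestHartung:
    def test_equal_p_is_fixed_point(self):
        for p in (0.001, 0.07, 0.5, 0.93):
            assert hartung_combine([p] * 30) == pytest.approx(p, abs=1e-12)

    def test_single_p_returned_as_is(self):
        assert hartung_combine([0.07]) == 0.07

    def test_matches_formula_oracle(self):
        vec = [0.01, 0.04, 0.10, 0.20, 0.50]
        assert hartung_combine(vec) == pytest.approx(hartung_oracle(vec), abs=1e-12)
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = rng.uniform(1e-6, 1 - 1e-6, size=rng.integers(2, 40)).tolist()
            assert hartung_combine(p) == pytest.approx(hartung_oracle(p), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(1e-6, 1 - 1e-6), min_size=2, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariant(self, p, rnd):
        shuffled = p.copy()
        rnd.shuffle(shuffled)
        assert hartung_combine(p) == pytest.approx(hartung_combine(shuffled), rel=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            hartung_combine([0.5, 0.0])
        with pytest.raises(ValueError):
            hartung_combine([0.5, 1.5])
        with pytest.raises(ValueError):
            hartung_combine([])

    def test_extreme_p_handled_after_clamping(self):
        assert 0 < hartung_combine([1e-310] * 5 + [1.0] * 5) <= 1


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        np.testing.assert_allclose(bh_adjust([0.005, 0.10]), [0.01, 0.10])

    def test_order_independent_and_capped(self):
        p = [0.9, 0.004, 0.03, 0.9]
        adj = bh_adjust(p)
        assert adj[1] == pytest.approx(0.016)
        assert np.all(adj <= 1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.uniform(1e-8, 1, size=25)
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)


class TestSiteFrequency:
    def test_zero_above_max_score(self, consensus_pwm, small_universe):
        sub = small_universe.subset(small_universe.gene_ids[:10])
        assert site_frequency(consensus_pwm, sub, consensus_pwm.max_score + 1) == 0.0

    def test_counting_fraction(self, consensus_pwm, promoter_factory):
        from esdeg.promoters import PromoterSet

        with_site = ["T" * 10 + "ACGTGA" + "T" * 10] * 3
        without = ["T" * 26]
        pset = PromoterSet(
            [promoter_factory(f"g{i}", s) for i, s in enumerate(with_site + without)]
        )
        freq = site_frequency(consensus_pwm, pset, consensus_pwm.max_score - 1e-9)
        assert freq == pytest.approx(0.75)

    def test_planted_consensus_rate_recovered(self, consensus_pcm, consensus_pwm):
        config = SimulationConfig(n_genes=20, promoter_length=60, seed=3)
        promoters = simulate_promoters(config)
        target = promoters.gene_ids[:12]
        planted, truth = plant_sites(promoters, consensus_pcm, 1.0, seed=8, gene_ids=target)
        assert len(truth) == 12
        threshold = consensus_pwm.max_score - 3.0  # consensus-ish sites only
        freq = site_frequency(consensus_pwm, planted, threshold)
        assert freq >= 0.60  # all planted plus possible chance hits

    def test_per_window_mode_counts_hits(self, consensus_pwm, promoter_factory):
        from esdeg.promoters import PromoterSet

        pset = PromoterSet([promoter_factory("g", "T" * 10 + "ACGTGA" + "T" * 10)])
        freq = site_frequency(
            consensus_pwm, pset, consensus_pwm.max_score - 1e-9, frequency="per_window"
        )
        assert freq == pytest.approx(1 / (2 * 21))


class TestLevelStats:
    def test_normal_tail_arithmetic(self):
        back = 0.3 + 0.1 * np.array([-1.0, 1.0]) / np.std([-1.0, 1.0], ddof=1)
        stats = level_stats_from_frequencies(
            np.array([0.5]), back[:, None], np.array([5e-4]), np.array([1.0])
        )
        assert stats[0].z == pytest.approx(2.0)
        assert stats[0].p == pytest.approx(1 - norm.cdf(2.0), abs=1e-6)
        assert stats[0].p == pytest.approx(0.02275, abs=1e-5)

    def test_equal_foreground_and_background_gives_half(self):
        back = np.array([[0.2], [0.4]])
        stats = level_stats_from_frequencies(
            np.array([0.3]), back, np.array([5e-4]), np.array([1.0])
        )
        assert stats[0].z == pytest.approx(0.0)
        assert stats[0].p == pytest.approx(0.5)

    def test_zero_spread_fallbacks(self, caplog):
        back = np.zeros((10, 1))
        with caplog.at_level("WARNING"):
            below = level_stats_from_frequencies(
                np.array([0.0]), back, np.array([5e-4]), np.array([1.0])
            )
            above = level_stats_from_frequencies(
                np.array([0.4]), back, np.array([5e-4]), np.array([1.0])
            )
        assert below[0].p == 1.0
        assert above[0].p == pytest.approx(1 / 11)


@pytest.fixture(scope="module")
def null_setup():
    config = SimulationConfig(n_genes=120, promoter_length=300, seed=21)
    promoters = simulate_promoters(config)
    pwm = pcm_to_pwm(random_pcm("NULLM", 8, seed=44, concentration=0.3))
    table = calibrate_thresholds(pwm, promoters, err_grid(n_levels=10))
    return promoters, pwm, table


class TestMCEnrichment:
    def test_null_z_centered_near_zero(self, null_setup):
        promoters, pwm, table = null_setup
        ids = promoters.gene_ids
        means = []
        for rep in range(30):
            rng = np.random.default_rng(1000 + rep)
            fg = list(rng.choice(ids, 15, replace=False))
            pool = [g for g in ids if g not in set(fg)]
            stats = mc_enrichment(
                pwm, fg, pool, promoters, table, n_resamples=150, seed=rep
            )
            finite = [s.z for s in stats if np.isfinite(s.z)]
            means.append(np.mean(finite))
        assert abs(np.mean(means)) < 3 / math.sqrt(len(means))

    def test_deterministic_given_seed(self, null_setup):
        promoters, pwm, table = null_setup
        ids = promoters.gene_ids
        fg, pool = ids[:15], ids[15:]
        a = mc_enrichment(pwm, fg, pool, promoters, table, n_resamples=100, seed=9)
        b = mc_enrichment(pwm, fg, pool, promoters, table, n_resamples=100, seed=9)
        assert a == b

    def test_pool_smaller_than_foreground_rejected(self, null_setup):
        promoters, pwm, table = null_setup
        ids = promoters.gene_ids
        with pytest.raises(ValueError, match="smaller"):
            mc_enrichment(pwm, ids[:50], ids[50:60], promoters, table, 100, 0)


class TestRankMotifs:
    @staticmethod
    def result(motif_id, unified_p, p_adj):
        return EnrichmentResult(motif_id=motif_id, level_stats=[], unified_p=unified_p, p_adj=p_adj)

    def test_ranks_follow_p_adj(self):
        ranked = rank_motifs(
            [self.result("B", 0.01, 0.01), self.result("A", 0.001, 0.001)]
        )
        assert [(r.rank, r.motif_id) for r in ranked] == [(1, "A"), (2, "B")]

    def test_ties_broken_lexicographically(self):
        ranked = rank_motifs(
            [self.result("Z", 0.01, 0.05), self.result("A", 0.01, 0.05)]
        )
        assert [r.motif_id for r in ranked] == ["A", "Z"]

    def test_report_threshold_filters_table(self):
        ranked = rank_motifs(
            [self.result("A", 0.001, 0.004), self.result("B", 0.2, 0.4)]
        )
        table = results_table(ranked, report_threshold=0.05)
        assert table.motif_id.tolist() == ["A"]
        full = results_table(ranked, report_threshold=None)
        assert full.motif_id.tolist() == ["A", "B"]


class TestEndToEnd:
    def test_planting_rate_monotonicity(self):
        planted_pcm = random_pcm("PL", 10, seed=99, concentration=0.1)
        unified = []
        for rate in (0.2, 0.8):
            config = SimulationConfig(
                n_genes=150,
                promoter_length=400,
                n_foreground=15,
                planting_rate_fg=rate,
                seed=31,
            )
            study = simulate_study(config, motif=planted_pcm)
            pool = study.promoters.gene_ids[15:]
            results = enrich_collection(
                [pcm_to_pwm(planted_pcm)],
                study.foreground_ids,
                pool,
                study.promoters,
                errs=err_grid(n_levels=10),
                n_resamples=200,
                seed=12,
            )
            unified.append(results[0].unified_p)
        assert unified[1] <= unified[0]

    def test_collection_deterministic_and_ranked(self):
        config = SimulationConfig(n_genes=80, promoter_length=300, n_foreground=10, seed=6)
        study = simulate_study(config)
        pwms = [pcm_to_pwm(random_pcm(f"M{i}", 8, seed=i, concentration=0.3)) for i in range(5)]
        pool = study.promoters.gene_ids[10:]
        kwargs = dict(errs=err_grid(n_levels=8), n_resamples=100, seed=42)
        a = enrich_collection(pwms, study.foreground_ids, pool, study.promoters, **kwargs)
        b = enrich_collection(pwms, study.foreground_ids, pool, study.promoters, **kwargs)
        assert [(r.motif_id, r.unified_p, r.p_adj) for r in a] == [
            (r.motif_id, r.unified_p, r.p_adj) for r in b
        ]
        assert [r.rank for r in a] == list(range(1, 6))
        assert all(x.p_adj >= x.unified_p - 1e-15 for x in a)

    def test_frequency_modes_both_run(self):
        config = SimulationConfig(n_genes=60, promoter_length=300, n_foreground=8, seed=2)
        study = simulate_study(config)
        pwm = pcm_to_pwm(random_pcm("M", 8, seed=3, concentration=0.3))
        pool = study.promoters.gene_ids[8:]
        for mode in ("promoter", "per_window"):
            results = enrich_collection(
                [pwm],
                study.foreground_ids,
                pool,
                study.promoters,
                errs=err_grid(n_levels=5),
                n_resamples=100,
                seed=1,
                frequency=mode,
            )
            assert 0 < results[0].unified_p <= 1
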