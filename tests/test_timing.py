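"""Global curve, local-extent standardisation and the cumulative-normal fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from replitime.binning import BinnedGenome
from replitime.enrichment import EnrichmentTrack
from replitime.timing import (
    STATUS_CONVERGED,
    STATUS_FALLBACK,
    STATUS_MASKED,
    GlobalReplicationCurve,
    LocalExtentSeries,
    ReplicationTimingModel,
    compare_conditions,
    global_curve_from_dotblot,
    local_extent,
    profile_at_matched_g,
)


class TestGlobalCurve:
    def test_ratio_to_reference(self, tmp_path):
        p = tmp_path / "blot.csv"
        pd.DataFrame(
            {"timepoint_min": [60, 90, 150], "signal": [10.0, 50.0, 100.0]}
        ).to_csv(p, index=False)
        curve = global_curve_from_dotblot(str(p))
        np.testing.assert_allclose(curve.g, [0.1, 0.5, 1.0])
        assert curve.t_ref == 150

    def test_equal_signals_both_unity(self):
        curve = GlobalReplicationCurve([60, 150], [100.0, 100.0], t_ref=150)
        np.testing.assert_allclose(curve.g, [1.0, 1.0])

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError, match="positive"):
            GlobalReplicationCurve([60, 150], [10.0, 0.0], t_ref=150)

    def test_non_monotone_warns_not_fails(self):
        with pytest.warns(UserWarning, match="non-monotone"):
            GlobalReplicationCurve([10, 20, 150], [50.0, 40.0, 100.0], t_ref=150)

    def test_simulated_dotblot_matches_truth(self, two_origin_config):
        from replitime import simulate as sim

        truth = sim.compute_truth(two_origin_config)
        _, df = sim.emit_global_curve(truth, two_origin_config, noise_sd=0.02)
        curve = global_curve_from_dotblot(df)
        g_true = truth.g_of_t() / truth.g_of_t()[-1]
        np.testing.assert_allclose(curve.g, g_true, rtol=0.1)


def _series(genome, timepoints, lprime, t_last):
    return LocalExtentSeries(genome, np.asarray(timepoints, float),
                             np.asarray(lprime, float), t_last)


class TestLocalExtent:
    def test_unit_enrichment_gives_g_ratio(self):
        genome = BinnedGenome([("c", 1500)], 300)
        curve = GlobalReplicationCurve([50, 100, 150], [25.0, 50.0, 100.0], 150)
        tracks = {
            t: EnrichmentTrack(genome, np.ones(5), stage="Eprime", timepoint=t)
            for t in (50.0, 100.0, 150.0)
        }
        series = local_extent(tracks, curve, 150.0)
        np.testing.assert_allclose(series.lprime[0], 0.25)
        np.testing.assert_allclose(series.lprime[1], 0.5)
        np.testing.assert_allclose(series.lprime[2], 1.0)

    def test_zero_final_extent_masks_bin(self):
        genome = BinnedGenome([("c", 600)], 300)
        curve = GlobalReplicationCurve([50, 150], [50.0, 100.0], 150)
        v_last = np.array([1.0, 0.0])
        tracks = {
            50.0: EnrichmentTrack(genome, np.ones(2), timepoint=50.0),
            150.0: EnrichmentTrack(genome, v_last, timepoint=150.0),
        }
        series = local_extent(tracks, curve, 150.0)
        assert np.isnan(series.lprime[:, 1]).all()
        assert not np.isnan(series.lprime[:, 0]).any()

    def test_tracks_truth_ratio_in_simulation(self, two_origin_config):
        from dataclasses import replace

        from replitime import simulate as sim
        from replitime.enrichment import enrichment_chain

        cfg = replace(two_origin_config, ip_depth=100.0)
        truth = sim.compute_truth(cfg)
        tracks, inp = sim.emit_count_tracks(cfg, truth)
        curve, _ = sim.emit_global_curve(truth)
        ep = {t: enrichment_chain(tr, inp, None) for t, tr in tracks.items()}
        series = local_extent(ep, curve, 150.0)
        i = 2  # t = 40 min, mid-S
        truth_ratio = truth.r[i] / truth.r[-1]
        ok = ~np.isnan(series.lprime[i])
        r = np.corrcoef(series.lprime[i][ok], truth_ratio[ok])[0, 1]
        assert r > 0.9


def exact_model_series(mu=0.5, sigma=0.1, n_bins=10):
    g = np.array([0.3, 0.4, 0.5, 0.6, 0.7])
    genome = BinnedGenome([("c", 300 * n_bins)], 300)
    ts = np.array([70.0, 75.0, 80.0, 85.0, 90.0, 160.0])
    curve = GlobalReplicationCurve(ts, np.append(g, 1.0) * 100, t_ref=160.0)
    y = ndtr((g[:, None] - mu) / sigma) * np.ones((5, n_bins))
    lp = np.vstack([y, np.ones((1, n_bins))])
    return _series(genome, ts, lp, 160.0), curve


class TestTimingFit:
    def test_noiseless_exact_recovery(self):
        series, curve = exact_model_series(0.5, 0.1)
        res = ReplicationTimingModel(series, curve).fit()
        assert np.abs(res.mu - 0.5).max() < 1e-4
        assert np.abs(res.sigma - 0.1).max() < 1e-4
        assert (res.status == STATUS_CONVERGED).all()

    def test_constant_one_falls_back_with_f_near_one(self):
        series, curve = exact_model_series()
        series.lprime[:] = 1.0
        res = ReplicationTimingModel(series, curve).fit()
        assert (res.status == STATUS_FALLBACK).all()
        f = res.evaluate_extent([0.25, 0.5, 0.75])
        np.testing.assert_allclose(f, 1.0, atol=1e-9)

    def test_too_few_points_masked(self):
        series, curve = exact_model_series()
        series.lprime[:3, 0] = np.nan  # only 2 fit points left at bin 0
        res = ReplicationTimingModel(series, curve).fit()
        assert res.status[0] == STATUS_MASKED
        assert np.isnan(res.mu[0])
        assert res.status[1] == STATUS_CONVERGED

    def test_f_monotone_in_g_everywhere(self):
        rng = np.random.default_rng(8)
        series, curve = exact_model_series(n_bins=50)
        series.lprime[:5] = np.clip(
            series.lprime[:5] + rng.normal(0, 0.15, size=(5, 50)), 0, 1.2
        )
        res = ReplicationTimingModel(series, curve).fit()
        grid = np.linspace(0.0, 1.0, 21)
        f = res.evaluate_extent(grid)
        assert np.all(np.diff(f, axis=0) >= -1e-12)
        assert f.min() >= 0.0 and f.max() <= 1.0

    def test_matches_scipy_curve_fit_oracle(self):
        """Dual route: the vectorised fitter agrees with scipy.curve_fit."""
        from scipy.optimize import curve_fit

        rng = np.random.default_rng(21)
        series, curve = exact_model_series(n_bins=30)
        g = np.array([0.3, 0.4, 0.5, 0.6, 0.7])
        mus = rng.uniform(0.3, 0.7, 30)
        sigmas = rng.uniform(0.05, 0.3, 30)
        y = ndtr((g[:, None] - mus) / sigmas)
        y = np.clip(y + rng.normal(0, 0.03, size=y.shape), 0, 1.2)
        series.lprime[:5] = y
        res = ReplicationTimingModel(series, curve).fit()

        def model(gv, mu, sigma):
            return ndtr((gv - mu) / sigma)

        for b in range(30):
            popt, _ = curve_fit(
                model, g, y[:, b], p0=[0.5, 0.2],
                bounds=([-0.25, 0.01], [1.5, 1.0]), maxfev=10_000,
            )
            sse_ref = ((model(g, *popt) - y[:, b]) ** 2).sum()
            assert res.sse[b] <= sse_ref + 1e-6

    def test_fit_timepoint_not_in_series_raises(self):
        series, curve = exact_model_series()
        with pytest.raises(ValueError, match="not in series"):
            ReplicationTimingModel(series, curve, [70.0, 75.0, 99.0])

    def test_summary_mentions_status_counts(self):
        series, curve = exact_model_series()
        res = ReplicationTimingModel(series, curve).fit()
        s = res.summary()
        assert "converged: 10" in s and "cumulative normal" in s

    def test_to_frame_has_model_columns(self):
        series, curve = exact_model_series()
        df = ReplicationTimingModel(series, curve).fit().to_frame()
        for col in ("chrom", "start", "end", "mu", "sigma", "status", "F25", "F50", "F75"):
            assert col in df.columns
        np.testing.assert_allclose(df["F50"], 0.5, atol=1e-6)


class TestEvaluateExtent:
    def test_g_equal_mu_gives_half(self):
        series, curve = exact_model_series(0.42, 0.07)
        res = ReplicationTimingModel(series, curve).fit()
        f = res.evaluate_extent([0.42])
        np.testing.assert_allclose(f, 0.5, atol=1e-3)

    def test_extreme_g_clipped(self):
        series, curve = exact_model_series(0.5, 0.05)
        res = ReplicationTimingModel(series, curve).fit()
        f = res.evaluate_extent([0.0, 1.0])
        assert f[0].max() < 1e-6
        assert f[1].min() > 1 - 1e-6


class TestCompareConditions:
    def test_identical_models_zero_delta(self):
        series, curve = exact_model_series()
        res = ReplicationTimingModel(series, curve).fit()
        out = compare_conditions(res, res, {"all": np.arange(10)})
        np.testing.assert_allclose(out["delta"], 0.0, atol=1e-12)
        assert out["test"] == "mannwhitneyu"

    def test_swapped_arguments_negate_delta(self):
        series_a, curve = exact_model_series(0.4, 0.1)
        series_b, _ = exact_model_series(0.6, 0.1)
        ra = ReplicationTimingModel(series_a, curve).fit()
        rb = ReplicationTimingModel(series_b, curve).fit()
        ab = compare_conditions(ra, rb)["delta"]
        ba = compare_conditions(rb, ra)["delta"]
        np.testing.assert_allclose(ab, -ba)
        assert (ab > 0).all()  # earlier model has higher F(0.5)


class TestMatchedGProfile:
    def test_interpolates_between_bracketing_timepoints(self):
        genome = BinnedGenome([("c", 900)], 300)
        curve = GlobalReplicationCurve([10, 20, 150], [20.0, 60.0, 100.0], 150)
        tracks = {
            10.0: EnrichmentTrack(genome, np.zeros(3), timepoint=10.0),
            20.0: EnrichmentTrack(genome, np.ones(3), timepoint=20.0),
        }
        prof = profile_at_matched_g(tracks, curve, 0.4)  # halfway 0.2 → 0.6
        np.testing.assert_allclose(prof.values, 0.5)

    def test_clamps_outside_range(self):
        genome = BinnedGenome([("c", 900)], 300)
        curve = GlobalReplicationCurve([10, 20, 150], [20.0, 60.0, 100.0], 150)
        tracks = {
            10.0: EnrichmentTrack(genome, np.zeros(3), timepoint=10.0),
            20.0: EnrichmentTrack(genome, np.ones(3), timepoint=20.0),
        }
        np.testing.assert_allclose(
            profile_at_matched_g(tracks, curve, 0.05).values, 0.0
        )
        np.testing.assert_allclose(
            profile_at_matched_g(tracks, curve, 0.9).values, 1.0
        )


@pytest.fixture(scope="module")
def thousand_bin_fit():
    """300-kb genome (1,000 bins), full chain at ip_depth 100."""
    from replitime import simulate as sim
    from replitime.binning import compute_at_ratio
    from replitime.enrichment import enrichment_chain

    origins = sim.demo_origins(17, [("c", 300_000)], spacing_kb=(45.0, 60.0))
    cfg = sim.SimulationConfig(
        chromosomes=[("c", 300_000)],
        origins=origins,
        timepoints=list(sim.DEMO_TIMEPOINTS),
        ip_depth=100.0,
        seed=17,
    )
    genome = cfg.genome()
    at = compute_at_ratio(sim.synthetic_genome_sequences(cfg), genome)
    truth = sim.compute_truth(cfg)
    tracks, inp = sim.emit_count_tracks(cfg, truth, at)
    curve, _ = sim.emit_global_curve(truth)
    ep = {t: enrichment_chain(tr, inp, at) for t, tr in tracks.items()}
    series = local_extent(ep, curve, 160.0)
    res = ReplicationTimingModel(series, curve, sim.DEMO_FIT_TIMEPOINTS).fit()
    return res, truth


class TestRecoveryFromSimulation:
    def test_median_mu_error_small(self, thousand_bin_fit):
        res, truth = thousand_bin_fit
        ok = (res.status == STATUS_CONVERGED) & ~np.isnan(truth.half_rep_g)
        err = np.abs(res.mu[ok] - truth.half_rep_g[ok])
        assert np.median(err) < 0.05

    def test_rank_agreement_with_truth(self, thousand_bin_fit):
        from scipy.stats import spearmanr

        res, truth = thousand_bin_fit
        ok = (res.status == STATUS_CONVERGED) & ~np.isnan(truth.half_rep_g)
        rho = spearmanr(res.mu[ok], truth.half_rep_g[ok]).statistic
        assert rho > 0.95

    def test_early_origin_bins_outrank_midpoints(self, thousand_bin_fit):
        res, truth = thousand_bin_fit
        f50 = res.evaluate_extent([0.5])[0]
        genome = res.genome
        origin_bins = [genome.bin_index(c, p) for c, p in truth.origin_positions]
        mids = [
            (a + b) // 2 for a, b in zip(origin_bins[:-1], origin_bins[1:])
        ]
        assert np.nanmedian(f50[origin_bins]) > np.nanmedian(f50[mids])


def test_depth_robustness_of_recovery():
    """Median |mu error| is nonincreasing as sequencing depth doubles."""
    from replitime import simulate as sim
    from replitime.enrichment import enrichment_chain

    origins = sim.demo_origins(23, [("c", 240_000)], spacing_kb=(45.0, 60.0))
    medians = []
    for depth in (25.0, 50.0, 100.0, 200.0):
        cfg = sim.SimulationConfig(
            chromosomes=[("c", 240_000)],
            origins=origins,
            timepoints=list(sim.DEMO_TIMEPOINTS),
            ip_depth=depth,
            input_depth=depth,
            seed=23,
        )
        truth = sim.compute_truth(cfg)
        tracks, inp = sim.emit_count_tracks(cfg, truth)
        curve, _ = sim.emit_global_curve(truth)
        ep = {t: enrichment_chain(tr, inp, None) for t, tr in tracks.items()}
        series = local_extent(ep, curve, 160.0)
        res = ReplicationTimingModel(series, curve, sim.DEMO_FIT_TIMEPOINTS).fit()
        ok = (res.status == STATUS_CONVERGED) & ~np.isnan(truth.half_rep_g)
        medians.append(np.median(np.abs(res.mu[ok] - truth.half_rep_g[ok])))
    assert all(b <= a + 1e-3 for a, b in zip(medians, medians[1:])), medians
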