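"""LIR estimator vs. exhaustive enumeration, decay-model recovery, indices."""

import datetime as dt
import itertools

import numpy as np
import pytest

import whalesoc as ws
from whalesoc.fidelity import (
    _m_closed,
    _m_emig,
    _m_reimm,
    _permute_within_season,
    pool_curve,
)

from conftest import d, history_from_days


def brute_force_lir(history, max_lag=230):
    """Independent LIR oracle: literal sum over all same-year day pairs."""
    days = history.day_numbers
    years = history.years
    num, den = {}, {}
    for t1, t2 in itertools.combinations(range(history.n_occasions), 2):
        if years[t1] != years[t2]:
            continue
        lag = int(days[t2] - days[t1])
        if not (1 <= lag <= max_lag):
            continue
        m = int(np.sum(history.seen[:, t1] & history.seen[:, t2]))
        n1 = int(history.seen[:, t1].sum())
        n2 = int(history.seen[:, t2].sum())
        num[lag] = num.get(lag, 0) + m
        den[lag] = den.get(lag, 0) + n1 * n2
    return {lag: num[lag] / den[lag] for lag in den if den[lag] > 0}


class TestLirEstimator:
    def test_single_individual_seen_daily_has_rate_one(self):
        h = history_from_days({d(k): [["A"]] for k in range(1, 8)})
        curve = ws.lir(h, min_pairs=1, n_boot=0)
        assert np.allclose(curve.rate, 1.0)

    def test_closed_population_perfect_detection_is_one_over_n(self):
        ids = [f"I{k}" for k in range(8)]
        h = history_from_days({d(k): [[i] for i in ids] for k in range(1, 6)})
        curve = ws.lir(h, min_pairs=1, n_boot=0)
        assert np.allclose(curve.rate, 1.0 / 8)

    def test_matches_brute_force_on_toy(self, toy_history):
        curve = ws.lir(toy_history, min_pairs=1, n_boot=0)
        oracle = brute_force_lir(toy_history)
        got = dict(zip(curve.lags.astype(int), curve.rate))
        assert got.keys() == oracle.keys()
        for lag, v in oracle.items():
            assert got[lag] == pytest.approx(v)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_small_histories(self, seed):
        rng = np.random.default_rng(seed)
        n_ind, n_day = rng.integers(2, 6), rng.integers(2, 6)
        day_groups = {}
        for k in range(n_day):
            present = [f"I{j}" for j in range(n_ind) if rng.random() < 0.6]
            if present:
                day_groups[d(int(k * rng.integers(1, 3)) + k + 1)] = [[p] for p in present]
        if len(day_groups) < 2:
            pytest.skip("degenerate draw")
        h = history_from_days(day_groups)
        curve = ws.lir(h, min_pairs=1, n_boot=0)
        oracle = brute_force_lir(h)
        got = dict(zip(curve.lags.astype(int), curve.rate))
        assert got.keys() == oracle.keys()
        for lag, v in oracle.items():
            assert got[lag] == pytest.approx(v)

    def test_min_pairs_filters_thin_lags(self, toy_history):
        strict = ws.lir(toy_history, min_pairs=10, n_boot=0)
        loose = ws.lir(toy_history, min_pairs=1, n_boot=0)
        assert strict.lags.size <= loose.lags.size

    def test_bootstrap_interval_brackets_point_estimate(self, synthetic_study):
        curve = ws.lir(synthetic_study["history"], n_boot=50, rng=3)
        ok = (curve.ci_lo <= curve.rate + 1e-12) & (curve.rate <= curve.ci_hi + 1e-12)
        assert ok.mean() > 0.9


class TestLirNull:
    def test_permutation_preserves_individual_season_counts(self, synthetic_study):
        h = synthetic_study["history"]
        rng = np.random.default_rng(0)
        X = h.seen.astype(float)
        Xp = _permute_within_season(X, h.years, rng)
        for y in np.unique(h.years):
            cols = h.years == y
            assert np.array_equal(X[:, cols].sum(axis=1), Xp[:, cols].sum(axis=1))

    def test_resident_population_exceeds_null_at_short_lags(self):
        # long within-season residency should beat the random-movement null
        cfg = ws.SimConfig(n_individuals=40, n_communities=2, years=2,
                           days_per_season=40, residency_mean=30.0,
                           return_p=0.9, seed=9)
        records, _ = ws.simulate(cfg)
        h = ws.build_capture_history(records)
        curve = ws.lir_null(h, ws.lir(h, n_boot=0), n_iter=60, rng=4)
        short = curve.lags <= 10
        assert (curve.running_mean[short] > curve.null_hi[short]).any()

    def test_null_draw_is_inside_envelope_most_lags(self):
        # observed data generated by the null process itself: ~5% exceedances
        rng = np.random.default_rng(5)
        ids = [f"I{k}" for k in range(30)]
        day_groups = {
            d(k): [[i] for i in ids if rng.random() < 0.3] for k in range(1, 40)
        }
        h = history_from_days({k: v for k, v in day_groups.items() if v})
        curve = ws.lir_null(h, ws.lir(h, n_boot=0, min_pairs=5), n_iter=80, rng=6)
        exceed = np.mean(curve.rate > curve.null_hi)
        assert exceed < 0.15


class TestDecayModels:
    def test_reimmigration_with_b_one_equals_closed(self):
        tau = np.linspace(1, 200, 50)
        p = {"N": 40.0, "a": 30.0, "b": 1.0}
        assert np.allclose(_m_reimm(tau, p), _m_closed(tau, {"N": 40.0}))

    def test_closed_population_recovers_n(self):
        # Bernoulli detection of a closed population: LIR = 1/N at every lag
        rng = np.random.default_rng(10)
        N, days = 50, 120
        seen = rng.random((N, days)) < 0.5
        dates = [d(k) for k in range(1, days + 1)]
        h = ws.CaptureHistory(
            [f"I{k}" for k in range(N)], dates, seen,
            [[np.array([i]) for i in np.flatnonzero(seen[:, t])] for t in range(days)],
        )
        curve = ws.lir(h, min_pairs=1, n_boot=0)
        fits = ws.fit_lir_models(curve)
        best = fits[0]
        assert best.model_id == "closed"
        assert best.params["N"] == pytest.approx(N, rel=0.10)

    def test_pure_exponential_curve_recovers_decay_constant(self):
        tau = np.arange(1, 230, dtype=float)
        N, a = 60.0, 35.0
        curve = ws.LagCurve(tau, (1 / N) * np.exp(-tau / a), np.full_like(tau, 100.0))
        fits = ws.fit_lir_models(curve, models=["emigration_mortality"])
        assert fits[0].params["a"] == pytest.approx(a, rel=0.10)
        assert fits[0].params["N"] == pytest.approx(N, rel=0.10)

    def test_extra_parameters_never_worsen_raw_fit(self, synthetic_study):
        curve = ws.lir(synthetic_study["history"], n_boot=0)
        fits = {f.model_id: f for f in ws.fit_lir_models(curve)}
        order = ["closed", "emigration_mortality", "emigration_reimmigration",
                 "emigration_reimmigration_mortality"]
        rss = [fits[m].rss for m in order]
        assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))

    def test_octave_pooling_weights_and_coverage(self, synthetic_study):
        curve = ws.lir(synthetic_study["history"], n_boot=0)
        tau, rate, w = pool_curve(curve)
        assert tau.size >= 4
        assert (np.diff(tau) > 0).all()
        assert (rate >= 0).all() and (w > 0).all()


class TestFidelityIndices:
    def test_seen_every_occasion_spanning_season_scores_one(self):
        h = history_from_days({d(k): [["A"], ["B"]] for k in range(1, 11)})
        fi = ws.fidelity_indices(h).set_index("individual_id")
        row = fi.loc["A"]
        assert row["occurrence"] == 1.0
        assert row["permanence"] == 1.0
        assert row["periodicity"] == 1.0
        assert row["ssfi"] == 1.0

    def test_endpoints_only_gives_full_span_sparse_periodicity(self):
        N = 10
        # F is seen daily and defines the effort/season span
        days = {
            d(k): ([["E"], ["F"]] if k in (1, N) else [["F"]]) for k in range(1, N + 1)
        }
        fi = ws.fidelity_indices(history_from_days(days)).set_index("individual_id")
        row = fi.loc["E"]
        assert row["permanence"] == 1.0
        assert row["periodicity"] == pytest.approx(2 / N)
        assert row["minimum_stay"] == N - 1

    def test_single_capture_year_has_zero_ssfi_and_flag(self):
        days = {d(1): [["A"], ["B"]], d(2): [["B"]], d(3): [["B"]]}
        fi = ws.fidelity_indices(history_from_days(days)).set_index("individual_id")
        assert fi.loc["A", "ssfi"] == 0.0
        assert bool(fi.loc["A", "single_capture"])

    def test_indices_bounded_and_ssfi_below_max(self, synthetic_study):
        fi = ws.fidelity_indices(synthetic_study["history"])
        for col in ("occurrence", "permanence", "periodicity", "ssfi"):
            assert fi[col].between(0, 1).all()
        assert (fi["ssfi"] <= np.maximum(fi["permanence"], fi["periodicity"]) + 1e-12).all()

    def test_aggregate_years_seen_fraction(self, synthetic_study):
        h = synthetic_study["history"]
        fi = ws.aggregate_fidelity(ws.fidelity_indices(h), n_years=3)
        assert fi["years_seen_fraction"].between(0, 1).all()
        assert len(fi) == h.n_individuals


class TestCompareGroups:
    def test_planted_residency_difference_detected(self):
        cfg = ws.SimConfig(
            n_individuals=40, n_communities=2, years=2, days_per_season=40,
            residency_mean=(35.0, 3.0), return_p=0.9, arrival_mean=(5.0, 5.0),
            seed=12,
        )
        records, truth = ws.simulate(cfg)
        h = ws.build_capture_history(records)
        res_ids = {i for i, c in truth.community_of.items() if c == 0 and i in h.index}
        trans_ids = {i for i, c in truth.community_of.items() if c == 1 and i in h.index}
        res = ws.compare_groups_lir(h, res_ids, trans_ids, n_iter=100,
                                    min_pairs=5, rng=13)
        # residents separate from transients once the short transient
        # occupancy window (3 d) has passed
        band = (res.extras["lags"] >= 5) & (res.extras["lags"] <= 25)
        assert res.statistic[band].mean() > 0
        assert (res.p_value[band] < 0.05).any()

    def test_random_labels_rarely_significant(self):
        cfg = ws.SimConfig(n_individuals=40, n_communities=2, years=2,
                           days_per_season=40, seed=14)
        records, _ = ws.simulate(cfg)
        h = ws.build_capture_history(records)
        rng = np.random.default_rng(15)
        ids = list(h.individuals)
        rng.shuffle(ids)
        res = ws.compare_groups_lir(h, set(ids[:20]), set(ids[20:]), n_iter=100,
                                    min_pairs=5, rng=16)
        assert (res.p_value < 0.05).mean() < 0.2

    def test_overlapping_groups_rejected(self, toy_history):
        with pytest.raises(ValueError):
            ws.compare_groups_lir(toy_history, {"A", "B"}, {"B", "C"})
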