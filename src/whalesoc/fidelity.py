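"""Site fidelity: lagged identification rates, decay models, residency indices.

The Lagged Identification Rate LIR(tau) estimates the probability that an
individual identified on a day is re-identified tau days later:

    LIR(tau) = sum_{(t, t+tau)} m(t, t+tau) / sum_{(t, t+tau)} n(t) n(t+tau)

summed over same-season day pairs at lag tau, where m is the number of
individuals identified on both days and n the number identified per day.
Decay-model fitting interprets the curve's shape in terms of population size,
residence time, and reimmigration; the permutation null scatters each
individual's capture days uniformly over the season's effort days, which
destroys residency structure while preserving capture counts and effort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._core import PermutationResult, as_rng, empirical_p

__all__ = [
    "LagCurve",
    "DecayModelFit",
    "lir",
    "lir_null",
    "fit_lir_models",
    "pool_curve",
    "fidelity_indices",
    "aggregate_fidelity",
    "compare_groups_lir",
]


@dataclass
class LagCurve:
    """A rate-versus-time-lag curve with optional bootstrap CI and null envelope."""

    lags: np.ndarray
    rate: np.ndarray
    n_pairs: np.ndarray
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    null_lo: np.ndarray | None = None
    null_med: np.ndarray | None = None
    null_hi: np.ndarray | None = None
    running_mean: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"lag": self.lags, "rate": self.rate, "n_pairs": self.n_pairs}
        for name in ("ci_lo", "ci_hi", "null_lo", "null_med", "null_hi", "running_mean"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)


@dataclass
class DecayModelFit:
    """One fitted lag-rate decay model."""

    model_id: str
    params: dict
    rss: float
    criterion: float
    converged: bool
    n_points: int

    def predict(self, lags) -> np.ndarray:
        return _MODELS[self.model_id][0](np.asarray(lags, float), self.params)


def running_mean(lags: np.ndarray, rate: np.ndarray, window: float = 10.0) -> np.ndarray:
    """Centered moving average over a +-window/2 day band, first point pinned
    to the first retained lag's rate."""
    out = np.empty_like(rate, dtype=float)
    for k, tau in enumerate(lags):
        m = np.abs(lags - tau) <= window / 2.0
        out[k] = rate[m].mean()
    if out.size:
        out[0] = rate[0]
    return out


# ---------------------------------------------------------------------------
# LIR estimator
# ---------------------------------------------------------------------------


def _same_season_pairs(history, max_lag: int):
    """Index arrays (t1, t2, lag) over within-year occasion pairs, lag in [1, max_lag]."""
    years = history.years
    days = history.day_numbers
    i_all, j_all, lag_all = [], [], []
    for y in np.unique(years):
        idx = np.flatnonzero(years == y)
        d = days[idx]
        t1, t2 = np.triu_indices(idx.size, k=1)
        lag = d[t2] - d[t1]
        m = (lag >= 1) & (lag <= max_lag)
        i_all.append(idx[t1[m]])
        j_all.append(idx[t2[m]])
        lag_all.append(lag[m])
    if not i_all:
        return (np.empty(0, np.intp),) * 3
    return (
        np.concatenate(i_all),
        np.concatenate(j_all),
        np.concatenate(lag_all).astype(np.intp),
    )


def _lir_num_den(X: np.ndarray, i_idx, j_idx, lag_idx, max_lag: int):
    """Numerator/denominator sums per lag for a capture matrix X."""
    num = np.zeros(max_lag + 1)
    den = np.zeros(max_lag + 1)
    if i_idx.size == 0:
        return num, den
    m_pairs = (X[:, i_idx] * X[:, j_idx]).sum(axis=0)
    n_t = X.sum(axis=0)
    np.add.at(num, lag_idx, m_pairs)
    np.add.at(den, lag_idx, n_t[i_idx] * n_t[j_idx])
    return num, den


def lir(
    history,
    max_lag: int = 230,
    min_pairs: int = 10,
    n_boot: int = 100,
    rng=None,
    window: float = 10.0,
) -> LagCurve:
    """Lagged Identification Rate over same-season day pairs.

    Lags are retained only where the number of paired identifications (the
    estimator's denominator, ``sum n(t) n(t+tau)``) reaches ``min_pairs``.
    Bootstrap CIs resample individuals with replacement (``n_boot`` replicates,
    2.5/97.5 percentiles).
    """
    if history.n_occasions < 2:
        raise ValueError("need at least two sampling occasions")
    rng = as_rng(rng)
    X = history.seen.astype(float)
    i_idx, j_idx, lag_idx = _same_season_pairs(history, max_lag)
    num, den = _lir_num_den(X, i_idx, j_idx, lag_idx, max_lag)
    retained = den >= max(min_pairs, 1)
    retained[0] = False
    if not retained.any():
        warnings.warn("no lags reach min_pairs; returning empty curve")
        empty = np.empty(0)
        return LagCurve(empty, empty, empty)
    lags = np.flatnonzero(retained)
    rate = num[retained] / den[retained]

    ci_lo = ci_hi = None
    if n_boot and n_boot > 0:
        n = X.shape[0]
        boots = np.empty((n_boot, lags.size))
        # per-individual numerator contributions are linear in bootstrap weights
        P = X[:, i_idx] * X[:, j_idx]
        C = np.zeros((max_lag + 1, n))
        np.add.at(C, lag_idx, P.T)
        for b in range(n_boot):
            w = np.bincount(rng.integers(0, n, size=n), minlength=n).astype(float)
            num_b = C @ w
            n_t = w @ X
            den_b = np.zeros(max_lag + 1)
            np.add.at(den_b, lag_idx, n_t[i_idx] * n_t[j_idx])
            with np.errstate(invalid="ignore", divide="ignore"):
                boots[b] = num_b[retained] / den_b[retained]
        ci_lo, ci_hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    curve = LagCurve(lags.astype(float), rate, den[retained], ci_lo, ci_hi)
    curve.running_mean = running_mean(curve.lags, curve.rate, window)
    return curve


def _permute_within_season(X: np.ndarray, years: np.ndarray, rng) -> np.ndarray:
    """Scatter each individual's capture days uniformly within each season,
    preserving per-individual seasonal capture counts and the effort set."""
    Xp = np.zeros_like(X)
    for y in np.unique(years):
        cols = np.flatnonzero(years == y)
        block = X[:, cols]
        counts = block.sum(axis=1).astype(int)
        r = rng.random(block.shape)
        ranks = r.argsort(axis=1).argsort(axis=1)
        Xp[:, cols] = ranks < counts[:, None]
    return Xp.astype(float)


def lir_null(
    history,
    curve: LagCurve,
    n_iter: int = 100,
    max_lag: int = 230,
    rng=None,
) -> LagCurve:
    """Null envelope for a LIR curve under random movement in and out.

    Each iteration permutes every individual's capture days uniformly over the
    season's occasions; the envelope is the 2.5/50/97.5 percentile band of the
    null rates at the observed curve's retained lags. The curve's running mean
    rising above the upper band marks lags with significant residency.
    """
    rng = as_rng(rng)
    X = history.seen.astype(float)
    years = history.years
    i_idx, j_idx, lag_idx = _same_season_pairs(history, max_lag)
    lag_sel = curve.lags.astype(int)
    null_rates = np.empty((n_iter, lag_sel.size))
    for it in range(n_iter):
        Xp = _permute_within_season(X, years, rng)
        num, den = _lir_num_den(Xp, i_idx, j_idx, lag_idx, max_lag)
        with np.errstate(invalid="ignore", divide="ignore"):
            null_rates[it] = (num / den)[lag_sel]
    lo, med, hi = np.nanpercentile(null_rates, [2.5, 50.0, 97.5], axis=0)
    curve.null_lo, curve.null_med, curve.null_hi = lo, med, hi
    return curve


# ---------------------------------------------------------------------------
# Decay models
# ---------------------------------------------------------------------------

# model_id -> (predict(tau, params), param names, builder from vector)


def _m_closed(tau, p):
    return np.full_like(tau, 1.0 / p["N"], dtype=float)


def _m_emig(tau, p):
    return (1.0 / p["N"]) * np.exp(-tau / p["a"])


def _m_reimm(tau, p):
    return (1.0 / p["N"]) * (p["b"] + (1.0 - p["b"]) * np.exp(-tau / p["a"]))


def _m_reimm_mort(tau, p):
    return _m_reimm(tau, p) * np.exp(-tau * p["delta"])


_MODELS = {
    "closed": (_m_closed, ["N"]),
    "emigration_mortality": (_m_emig, ["N", "a"]),
    "emigration_reimmigration": (_m_reimm, ["N", "a", "b"]),
    "emigration_reimmigration_mortality": (_m_reimm_mort, ["N", "a", "b", "delta"]),
}


def _pack(model_id, vec):
    names = _MODELS[model_id][1]
    p = {}
    for name, v in zip(names, vec):
        v = float(np.clip(v, -500.0, 500.0))
        if name == "b":
            p[name] = 1.0 / (1.0 + np.exp(-v))  # logit scale
        else:
            p[name] = np.exp(v)  # log scale, positive
    return p


def _fit_one(model_id, tau, rate, w, starts):
    f = _MODELS[model_id][0]

    def resid(vec):
        return np.sqrt(w) * (f(tau, _pack(model_id, vec)) - rate)

    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return None, np.inf, False
    rss, sol = best
    return _pack(model_id, sol.x), rss, bool(best[1].success)


def pool_curve(curve: LagCurve, octaves: int = 9):
    """Pool a lag curve into octave bins centered at tau = 2^0 .. 2^(octaves-1).

    Bin k gathers lags in [2^(k-1/2), 2^(k+1/2)); pooled lag and rate are
    weighted means (weights = paired identifications). Returns (tau, rate, w).
    """
    lags, rate, w = curve.lags, curve.rate, curve.n_pairs
    taus, rates, weights = [], [], []
    for k in range(octaves):
        lo, hi = 2**k / np.sqrt(2.0), 2**k * np.sqrt(2.0)
        m = (lags >= lo) & (lags < hi)
        if not m.any():
            continue
        wk = w[m]
        taus.append(np.average(lags[m], weights=wk))
        rates.append(np.average(rate[m], weights=wk))
        weights.append(wk.sum())
    return np.array(taus), np.array(rates), np.array(weights)


def _aicc(rss, n, k):
    if n - k - 1 <= 0 or rss <= 0:
        return np.inf
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_lir_models(curve: LagCurve, models=None, pool: bool = True) -> list:
    """Fit candidate demographic decay models to a LIR curve.

    Candidates: closed (R = 1/N); emigration/mortality (R = e^(-tau/a)/N);
    emigration + reimmigration (R = (b + (1-b) e^(-tau/a))/N); and the latter
    with an additional mortality decay. Fitting is weighted least squares on
    octave-pooled points; models are ranked by a small-sample corrected
    information criterion on the least-squares deviance. Nested models are
    seeded from their simpler parent so added parameters never worsen the raw
    fit. Non-convergent fits are returned flagged, not raised.
    """
    models = list(models) if models is not None else list(_MODELS)
    tau, rate, w = pool_curve(curve) if pool else (curve.lags, curve.rate, curve.n_pairs)
    if tau.size < 4:
        raise ValueError("need at least 4 pooled lag points to fit decay models")
    w = w / w.mean()
    mean_rate = max(np.average(rate, weights=w), 1e-12)
    logN0 = np.log(1.0 / mean_rate)
    fits = {}
    results = []
    starts_by_model = {
        "closed": [[logN0]],
        "emigration_mortality": [
            [logN0, np.log(np.median(tau))],
            [logN0, np.log(10 * tau.max())],
        ],
        "emigration_reimmigration": [
            [logN0, np.log(np.median(tau)), -3.0],
            [logN0, np.log(np.median(tau)), 3.0],
        ],
        "emigration_reimmigration_mortality": [
            [logN0, np.log(np.median(tau)), -3.0, np.log(1e-6)],
        ],
    }
    parents = {
        "emigration_mortality": "closed",
        "emigration_reimmigration": "emigration_mortality",
        "emigration_reimmigration_mortality": "emigration_reimmigration",
    }
    for model_id in _MODELS:  # fit in nesting order
        if model_id not in models and model_id not in parents.values():
            continue
        starts = list(starts_by_model[model_id])
        parent = parents.get(model_id)
        if parent in fits and fits[parent][0] is not None:
            pp = fits[parent][0]
            vec = [np.log(pp["N"])]
            if model_id != "closed":
                vec.append(np.log(pp.get("a", 10 * tau.max())))
            if "b" in _MODELS[model_id][1]:
                b = pp.get("b", 1e-3)
                b = min(max(b, 1e-6), 1 - 1e-6)
                vec.append(np.log(b / (1 - b)))
            if "delta" in _MODELS[model_id][1]:
                vec.append(np.log(max(pp.get("delta", 1e-8), 1e-12)))
            starts.append(vec)
        params, rss, ok = _fit_one(model_id, tau, rate, w, starts)
        # guard: a nested parent's solution must never beat the richer model
        if parent in fits and fits[parent][1] < rss:
            rss = fits[parent][1]
            params, ok = _embed_parent(model_id, fits[parent][0]), fits[parent][2]
        fits[model_id] = (params, rss, ok)
        if model_id in models:
            k = len(_MODELS[model_id][1])
            results.append(
                DecayModelFit(model_id, params or {}, rss, _aicc(rss, tau.size, k), ok, tau.size)
            )
    results.sort(key=lambda f: f.criterion)
    return results


def _embed_parent(model_id, parent_params):
    p = dict(parent_params)
    if model_id != "closed" and "a" not in p:
        p["a"] = 1e12  # no decay
    if "b" in _MODELS[model_id][1] and "b" not in p:
        p["b"] = 1e-12
    if "delta" in _MODELS[model_id][1] and "delta" not in p:
        p["delta"] = 0.0
    return p


# ---------------------------------------------------------------------------
# Individual fidelity indices
# ---------------------------------------------------------------------------


def fidelity_indices(history, season_bounds: dict | None = None,
                     inclusive_stay: bool = False) -> pd.DataFrame:
    """Per individual-year site-fidelity indices.

    occurrence = capture days / effort occasions that season;
    permanence = exclusive capture span / exclusive season span;
    periodicity = capture days / inclusive capture span;
    SSFI = harmonic mean of permanence and periodicity (0 for single-capture
    seasons, flagged by ``single_capture``);
    minimum_stay = last - first capture day (add one with ``inclusive_stay``).
    Season bounds default to each year's first and last effort day.
    """
    years = history.years
    days = history.day_numbers
    rows = []
    for y in np.unique(years):
        cols = np.flatnonzero(years == y)
        d = days[cols]
        doy = np.array([history.occasions[c].timetuple().tm_yday for c in cols])
        if season_bounds and int(y) in season_bounds:
            s0, s1 = season_bounds[int(y)]
        else:
            s0, s1 = d.min(), d.max()
        season_span = max(s1 - s0, 1)
        block = history.seen[:, cols]
        n_occ = cols.size
        for i in np.flatnonzero(block.any(axis=1)):
            cap = np.flatnonzero(block[i])
            ncap = cap.size
            first, last = d[cap[0]], d[cap[-1]]
            span_excl = last - first
            span_incl = span_excl + 1
            occurrence = ncap / n_occ
            permanence = span_excl / season_span
            periodicity = ncap / span_incl
            if permanence > 0 and periodicity > 0:
                ssfi = 2.0 / (1.0 / permanence + 1.0 / periodicity)
            else:
                ssfi = 0.0
            rows.append(
                {
                    "individual_id": history.individuals[i],
                    "year": int(y),
                    "n_captures": int(ncap),
                    "occurrence": occurrence,
                    "permanence": permanence,
                    "periodicity": periodicity,
                    "ssfi": ssfi,
                    "minimum_stay": int(span_excl + (1 if inclusive_stay else 0)),
                    "arrival_day": int(doy[cap[0]]),
                    "single_capture": bool(ncap == 1),
                }
            )
    return pd.DataFrame(rows)


def aggregate_fidelity(per_year: pd.DataFrame, n_years: int) -> pd.DataFrame:
    """Per-individual means of the yearly indices plus years-seen fraction."""
    g = per_year.groupby("individual_id")
    out = g.agg(
        years_seen=("year", "nunique"),
        mean_arrival_day=("arrival_day", "mean"),
        mean_minimum_stay=("minimum_stay", "mean"),
        mean_ssfi=("ssfi", "mean"),
        mean_occurrence=("occurrence", "mean"),
    )
    out["years_seen_fraction"] = out["years_seen"] / n_years
    return out


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def compare_groups_lir(
    history,
    group_a,
    group_b,
    n_iter: int = 1000,
    max_lag: int = 230,
    min_pairs: int = 10,
    rng=None,
) -> PermutationResult:
    """Permutation test of LIR differences between two individual sets.

    The statistic is LIR_a(tau) - LIR_b(tau) at each lag retained in both
    groups; the null shuffles group labels over the pooled individuals. The
    per-lag p-values are two-tailed.
    """
    rng = as_rng(rng)
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b or (group_a & group_b):
        raise ValueError("groups must be disjoint and non-empty")
    idx_a = np.array(sorted(history.index[i] for i in group_a if i in history.index))
    idx_b = np.array(sorted(history.index[i] for i in group_b if i in history.index))
    X = history.seen.astype(float)
    i_idx, j_idx, lag_idx = _same_season_pairs(history, max_lag)

    def rates(ia, ib):
        na, da = _lir_num_den(X[ia], i_idx, j_idx, lag_idx, max_lag)
        nb, db = _lir_num_den(X[ib], i_idx, j_idx, lag_idx, max_lag)
        keep = (da >= min_pairs) & (db >= min_pairs)
        with np.errstate(invalid="ignore", divide="ignore"):
            return keep, na / da, nb / db

    keep, ra, rb = rates(idx_a, idx_b)
    keep[0] = False
    lags = np.flatnonzero(keep)
    if lags.size == 0:
        warnings.warn("no lags retained in both groups")
    obs = (ra - rb)[lags]
    pool = np.concatenate([idx_a, idx_b])
    null = np.empty((n_iter, lags.size))
    for it in range(n_iter):
        perm = rng.permutation(pool)
        _, ra_n, rb_n = rates(perm[: idx_a.size], perm[idx_a.size:])
        null[it] = (ra_n - rb_n)[lags]
    p = np.array(
        [empirical_p(obs[k], null[~np.isnan(null[:, k]), k], "two-sided") for k in range(lags.size)]
    )
    return PermutationResult(
        statistic=obs,
        null=null,
        p_value=p,
        n_iter=n_iter,
        alternative="two-sided",
        extras={"lags": lags.astype(float), "rate_a": ra[lags], "rate_b": rb[lags]},
    )
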