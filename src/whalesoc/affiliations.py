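"""Generalized Affiliation Indices: association strength net of structure.

A dyad's raw association index confounds social preference with structural
opportunity — how gregarious the two animals are, and how much they overlap
in space and time. The GAI removes this by regressing the dyadic association
counts (x successes out of d joint-sampling occasions, binomial family) on
three structural predictors and taking the signed deviance residual as the
affiliation index: positive = more association than structure predicts
(preference), negative = less (avoidance / selectivity).

Predictors: joint gregariousness (log product of the partners' summed
association indices, each sum excluding the focal dyad); geographic overlap
(proportion of co-identified years with yearly positions within a radius);
temporal overlap (co-identified years over years either was identified).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._core import PermutationResult, as_rng, empirical_p
from .associations import DatastreamPermuter, DyadStats

__all__ = [
    "PredictorSet",
    "AffiliationMatrix",
    "yearly_positions",
    "predictors",
    "gai_matrix",
    "preference_tests",
]

_GREG_FLOOR = 1e-6


@dataclass
class PredictorSet:
    """Symmetric structural-predictor matrices aligned to a dyad set."""

    ids: list
    gregariousness: np.ndarray
    temporal_overlap: np.ndarray
    geographic_overlap: np.ndarray | None

    def names(self) -> list:
        out = ["gregariousness", "temporal_overlap"]
        if self.geographic_overlap is not None:
            out.append("geographic_overlap")
        return out

    def matrix(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class AffiliationMatrix:
    """Symmetric GAI matrix with the dyads entering the regression flagged."""

    ids: list
    gai: np.ndarray
    valid: np.ndarray          # dyads included in the regression (symmetric bool)
    predictors: PredictorSet
    model_params: pd.Series
    deviance: float
    null_deviance: float

    def pair_values(self):
        ii, jj = np.nonzero(np.triu(self.valid, k=1))
        return ii, jj, self.gai[ii, jj]


def yearly_positions(encounters) -> pd.DataFrame:
    """Per individual-year mean fjord position from encounter records."""
    rows = [
        {"individual_id": m, "year": e.date.year, "position_km": e.position_km}
        for e in encounters
        if e.position_km is not None
        for m in e.member_ids
    ]
    if not rows:
        return pd.DataFrame(columns=["individual_id", "year", "position_km"])
    return (
        pd.DataFrame(rows)
        .groupby(["individual_id", "year"], as_index=False)["position_km"]
        .mean()
    )


def _gregariousness(sri: np.ndarray) -> np.ndarray:
    """Joint gregariousness with the focal dyad excluded from each sum."""
    s = np.nan_to_num(sri, nan=0.0)
    totals = s.sum(axis=1)
    left = np.maximum(totals[:, None] - s, _GREG_FLOOR)
    right = np.maximum(totals[None, :] - s, _GREG_FLOOR)
    return np.log(left * right)


def predictors(
    history,
    dyads: DyadStats,
    positions: pd.DataFrame | None = None,
    radius_km: float = 15.0,
) -> PredictorSet:
    """Structural predictors for every dyad in ``dyads``.

    ``positions`` is a per individual-year position table (see
    :func:`yearly_positions`); without it the geographic-overlap predictor is
    dropped with a warning. Geographic overlap is NaN for dyads with no
    co-identified years (such dyads are excluded from the GAI regression).
    """
    ids = dyads.ids
    idx = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    years = history.years
    uniq_years = np.unique(years)
    seen_years = np.zeros((n, uniq_years.size), dtype=bool)
    for yi, y in enumerate(uniq_years):
        block = history.seen[:, years == y].any(axis=1)
        for k, ind in enumerate(ids):
            seen_years[k, yi] = block[history.index[ind]]
    co = seen_years.astype(int) @ seen_years.T.astype(int)
    any_years = seen_years.sum(axis=1)
    union = any_years[:, None] + any_years[None, :] - co
    with np.errstate(invalid="ignore", divide="ignore"):
        temporal = np.where(union > 0, co / np.maximum(union, 1), 0.0)

    geographic = None
    if positions is not None and len(positions):
        pos = np.full((n, uniq_years.size), np.nan)
        ymap = {int(y): yi for yi, y in enumerate(uniq_years)}
        for row in positions.itertuples(index=False):
            if row.individual_id in idx and int(row.year) in ymap:
                pos[idx[row.individual_id], ymap[int(row.year)]] = row.position_km
        geographic = np.full((n, n), np.nan)
        have = ~np.isnan(pos)
        for i in range(n):
            both = have[i][None, :] & have  # (n, years)
            near = np.abs(pos[i][None, :] - pos) <= radius_km
            n_both = both.sum(axis=1)
            with np.errstate(invalid="ignore"):
                geographic[i] = np.where(
                    n_both > 0, (both & near).sum(axis=1) / np.maximum(n_both, 1), np.nan
                )
        np.fill_diagonal(geographic, np.nan)
    else:
        warnings.warn("no yearly positions supplied; geographic overlap dropped")

    return PredictorSet(
        ids=list(ids),
        gregariousness=_gregariousness(dyads.sri),
        temporal_overlap=temporal,
        geographic_overlap=geographic,
    )


def _fit_gai(x, d, design, names):
    exog = sm.add_constant(design, has_constant="add")
    endog = np.column_stack([x, d - x])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    try:
        res = model.fit()
    except Exception as err:  # separation / convergence failures
        raise RuntimeError(
            f"GAI regression failed with predictors {names}: {err}"
        ) from err
    return res


def gai_matrix(dyads: DyadStats, preds: PredictorSet, use=None) -> AffiliationMatrix:
    """Fit the affiliation regression and return signed deviance residuals.

    Dyads enter the fit when d > 0 and every predictor is finite; at least
    three times as many dyads as predictors are required.
    """
    names = list(use) if use is not None else preds.names()
    mask = dyads.pair_mask()
    cols = [preds.matrix(nm) for nm in names]
    finite = np.ones_like(mask)
    for c in cols:
        finite &= np.isfinite(c)
    mask = mask & finite
    ii, jj = np.nonzero(mask)
    if ii.size < 3 * len(names):
        raise ValueError("need at least 3x more dyads than predictors")
    x = dyads.x[ii, jj].astype(float)
    d = dyads.d[ii, jj].astype(float)
    design = np.column_stack([c[ii, jj] for c in cols])
    res = _fit_gai(x, d, design, names)
    gai = np.full_like(dyads.sri, np.nan)
    gai[ii, jj] = res.resid_deviance
    gai[jj, ii] = res.resid_deviance
    valid = np.zeros_like(mask)
    valid[ii, jj] = True
    valid[jj, ii] = True
    return AffiliationMatrix(
        ids=list(dyads.ids),
        gai=gai,
        valid=valid,
        predictors=preds,
        model_params=pd.Series(res.params, index=["const"] + names),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
    )


def _subset_pair_mask(ids, valid, set_a, set_b=None) -> np.ndarray:
    in_a = np.array([i in set_a for i in ids])
    in_b = in_a if set_b is None else np.array([i in set_b for i in ids])
    m = (in_a[:, None] & in_b[None, :]) | (in_b[:, None] & in_a[None, :])
    return np.triu(m & valid, k=1)


def preference_tests(
    history,
    dyads: DyadStats,
    preds: PredictorSet,
    subsets: dict,
    n_iter: int = 1000,
    min_sightings: int = 5,
    alpha: float = 0.05,
    rng=None,
) -> dict:
    """Data-stream permutation tests of affiliation preference by subnetwork.

    ``subsets`` maps a label to an id set (within-set ties) or an (a, b) pair
    of id sets (between-set ties). Each permutation swaps group members
    within days, recomputes the associations, re-derives gregariousness,
    refits the affiliation regression, and collects null GAIs. Two
    population statistics per subset: the prevalence of significant positive
    affiliations (dyads whose observed GAI exceeds their null 95th
    percentile) and the standard deviation of the GAI; each is compared
    one-tailed (high) to its null distribution.
    """
    rng = as_rng(rng)
    obs = gai_matrix(dyads, preds)
    names = preds.names()
    ii, jj = np.nonzero(np.triu(obs.valid, k=1))
    d = dyads.d[ii, jj].astype(float)
    x_cols_fixed = [preds.matrix(nm)[ii, jj] for nm in names if nm != "gregariousness"]
    fixed_names = [nm for nm in names if nm != "gregariousness"]

    perm = DatastreamPermuter(history, min_sightings=min_sightings, rng=rng)
    if perm.keep.size != len(dyads.ids):
        raise ValueError("dyads and permuter cover different individual sets")
    null_gai = np.empty((n_iter, ii.size))
    for it, x_perm in enumerate(perm.stream(n_iter)):
        with np.errstate(invalid="ignore", divide="ignore"):
            sri_p = np.where(dyads.d > 0, x_perm / np.maximum(dyads.d, 1), np.nan)
        design_cols = []
        for nm in names:
            if nm == "gregariousness":
                design_cols.append(_gregariousness(sri_p)[ii, jj])
        design = np.column_stack(design_cols + x_cols_fixed) if design_cols else np.column_stack(x_cols_fixed)
        # keep predictor order stable: gregariousness first when present
        res = _fit_gai(x_perm[ii, jj].astype(float), d, design,
                       ["gregariousness"] * bool(design_cols) + fixed_names)
        null_gai[it] = res.resid_deviance

    q95 = np.quantile(null_gai, 0.95, axis=0)
    obs_flat = obs.gai[ii, jj]
    results = {}
    for label, spec_sets in subsets.items():
        if isinstance(spec_sets, (tuple, list)) and len(spec_sets) == 2:
            set_a, set_b = spec_sets
        else:
            set_a, set_b = spec_sets, None
        m = _subset_pair_mask(obs.ids, obs.valid, set(set_a), set(set_b) if set_b else None)
        sel = m[ii, jj]
        if sel.sum() < 2:
            warnings.warn(f"subset {label!r} has fewer than 2 dyads; skipped")
            continue
        o = obs_flat[sel]
        ng = null_gai[:, sel]
        prev_obs = float((o > q95[sel]).mean())
        prev_null = (ng > q95[None, sel]).mean(axis=1)
        sd_obs = float(o.std())
        sd_null = ng.std(axis=1)
        results[label] = PermutationResult(
            statistic=prev_obs,
            null=prev_null,
            p_value=empirical_p(prev_obs, prev_null, "greater"),
            n_iter=n_iter,
            extras={
                "n_dyads": int(sel.sum()),
                "sd_observed": sd_obs,
                "sd_null": sd_null,
                "p_sd": empirical_p(sd_obs, sd_null, "greater"),
                "prop_negative": float((o < 0).mean()),
                "max_gai": float(o.max()),
            },
        )
    return results
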