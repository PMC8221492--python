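"""Social niche partitioning tests: trait clustering vs. social communities.

The congruency framework asks whether a population's social communities line
up with habitat-use traits. Individuals are clustered on standardized trait
variables with k-means (k pinned to the social community count), and the
agreement between the trait clustering and the social partition is measured
with the Adjusted Rand Index (ARI). Significance comes from two independent
randomizations: the forward null shuffles social community labels across
individuals; the reverse null shuffles each trait variable across individuals
and re-clusters. A sweep over all variable subsets ranks the trait
combinations and scores variable importance. The dyadic behavior-transference
test works at the pair level: do dyads that practice one behavior together
engage in other behaviors together more (or less) than remaining dyads?
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from ._core import PermutationResult, as_rng, empirical_p
from .fidelity import aggregate_fidelity, fidelity_indices

__all__ = [
    "TraitTable",
    "CongruencyResult",
    "trait_table",
    "standardize",
    "trait_kmeans",
    "congruency_test",
    "reverse_randomization",
    "subset_sweep",
    "behavior_transference",
]

BEHAVIOR_RATE_VARS = {
    "bubble_net_rate": "bubble_net",
    "feed_rate": "feed_other",
    "social_rate": "social",
    "rest_rate": "rest",
}


@dataclass
class CongruencyResult:
    """Agreement between a trait clustering and the social partition."""

    variables: tuple
    ari: float
    p_value: float
    null_mean: float
    null_q95: float
    n_iter: int
    rand_fraction: float | None = None  # raw fraction of congruent dyads


def trait_table(encounters, history) -> pd.DataFrame:
    """Per-individual habitat-use and site-fidelity traits from observed data.

    Behavioral rates are the proportion of an individual's encounters
    exhibiting each behavior; positional traits are the mean and SD of the
    fjord positions of its encounters; fidelity traits (years-seen fraction,
    mean arrival day, mean minimum stay, mean SSFI) come from the capture
    history. Rows align with the history's individuals.
    """
    per = {
        ind: {"n_enc": 0, "pos": [], **{v: 0 for v in BEHAVIOR_RATE_VARS}}
        for ind in history.individuals
    }
    for e in encounters:
        for m in e.member_ids:
            if m not in per:
                continue
            rec = per[m]
            rec["n_enc"] += 1
            if e.position_km is not None:
                rec["pos"].append(e.position_km)
            for var, code in BEHAVIOR_RATE_VARS.items():
                rec[var] += code in e.behaviors
    rows = {}
    for ind, rec in per.items():
        n = max(rec["n_enc"], 1)
        pos = np.array(rec["pos"], dtype=float)
        rows[ind] = {
            "mean_position": pos.mean() if pos.size else np.nan,
            "sd_position": pos.std(ddof=0) if pos.size > 1 else 0.0,
            **{var: rec[var] / n for var in BEHAVIOR_RATE_VARS},
        }
    traits = pd.DataFrame.from_dict(rows, orient="index")
    fid = aggregate_fidelity(fidelity_indices(history), n_years=np.unique(history.years).size)
    traits = traits.join(
        fid[["years_seen_fraction", "mean_arrival_day", "mean_minimum_stay", "mean_ssfi"]]
    )
    traits.index.name = "individual_id"
    return traits


#: alias used in signatures/docs — the trait table is a plain DataFrame
TraitTable = pd.DataFrame


def standardize(traits: pd.DataFrame) -> pd.DataFrame:
    """Z-score each trait over the analyzed individuals (computed before any
    variable subsetting). Constant columns become zeros."""
    mu = traits.mean()
    sd = traits.std(ddof=0).replace(0.0, 1.0)
    return (traits - mu) / sd


def trait_kmeans(
    traits: pd.DataFrame,
    variables=None,
    k: int = 7,
    seed=None,
    n_starts: int = 10,
    max_iter: int = 100,
) -> pd.Series:
    """k-means partition of individuals on standardized trait variables.

    k is pinned to the social partition's community count; clustering uses
    ``n_starts`` restarts of at most ``max_iter`` iterations, keeping the
    lowest-inertia solution. Constant variables are dropped with a warning.
    """
    z = standardize(traits)
    cols = list(variables) if variables is not None else list(z.columns)
    keep = []
    for c in cols:
        if traits[c].nunique(dropna=True) <= 1:
            warnings.warn(f"constant variable {c!r} dropped from clustering")
        else:
            keep.append(c)
    if not keep:
        raise ValueError("no non-constant variables to cluster on")
    data = z[keep].dropna()
    if k > len(data):
        raise ValueError(f"k={k} exceeds the {len(data)} individuals with complete traits")
    seed_int = int(as_rng(seed).integers(0, 2**31 - 1))
    km = KMeans(n_clusters=k, n_init=n_starts, max_iter=max_iter, random_state=seed_int)
    labels = km.fit_predict(data.to_numpy())
    return pd.Series(labels, index=data.index, name="trait_cluster")


def _align(social: pd.Series | dict, trait_partition: pd.Series):
    social = pd.Series(social)
    common = trait_partition.index.intersection(social.index)
    return social.loc[common].to_numpy(), trait_partition.loc[common].to_numpy()


def _ari(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand Index via the contingency table (hypergeometric chance
    model) — algebraically identical to the standard library implementations
    but cheap enough for tight permutation loops."""
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    table = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb)
    comb2 = lambda v: v * (v - 1) / 2.0
    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    n_pairs = comb2(a.size)
    expected = sum_a * sum_b / n_pairs if n_pairs else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def _rand_fraction(a: np.ndarray, b: np.ndarray) -> float:
    """Raw fraction of dyads congruent between two partitions (Rand index)."""
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(a.size, k=1)
    return float((same_a[iu] == same_b[iu]).mean())


def congruency_test(social, trait_partition: pd.Series, n_iter: int = 1000,
                    rng=None, variables=()) -> CongruencyResult:
    """Forward congruency test: observed ARI vs. label-shuffled social nulls.

    The null shuffles community assignments across individuals (preserving
    community sizes) and recomputes the ARI against the fixed trait
    partition; p is the add-one fraction of null ARIs at least as large as
    observed. The raw fraction of congruent dyads is reported alongside, but
    the chance-corrected ARI is the authoritative statistic.
    """
    rng = as_rng(rng)
    s, t = _align(social, trait_partition)
    ari = adjusted_rand_score(s, t)
    null = np.empty(n_iter)
    for it in range(n_iter):
        null[it] = _ari(s[rng.permutation(s.size)], t)
    return CongruencyResult(
        variables=tuple(variables),
        ari=float(ari),
        p_value=empirical_p(ari, null, "greater"),
        null_mean=float(null.mean()),
        null_q95=float(np.quantile(null, 0.95)),
        n_iter=n_iter,
        rand_fraction=_rand_fraction(s, t),
    )


def reverse_randomization(
    social,
    traits: pd.DataFrame,
    variables,
    k: int | None = None,
    n_iter: int = 1000,
    rng=None,
) -> PermutationResult:
    """Reverse congruency check: trait-shuffle + re-cluster null.

    Each iteration permutes every trait variable independently across
    individuals, re-runs k-means on the shuffled traits, and records the ARI
    against the (fixed) social partition; p is the add-one fraction of null
    ARIs at least as large as the realized one.
    """
    rng = as_rng(rng)
    social = pd.Series(social)
    if k is None:
        k = social.nunique()
    obs_part = trait_kmeans(traits, variables, k=k, seed=rng)
    s, t = _align(social, obs_part)
    obs = adjusted_rand_score(s, t)
    cols = list(variables)
    # z-scoring commutes with per-column permutation, so the null can work
    # on the standardized array directly with the same k-means protocol
    z = standardize(traits)[cols].loc[obs_part.index].to_numpy()
    s_null = pd.Series(social).loc[obs_part.index].to_numpy()
    null = np.empty(n_iter)
    work = z.copy()
    for it in range(n_iter):
        for c in range(work.shape[1]):
            work[:, c] = z[rng.permutation(z.shape[0]), c]
        km = KMeans(n_clusters=k, n_init=10, max_iter=100,
                    random_state=int(rng.integers(0, 2**31 - 1)))
        null[it] = _ari(s_null, km.fit_predict(work))
    return PermutationResult(
        statistic=float(obs),
        null=null,
        p_value=empirical_p(obs, null, "greater"),
        n_iter=n_iter,
        extras={"variables": tuple(cols), "k": k},
    )


def subset_sweep(
    social,
    traits: pd.DataFrame,
    variable_pool,
    n_iter: int = 1000,
    alpha: float = 0.05,
    k: int | None = None,
    rng=None,
):
    """Congruency of every non-empty variable subset, with variable importance.

    Enumerates the 2^p - 1 subsets of ``variable_pool`` (p <= 12), clusters
    each with k-means, and runs the forward congruency test. Returns a results
    frame ranked by ARI and a per-variable importance series: the proportion
    of significant subsets (p <= alpha) that include the variable.
    """
    pool = list(variable_pool)
    if len(pool) > 12:
        raise ValueError("variable pool too large to enumerate (max 12)")
    rng = as_rng(rng)
    social = pd.Series(social)
    if k is None:
        k = social.nunique()
    rows = []
    for r in range(1, len(pool) + 1):
        for combo in itertools.combinations(pool, r):
            part = trait_kmeans(traits, combo, k=k, seed=rng)
            res = congruency_test(social, part, n_iter=n_iter, rng=rng, variables=combo)
            rows.append(
                {
                    "variables": combo,
                    "n_variables": r,
                    "ari": res.ari,
                    "p_value": res.p_value,
                    "significant": res.p_value <= alpha,
                }
            )
    out = pd.DataFrame(rows).sort_values("ari", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    sig = out[out["significant"]]
    importance = pd.Series(
        {
            v: (sig["variables"].apply(lambda c: v in c).mean() if len(sig) else 0.0)
            for v in pool
        },
        name="importance",
    )
    return out, importance


# ---------------------------------------------------------------------------
# Dyadic behavior transference
# ---------------------------------------------------------------------------

_TRANSFER_BEHAVIORS = ("bubble_net", "feed_other", "travel", "robust", "rest")


def _dyad_behavior_counts(encounters, behaviors):
    """Sparse dyad x encounter incidence and encounter x behavior indicators."""
    dyad_index = {}
    rows, cols = [], []
    enc_behavior = np.zeros((len(encounters), len(behaviors)), dtype=np.float64)
    for e_i, e in enumerate(encounters):
        members = sorted(e.member_ids)
        for bi, b in enumerate(behaviors):
            enc_behavior[e_i, bi] = float(b in e.behaviors)
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                key = (members[a_i], members[b_i])
                if key not in dyad_index:
                    dyad_index[key] = len(dyad_index)
                rows.append(dyad_index[key])
                cols.append(e_i)
    inc = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(dyad_index), len(encounters))
    )
    return dyad_index, inc, enc_behavior


def behavior_transference(
    encounters,
    behaviors=_TRANSFER_BEHAVIORS,
    dyad_min: int = 3,
    n_boot: int = 10000,
    n_null: int = 1000,
    rng=None,
) -> pd.DataFrame:
    """Bootstrap-differencing test of behavior transference between dyads.

    For dyads seen together on at least ``dyad_min`` occasions, each behavior
    splits the dyads into practitioners (at least one joint encounter with
    the behavior) and others. The statistic for a (primary, secondary) cell
    is the mean of the bootstrap distribution of differences in the
    secondary-behavior rate (one random practitioner minus one random other,
    ``n_boot`` draws). The null rebuilds the statistic after permuting the
    encounter-level behavior annotations (``n_null`` iterations, where the
    null statistic is the exact expectation of the same bootstrap). The
    returned p-value is the add-one fraction of null statistics at or below
    the observed one: p < 0.025 means practitioners are significantly *less*
    likely to share the secondary behavior, p > 0.975 significantly *more*.
    Untestable cells (an empty dyad group) are NaN. The matrix is genuinely
    asymmetric: primary behaviors are rows, secondary columns.
    """
    rng = as_rng(rng)
    behaviors = list(behaviors)
    dyad_index, inc, enc_behavior = _dyad_behavior_counts(encounters, behaviors)
    n_joint = np.asarray(inc.sum(axis=1)).ravel()
    keep = n_joint >= dyad_min
    if not keep.any():
        raise ValueError(f"no dyads seen together on >= {dyad_min} occasions")
    inc = inc[keep]
    n_joint = n_joint[keep]

    def stats_matrix(counts):
        """Mean difference practitioner-vs-other per (primary, secondary)."""
        rates = counts / n_joint[:, None]
        out = np.full((len(behaviors), len(behaviors)), np.nan)
        sizes = []
        for pi in range(len(behaviors)):
            prac = counts[:, pi] > 0
            other = ~prac
            sizes.append((int(prac.sum()), int(other.sum())))
            if not prac.any() or not other.any():
                continue
            for si in range(len(behaviors)):
                if si == pi:
                    continue
                out[pi, si] = rates[prac, si].mean() - rates[other, si].mean()
        return out, sizes

    counts_obs = inc @ enc_behavior
    exact_obs, sizes = stats_matrix(counts_obs)
    never_seen = counts_obs.sum(axis=0) == 0  # behavior absent among these dyads
    exact_obs[never_seen, :] = np.nan
    exact_obs[:, never_seen] = np.nan

    # observed statistic: literal bootstrap mean (n_boot paired draws)
    obs = np.full_like(exact_obs, np.nan)
    rates_obs = counts_obs / n_joint[:, None]
    for pi in range(len(behaviors)):
        prac = np.flatnonzero(counts_obs[:, pi] > 0)
        other = np.flatnonzero(counts_obs[:, pi] == 0)
        if prac.size == 0 or other.size == 0:
            continue
        a = prac[rng.integers(0, prac.size, size=n_boot)]
        b = other[rng.integers(0, other.size, size=n_boot)]
        for si in range(len(behaviors)):
            if si == pi:
                continue
            obs[pi, si] = float((rates_obs[a, si] - rates_obs[b, si]).mean())

    obs[never_seen, :] = np.nan
    obs[:, never_seen] = np.nan

    null = np.empty((n_null,) + exact_obs.shape)
    n_enc = enc_behavior.shape[0]
    for it in range(n_null):
        null[it] = stats_matrix(inc @ enc_behavior[rng.permutation(n_enc)])[0]

    p = np.full_like(exact_obs, np.nan)
    for pi in range(len(behaviors)):
        for si in range(len(behaviors)):
            if pi == si or np.isnan(obs[pi, si]):
                continue
            cell = null[:, pi, si]
            cell = cell[~np.isnan(cell)]
            if cell.size == 0:
                continue
            p[pi, si] = (np.sum(cell <= obs[pi, si]) + 1) / (cell.size + 1)

    out = pd.DataFrame(p, index=behaviors, columns=behaviors)
    out.attrs["group_sizes"] = dict(zip(behaviors, sizes))
    out.attrs["observed_mean_difference"] = pd.DataFrame(
        obs, index=behaviors, columns=behaviors
    )
    out.attrs["n_dyads"] = int(keep.sum())
    return out
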