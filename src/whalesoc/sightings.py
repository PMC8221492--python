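"""Photo-identification data model: sighting records, encounters, capture histories.

A *sampling occasion* is one calendar day of photo-identification effort. An
*encounter* is a unique observation of a unique group on one day: if a group of
identical composition is observed twice in a day it is kept once, but a
different member set seen later the same day is a separate encounter. The
capture history is the individuals x occasions binary matrix plus the per-day
group memberships, which is the substrate for every downstream estimator.
"""

from __future__ import annotations

import datetime as dt
import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BEHAVIORS",
    "SightingRecord",
    "Encounter",
    "CaptureHistory",
    "SchemaError",
    "RowError",
    "read_sightings",
    "write_sightings",
    "build_encounters",
    "build_capture_history",
    "restrict_history",
    "annual_summary",
    "annual_return_rate",
    "recapture_distribution",
    "load_printed_capture_table",
    "capture_table_stats",
]

#: Controlled behavior vocabulary. Unknown codes map to "other" with a warning.
BEHAVIORS = frozenset(
    {"bubble_net", "feed_other", "travel", "rest", "sleep", "robust", "social", "other"}
)

#: Default CSV column map (canonical field -> column name).
DEFAULT_SCHEMA = {
    "date": "date",
    "individual_id": "individual_id",
    "group_id": "group_id",
    "position_km": "position_km",
    "lat": "lat",
    "lon": "lon",
    "behaviors": "behaviors",
    "calf": "calf",
    "known_mother": "known_mother",
    "platform": "platform",
}


class SchemaError(ValueError):
    """A required column is missing from the input CSV."""


class RowError(ValueError):
    """One or more rows failed validation; the message lists line numbers."""


@dataclass(frozen=True)
class SightingRecord:
    """One photo-identification event of one individual."""

    date: dt.date
    individual_id: str
    group_id: str
    position_km: float | None = None
    lat: float | None = None
    lon: float | None = None
    behaviors: frozenset = frozenset()
    calf: bool = False
    known_mother: bool = False
    platform: str = "vessel"

    def __post_init__(self):
        if not self.individual_id:
            raise ValueError("individual_id must be non-empty")
        unknown = set(self.behaviors) - BEHAVIORS
        if unknown:
            raise ValueError(f"behaviors outside vocabulary: {sorted(unknown)}")


@dataclass(frozen=True)
class Encounter:
    """A unique observation of a unique group on one day."""

    group_id: str
    date: dt.date
    member_ids: frozenset
    behaviors: frozenset = frozenset()
    position_km: float | None = None
    calf: bool = False
    known_mother: bool = False

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class CaptureHistory:
    """Individuals x occasions capture matrix with per-day group memberships.

    ``seen[i, t]`` is True when individual ``individuals[i]`` was identified on
    occasion ``occasions[t]``. ``groups_by_day[t]`` lists the member-index
    arrays of the groups encountered that day.
    """

    individuals: list
    occasions: list
    seen: np.ndarray
    groups_by_day: list
    index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {ind: i for i, ind in enumerate(self.individuals)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def years(self) -> np.ndarray:
        return np.array([d.year for d in self.occasions])

    @property
    def day_numbers(self) -> np.ndarray:
        """Occasion dates as integer day counts (for lag arithmetic)."""
        return np.array([d.toordinal() for d in self.occasions])

    def capture_counts(self) -> np.ndarray:
        """Number of occasions on which each individual was identified."""
        return self.seen.sum(axis=1)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if pd.isna(v) or v == "":
        return False
    return str(v).strip().lower() in {"1", "true", "t", "yes", "y"}


def _parse_behaviors(v) -> frozenset:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return frozenset()
    codes = {c.strip() for c in str(v).split(";") if c.strip()}
    unknown = codes - BEHAVIORS
    if unknown:
        warnings.warn(f"unknown behavior codes mapped to 'other': {sorted(unknown)}")
        codes = (codes & BEHAVIORS) | {"other"}
    return frozenset(codes)


def read_sightings(path, schema: dict | None = None) -> list:
    """Read a sighting-record CSV into chronologically sorted records.

    ``schema`` maps canonical field names to the file's column names (fields
    absent from the map or the file are left at their defaults). ``date`` and
    ``individual_id`` are required. Malformed rows are collected and raised as
    a single :class:`RowError` listing line numbers (header = line 1).
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype=str)
    for required in ("date", "individual_id"):
        if colmap[required] not in df.columns:
            raise SchemaError(f"required column {colmap[required]!r} missing from {path}")

    records, errors = [], []
    have = {f: c for f, c in colmap.items() if c in df.columns}
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        raw = dict(zip(df.columns, row))
        try:
            date = dt.date.fromisoformat(str(raw[have["date"]]).strip())
        except (ValueError, TypeError):
            errors.append(f"line {line}: unparseable date {raw[have['date']]!r}")
            continue
        ind = raw[have["individual_id"]]
        ind = "" if pd.isna(ind) else str(ind).strip()
        if not ind:
            errors.append(f"line {line}: empty individual_id")
            continue

        def _get(f, default=None):
            if f not in have:
                return default
            v = raw[have[f]]
            return default if (v is None or (isinstance(v, float) and np.isnan(v)) or v == "" or pd.isna(v)) else v

        def _float(f):
            v = _get(f)
            if v is None:
                return None
            try:
                return float(v)
            except ValueError:
                errors.append(f"line {line}: non-numeric {f} {v!r}")
                return None

        records.append(
            SightingRecord(
                date=date,
                individual_id=ind,
                group_id=str(_get("group_id", f"enc{line}")),
                position_km=_float("position_km"),
                lat=_float("lat"),
                lon=_float("lon"),
                behaviors=_parse_behaviors(_get("behaviors")),
                calf=_parse_bool(_get("calf", False)),
                known_mother=_parse_bool(_get("known_mother", False)),
                platform=str(_get("platform", "vessel")),
            )
        )
    if errors:
        raise RowError("malformed rows:\n" + "\n".join(errors))
    records.sort(key=lambda r: r.date)
    return records


def write_sightings(records, path) -> None:
    """Write records to CSV in the default schema (round-trips with read)."""
    rows = [
        {
            "date": r.date.isoformat(),
            "individual_id": r.individual_id,
            "group_id": r.group_id,
            "position_km": r.position_km,
            "lat": r.lat,
            "lon": r.lon,
            "behaviors": ";".join(sorted(r.behaviors)),
            "calf": r.calf,
            "known_mother": r.known_mother,
            "platform": r.platform,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Encounters and capture histories
# ---------------------------------------------------------------------------


def build_encounters(records) -> list:
    """Collapse records into encounters, deduplicating same-day identical groups.

    Records sharing (date, group_id) form one observed group. Two observations
    of the same member set on the same day collapse to one encounter; a
    different member set on the same day is kept as a separate encounter.
    """
    by_group: dict = {}
    order = []
    for r in records:
        key = (r.date, r.group_id)
        if key not in by_group:
            by_group[key] = []
            order.append(key)
        by_group[key].append(r)

    encounters, seen_comp = [], set()
    for key in order:
        grp = by_group[key]
        members = frozenset(g.individual_id for g in grp)
        comp_key = (key[0], members)
        if comp_key in seen_comp:
            continue
        seen_comp.add(comp_key)
        behaviors = frozenset().union(*(g.behaviors for g in grp))
        positions = [g.position_km for g in grp if g.position_km is not None]
        encounters.append(
            Encounter(
                group_id=key[1],
                date=key[0],
                member_ids=members,
                behaviors=behaviors,
                position_km=float(np.mean(positions)) if positions else None,
                calf=any(g.calf for g in grp),
                known_mother=any(g.known_mother for g in grp),
            )
        )
    return encounters


def build_capture_history(records=None, encounters=None) -> CaptureHistory:
    """Build the capture matrix and per-day groups from records or encounters."""
    if encounters is None:
        if records is None:
            raise ValueError("provide records or encounters")
        encounters = build_encounters(records)
    if not encounters:
        raise ValueError("no encounters")
    occasions = sorted({e.date for e in encounters})
    day_idx = {d: t for t, d in enumerate(occasions)}
    individuals = sorted({m for e in encounters for m in e.member_ids})
    ind_idx = {ind: i for i, ind in enumerate(individuals)}
    seen = np.zeros((len(individuals), len(occasions)), dtype=bool)
    groups_by_day: list = [[] for _ in occasions]
    for e in encounters:
        t = day_idx[e.date]
        idx = np.array(sorted(ind_idx[m] for m in e.member_ids), dtype=np.intp)
        groups_by_day[t].append(idx)
        seen[idx, t] = True
    return CaptureHistory(individuals, occasions, seen, groups_by_day)


def restrict_history(history: CaptureHistory, years=None, individuals=None,
                     min_sightings: int = 1) -> CaptureHistory:
    """Sub-history by year range and/or individual subset.

    ``min_sightings`` is applied after the year restriction, so running-window
    analyses qualify individuals on within-window effort.
    """
    occ_mask = np.ones(history.n_occasions, dtype=bool)
    if years is not None:
        yrs = set(years)
        occ_mask = np.array([d.year in yrs for d in history.occasions])
    keep_t = np.flatnonzero(occ_mask)
    seen = history.seen[:, keep_t]
    ind_mask = seen.sum(axis=1) >= min_sightings
    if individuals is not None:
        wanted = {history.index[i] for i in individuals if i in history.index}
        ind_mask &= np.isin(np.arange(history.n_individuals), sorted(wanted))
    keep_i = np.flatnonzero(ind_mask)
    remap = -np.ones(history.n_individuals, dtype=np.intp)
    remap[keep_i] = np.arange(keep_i.size)
    groups = []
    for t in keep_t:
        day = []
        for g in history.groups_by_day[t]:
            gg = remap[g]
            gg = gg[gg >= 0]
            if gg.size:
                day.append(gg)
        groups.append(day)
    new_inds = [history.individuals[i] for i in keep_i]
    new_seen = seen[keep_i]
    # drop occasions left with no identifications after the individual cut
    occ_keep = new_seen.any(axis=0)
    return CaptureHistory(
        new_inds,
        [history.occasions[t] for t, k in zip(keep_t, occ_keep) if k],
        new_seen[:, occ_keep],
        [g for g, k in zip(groups, occ_keep) if k],
    )


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------


def annual_summary(history: CaptureHistory) -> pd.DataFrame:
    """Per-year capture summary: identifications, recaptures and their rates.

    Columns mirror a standard capture-history table: total identifications
    (individual-day captures), unique individuals, new individuals, and three
    recapture measures -- within-season (identifications of individuals already
    seen that season, as a share of total identifications), prior-year
    (individuals also seen the previous year, as a share of unique), and
    any-prior-year (individuals seen in any earlier year, as a share of unique).
    """
    if history.n_occasions == 0:
        raise ValueError("empty capture history")
    years = history.years
    uniq_years = np.unique(years)
    seen_in_year = {y: history.seen[:, years == y].any(axis=1) for y in uniq_years}
    ever_before = np.zeros(history.n_individuals, dtype=bool)
    prev_mask = None
    rows = []
    for y in uniq_years:
        mask = seen_in_year[y]
        total = int(history.seen[:, years == y].sum())
        unique = int(mask.sum())
        within_n = total - unique
        prior_n = int((mask & prev_mask).sum()) if prev_mask is not None else np.nan
        anyprior_n = int((mask & ever_before).sum())
        new = unique - anyprior_n
        rows.append(
            {
                "year": int(y),
                "total_ids": total,
                "unique_ids": unique,
                "new_ids": new,
                "within_season_n": within_n,
                "within_season_pct": 100.0 * within_n / total if total else np.nan,
                "prior_year_n": prior_n,
                "prior_year_pct": 100.0 * prior_n / unique if prev_mask is not None else np.nan,
                "any_prior_n": anyprior_n if prev_mask is not None else np.nan,
                "any_prior_pct": 100.0 * anyprior_n / unique if prev_mask is not None else np.nan,
            }
        )
        ever_before |= mask
        prev_mask = mask
    return pd.DataFrame(rows).set_index("year")


def annual_return_rate(history: CaptureHistory, include_first_year: bool = False) -> pd.Series:
    """Annual return rate: prior-year recaptures / unique individuals per year.

    With ``include_first_year`` the first season contributes a zero (the
    convention under which the multi-year mean drops by a few points).
    """
    summ = annual_summary(history)
    rate = summ["prior_year_pct"] / 100.0
    if include_first_year:
        rate = rate.fillna(0.0)
    else:
        rate = rate.dropna()
    return rate


def recapture_distribution(history: CaptureHistory) -> pd.DataFrame:
    """Cumulative recapture counts: individuals seen in >=k years / >=m occasions.

    Returns a frame indexed by threshold ``k`` with columns ``n_ge_years``
    (count of individuals seen in at least k distinct years) and
    ``n_ge_occasions`` (seen on at least k sampling occasions); both columns
    are non-increasing and anchored at the identified population size.
    """
    years = history.years
    uniq_years = np.unique(years)
    years_seen = np.zeros(history.n_individuals, dtype=int)
    for y in uniq_years:
        years_seen += history.seen[:, years == y].any(axis=1)
    occ_seen = history.capture_counts()
    kmax = max(int(occ_seen.max()), len(uniq_years))
    ks = np.arange(1, kmax + 1)
    return pd.DataFrame(
        {
            "n_ge_years": [(years_seen >= k).sum() for k in ks],
            "n_ge_occasions": [(occ_seen >= k).sum() for k in ks],
        },
        index=pd.Index(ks, name="k"),
    )


# ---------------------------------------------------------------------------
# Published capture-table helpers
# ---------------------------------------------------------------------------


def load_printed_capture_table() -> pd.DataFrame:
    """Load the published 16-season Kitimat Fjord System capture-history table.

    These are the printed per-year summary rows (photo-ID totals and recapture
    percentages, 2004-2019) shipped as package data; they serve as a fixed
    reference input for summary arithmetic.
    """
    with importlib.resources.files("whalesoc.data").joinpath("kfs_capture_table.csv").open() as f:
        return pd.read_csv(f).set_index("year")


def capture_table_stats(table: pd.DataFrame) -> dict:
    """Column statistics of an annual capture table (means/SDs of recapture rates).

    Returns within-season recapture mean and SD, prior-year recapture mean, and
    the maximum annual (prior-year) return, all in percent. SDs are sample SDs
    (ddof=1), matching the convention of summary rows in capture tables.
    """
    within = table["within_season_pct"].dropna().astype(float)
    prior = table["prior_year_pct"].dropna().astype(float)
    return {
        "within_season_mean_pct": float(within.mean()),
        "within_season_sd_pct": float(within.std(ddof=1)),
        "prior_year_mean_pct": float(prior.mean()),
        "max_annual_return_pct": float(prior.max()),
    }
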