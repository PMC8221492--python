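"""Shared fixtures: hand-built toy histories and a mid-sized synthetic study."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

import whalesoc as ws


def history_from_days(day_groups):
    """Build a CaptureHistory from a {date: [group-member-lists]} mapping."""
    records = []
    for date, groups in day_groups.items():
        for gi, members in enumerate(groups):
            for m in members:
                records.append(
                    ws.SightingRecord(date=date, individual_id=m, group_id=f"{date}g{gi}")
                )
    return ws.build_capture_history(records)


def d(day: int, year: int = 2010) -> dt.date:
    """Day-of-season shorthand: season starts June 1."""
    return dt.date(year, 6, 1) + dt.timedelta(days=day - 1)


@pytest.fixture(scope="session")
def toy_history():
    """Five days, five individuals, known by hand.

    Day 1: (A,B), (C);  Day 2: (A,B,C);  Day 3: (D,) (A);  Day 4: (A,B), (C,D);
    Day 5: (E,), (A,C).
    """
    return history_from_days(
        {
            d(1): [["A", "B"], ["C"]],
            d(2): [["A", "B", "C"]],
            d(3): [["D"], ["A"]],
            d(4): [["A", "B"], ["C", "D"]],
            d(5): [["E"], ["A", "C"]],
        }
    )


@pytest.fixture(scope="session")
def synthetic_study():
    """A moderately sized planted-community study used across modules."""
    cfg = ws.SimConfig(n_individuals=60, years=3, days_per_season=40, seed=11)
    records, truth = ws.simulate(cfg)
    encounters = ws.build_encounters(records)
    history = ws.build_capture_history(encounters=encounters)
    return {
        "config": cfg,
        "records": records,
        "truth": truth,
        "encounters": encounters,
        "history": history,
    }


@pytest.fixture(scope="session")
def synthetic_dyads(synthetic_study):
    return ws.sri_matrix(synthetic_study["history"], min_sightings=5)
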