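"""Shared fixtures: hand-built report databases and a two-drug demographic
fixture with known strata counts (generated programmatically, no data files)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pvsignals import (
    HierarchyMap,
    ReportRecord,
    SyntheticConfig,
    build_database,
)


def make_db(triples, hierarchy=None):
    """Build a database from (report_id, drugs, events) triples (demographics
    default to unknown)."""
    records = [
        ReportRecord(report_id=rid, drugs=frozenset(drugs), events=frozenset(events))
        for rid, drugs, events in triples
    ]
    if hierarchy is None:
        pts = sorted({e for _, _, evs in triples for e in evs})
        hierarchy = HierarchyMap({pt: "S1" for pt in pts})
    return build_database(records, hierarchy)


@pytest.fixture
def tiny_db():
    """Four reports: {D,E}, {D}, {E}, {X} -> (a,b,c,d) = (1,1,1,1) for (D,E)."""
    return make_db(
        [
            ("r1", ["D"], ["E"]),
            ("r2", ["D"], ["F"]),
            ("r3", ["X"], ["E"]),
            ("r4", ["X"], ["F"]),
        ]
    )


# --- two-drug demographic fixture with exact strata counts -----------------

#: Strata counts for the synthetic two-drug demographic fixture (drug A has
#: 1572 reports, drug B 485; axes are independent marginals).
DEMO_A = {
    "sex": {"female": 633, "male": 902, "unknown": 37},
    "age_band": {
        "0-27 days": 5, "28 days-23 months": 2, "2-11 years": 5, "12-17 years": 9,
        "18-44 years": 142, "45-64 years": 465, "65-74 years": 465,
        ">=75 years": 395, "unknown": 84,
    },
    "region": {"Africa": 0, "Americas": 2, "Asia": 1567, "Europe": 2, "Oceania": 1, "unknown": 0},
}
DEMO_B = {
    "sex": {"female": 229, "male": 206, "unknown": 50},
    "age_band": {
        "0-27 days": 2, "28 days-23 months": 5, "2-11 years": 15, "12-17 years": 4,
        "18-44 years": 170, "45-64 years": 112, "65-74 years": 39,
        ">=75 years": 34, "unknown": 104,
    },
    "region": {"Africa": 4, "Americas": 215, "Asia": 55, "Europe": 196, "Oceania": 15, "unknown": 0},
}


def _expand(counts: dict[str, int]) -> list[str]:
    out: list[str] = []
    for label, n in counts.items():
        out.extend([label] * n)
    return out


def demographic_frame() -> pd.DataFrame:
    """Long line-list rows for the two-drug demographic fixture: one row per
    report, single event PT, axes assigned independently by position."""
    rows = []
    rid = 0
    for drug, demo in (("DRUG_A", DEMO_A), ("DRUG_B", DEMO_B)):
        sexes = _expand(demo["sex"])
        ages = _expand(demo["age_band"])
        regions = _expand(demo["region"])
        assert len(sexes) == len(ages) == len(regions)
        for sex, age, region in zip(sexes, ages, regions):
            rid += 1
            rows.append(
                {
                    "report_id": f"r{rid:05d}",
                    "drug": drug,
                    "pt": "P1",
                    "sex": sex,
                    "age_band": age,
                    "region": region,
                    "year": 2024,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def demographic_line_list(tmp_path_factory):
    """The fixture written as a CSV line list plus its one-PT hierarchy."""
    d = tmp_path_factory.mktemp("demo_fixture")
    line_list = d / "line_list.csv"
    hierarchy = d / "hierarchy.csv"
    demographic_frame().to_csv(line_list, index=False)
    pd.DataFrame({"pt": ["P1"], "soc": ["S1"]}).to_csv(hierarchy, index=False)
    return line_list, hierarchy


def small_random_config(seed: int, n_reports: int = 200) -> SyntheticConfig:
    """A small random multi-drug scenario for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    drugs = [f"D{i}" for i in range(1, 6)]
    pts = [f"P{i}" for i in range(1, 13)]
    dw = rng.dirichlet(np.ones(len(drugs)))
    pw = rng.dirichlet(np.ones(len(pts)))
    return SyntheticConfig(
        n_reports=n_reports,
        drug_freqs=dict(zip(drugs, dw.tolist())),
        event_freqs=dict(zip(pts, pw.tolist())),
        seed=seed,
    )
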