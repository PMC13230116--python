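"""2x2 contingency tables for drug-event pairs.

For a target drug D and target event E in a database of N spontaneous
reports the table is::

              event E    not E
    drug D       a         b      (a+b reports with the drug)
    other        c         d      (c+d reports without it)

Counting is report-level: a report contributes at most 1 to any cell, even
if it mentions the drug together with several qualifying PTs.  The
comparator is all other reports in the supplied database; restricting the
database restricts the comparator.

At SOC level an event "occurs" in a report when the report carries at least
one PT whose primary SOC is the target (occurrence-denominator percentages
live in :mod:`pvsignals.descriptives`, not here).
"""

from __future__ import annotations

from dataclasses import dataclass

from .report_model import ReportDatabase

LEVELS = ("pt", "soc")


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts a, b, c, d of one drug-event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table must describe at least one report")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        """Reports containing the drug (a+b)."""
        return self.a + self.b

    @property
    def n_event(self) -> int:
        """Reports containing the event (a+c)."""
        return self.a + self.c

    @property
    def expected(self) -> float:
        """Expected count E = (a+b)(a+c)/N under independence."""
        return self.n_drug * self.n_event / self.n

    def transpose(self) -> "ContingencyTable":
        """Swap the roles of drug and event: (a,b,c,d) -> (a,c,b,d)."""
        return ContingencyTable(self.a, self.c, self.b, self.d)


def _event_report_ids(db: ReportDatabase, event: str, level: str) -> set[str]:
    if level == "pt":
        return db.pt_index.get(event, set())
    # soc: union of the report sets of every PT whose primary SOC matches
    ids: set[str] = set()
    for pt, soc in db.hierarchy.pt_to_soc.items():
        if soc == event:
            ids |= db.pt_index.get(pt, set())
    return ids


def build_table(db: ReportDatabase, drug: str, event: str, level: str = "pt") -> ContingencyTable:
    """Build the 2x2 table for one drug-event pair.

    ``level`` selects whether ``event`` is a PT code or a SOC code (PT codes
    resolved through the database hierarchy).  Codes absent from the
    database are valid and simply yield zero margins.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    n = db.n_reports
    drug_ids = db.reports_for_drug(drug)
    event_ids = _event_report_ids(db, event, level)
    a = len(drug_ids & event_ids)
    b = len(drug_ids) - a
    c = len(event_ids) - a
    d = n - a - b - c
    return ContingencyTable(a, b, c, d)


def all_pairs(db: ReportDatabase, drug: str, level: str = "pt") -> list[tuple[str, ContingencyTable]]:
    """One (event, table) pair per event code observed anywhere in ``db``.

    At PT level the sum over events of ``a`` equals the drug's total
    (report, PT) pair count; at SOC level events are the hierarchy's SOCs
    observed in the database.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if level == "pt":
        events = db.pts()
    else:
        observed = {
            soc
            for pt, soc in db.hierarchy.pt_to_soc.items()
            if pt in db.pt_index
        }
        events = sorted(observed)
    return [(ev, build_table(db, drug, ev, level)) for ev in events]


def export_tables(pairs: list[tuple[str, ContingencyTable]], path, delimiter: str = ",") -> None:
    """Write (event, a, b, c, d) rows as delimited text."""
    import pandas as pd

    pd.DataFrame(
        [(ev, t.a, t.b, t.c, t.d) for ev, t in pairs],
        columns=["event", "a", "b", "c", "d"],
    ).to_csv(path, sep=delimiter, index=False)
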