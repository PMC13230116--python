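"""Descriptive summaries of a spontaneous-report database.

Frequency tables with percentages for one drug's reports:

* :func:`demographics` — report counts per sex / age-band / region / year
  stratum (report denominator);
* :func:`soc_distribution` — adverse-event distribution over system organ
  classes, on either the occurrence denominator (report-PT pairs, default)
  or the distinct-report denominator;
* :func:`pt_frequency` — top-k preferred terms by report count, percentages
  on the occurrence denominator.

Percentages are printed at 2 decimal places with half-up rounding, the
convention of published report summaries; the denominator used is always
echoed in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .report_model import AGE_BANDS, REGIONS, SEX_CATEGORIES, ReportDatabase, UNKNOWN

DENOMINATORS = ("reports", "occurrences")
AXES = ("sex", "age_band", "region", "year")


def round_half_up(x: float, places: int = 2) -> float:
    """Decimal half-up rounding (5 rounds away from zero), unlike the
    banker's rounding of the built-in ``round``."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FrequencyTable:
    """Stratum counts and 2-dp percentages for one drug and one axis."""

    axis: str
    drug: str
    labels: list[str]
    counts: list[int]
    denominator: str = "reports"
    total: int = 0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.denominator not in DENOMINATORS:
            raise ValueError(f"unknown denominator {self.denominator!r}")
        if self.total == 0:
            self.total = sum(self.counts)

    @property
    def percentages(self) -> list[float]:
        if self.total == 0:
            return [0.0 for _ in self.counts]
        return [round_half_up(100.0 * c / self.total) for c in self.counts]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.labels,
                "count": self.counts,
                "percent": self.percentages,
                "denominator": self.denominator,
                "total": self.total,
            }
        )

    def export(self, path: str | Path, delimiter: str = ",") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)

    def as_dict(self) -> dict[str, tuple[int, float]]:
        return dict(zip(self.labels, zip(self.counts, self.percentages)))


def demographics(db: ReportDatabase, drug: str) -> dict[str, FrequencyTable]:
    """Per-axis report counts and percentages for one drug.

    Each axis (sex, age band, region, year) is an independent marginal of
    the same report set, so every axis total equals the drug's report
    count.  Unknown strata are tabulated, never dropped; the year axis
    lists only observed years (plus unknown if present).  An absent drug
    yields empty tables with a zero denominator flagged in ``warnings``.
    """
    ids = db.reports_for_drug(drug)
    recs = [r for r in db.records if r.report_id in ids]
    total = len(recs)
    warnings = [] if total else [f"drug {drug!r} has no reports in this database"]
    out: dict[str, FrequencyTable] = {}

    fixed_axes = {
        "sex": (SEX_CATEGORIES, lambda r: r.sex),
        "age_band": (AGE_BANDS, lambda r: r.age_band),
        "region": (REGIONS, lambda r: r.region),
    }
    for axis, (cats, getter) in fixed_axes.items():
        counts = {c: 0 for c in cats}
        for r in recs:
            counts[getter(r)] += 1
        out[axis] = FrequencyTable(
            axis=axis,
            drug=drug,
            labels=list(cats),
            counts=[counts[c] for c in cats],
            denominator="reports",
            total=total,
            warnings=list(warnings),
        )

    year_counts: dict[str, int] = {}
    for r in recs:
        label = UNKNOWN if r.year is None else str(r.year)
        year_counts[label] = year_counts.get(label, 0) + 1
    year_labels = sorted((y for y in year_counts if y != UNKNOWN), key=int)
    if UNKNOWN in year_counts:
        year_labels.append(UNKNOWN)
    out["year"] = FrequencyTable(
        axis="year",
        drug=drug,
        labels=year_labels,
        counts=[year_counts[y] for y in year_labels],
        denominator="reports",
        total=total,
        warnings=list(warnings),
    )
    return out


def _drug_records(db: ReportDatabase, drug: str):
    ids = db.reports_for_drug(drug)
    return [r for r in db.records if r.report_id in ids]


def soc_distribution(
    db: ReportDatabase, drug: str, denominator: str = "occurrences"
) -> FrequencyTable:
    """Adverse-event distribution over SOCs for one drug.

    In ``occurrences`` mode (default) the counts are report-PT pairs
    aggregated by the PT's primary SOC and the denominator is the drug's
    total report-PT pair count, so SOC counts equal the sum of PT-level
    ``a`` values within the SOC.  In ``reports`` mode counts are distinct
    reports with at least one PT in the SOC (these can overlap, so they may
    sum above the report total).  PTs that do not resolve through the
    hierarchy are excluded, listed in ``warnings`` and never silently
    dropped.
    """
    if denominator not in DENOMINATORS:
        raise ValueError(f"unknown denominator {denominator!r}")
    recs = _drug_records(db, drug)
    unresolved: set[str] = set()
    warnings: list[str] = []
    soc_counts: dict[str, int] = {}
    total = 0
    if denominator == "occurrences":
        for r in recs:
            for pt in r.events:
                soc = db.hierarchy.soc_of(pt)
                if soc is None:
                    unresolved.add(pt)
                    continue
                soc_counts[soc] = soc_counts.get(soc, 0) + 1
                total += 1
    else:
        for r in recs:
            socs = set()
            for pt in r.events:
                soc = db.hierarchy.soc_of(pt)
                if soc is None:
                    unresolved.add(pt)
                else:
                    socs.add(soc)
            for soc in socs:
                soc_counts[soc] = soc_counts.get(soc, 0) + 1
        total = len(recs)
    if unresolved:
        warnings.append(f"unresolved PTs excluded: {sorted(unresolved)}")
    labels = sorted(soc_counts, key=lambda s: (-soc_counts[s], s))
    return FrequencyTable(
        axis="soc",
        drug=drug,
        labels=labels,
        counts=[soc_counts[s] for s in labels],
        denominator=denominator,
        total=total,
        warnings=warnings,
    )


def pt_frequency(db: ReportDatabase, drug: str, k: int = 50) -> FrequencyTable:
    """Top-k PTs for one drug, ranked by report count descending (ties
    alphabetical), percentages on the occurrence denominator (total
    report-PT pairs for the drug)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    recs = _drug_records(db, drug)
    pt_counts: dict[str, int] = {}
    total = 0
    for r in recs:
        for pt in r.events:
            pt_counts[pt] = pt_counts.get(pt, 0) + 1
            total += 1
    ranked = sorted(pt_counts, key=lambda p: (-pt_counts[p], p))[:k]
    return FrequencyTable(
        axis="pt",
        drug=drug,
        labels=ranked,
        counts=[pt_counts[p] for p in ranked],
        denominator="occurrences",
        total=total,
    )
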