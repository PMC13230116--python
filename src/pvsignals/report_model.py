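"""Record-level data model for spontaneous adverse-event report databases.

Public pharmacovigilance front-ends (e.g. WHO VigiAccess) expose only
aggregated counts, but every disproportionality analysis presupposes a
record-level database: one report carrying one or more suspected drugs, one
or more adverse-event preferred terms (PTs), and report-level demographics.
This module defines that canonical schema, readers/writers for a long-format
delimited line list (one row per report-drug-event triple), and a validated
PT -> system-organ-class (SOC) hierarchy map emulating the two MedDRA levels
the analysis needs.

Conventions:

* codes are matched case-sensitively after whitespace trimming (controlled
  vocabulary semantics);
* missing demographics are the first-class category ``"unknown"``, never
  dropped, because report summaries tabulate unknown strata explicitly;
* demographics attach to the report, not to the drug-event pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("pvsignals")

#: Closed category sets for report demographics.  Age bands follow the
#: conventional paediatric/adult partition used by WHO spontaneous-report
#: summaries; "unknown" is a first-class stratum on every axis.
SEX_CATEGORIES = ("female", "male", "unknown")
AGE_BANDS = (
    "0-27 days",
    "28 days-23 months",
    "2-11 years",
    "12-17 years",
    "18-44 years",
    "45-64 years",
    "65-74 years",
    ">=75 years",
    "unknown",
)
REGIONS = ("Africa", "Americas", "Asia", "Europe", "Oceania", "unknown")

UNKNOWN = "unknown"

#: Mandatory line-list columns; demographic columns are optional.
MANDATORY_COLUMNS = ("report_id", "drug", "pt")
DEMOGRAPHIC_COLUMNS = ("sex", "age_band", "region", "year")


class SchemaError(ValueError):
    """A line list or hierarchy file violates the expected schema."""


@dataclass(frozen=True)
class ReportRecord:
    """One spontaneous report: drugs, event PTs and report demographics.

    ``year`` is an integer calendar year, or ``None`` when unknown.
    """

    report_id: str
    drugs: frozenset[str]
    events: frozenset[str]
    sex: str = UNKNOWN
    age_band: str = UNKNOWN
    region: str = UNKNOWN
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.report_id or not str(self.report_id).strip():
            raise ValueError("report_id must be non-blank")
        if not self.drugs or any(not d.strip() for d in self.drugs):
            raise ValueError(f"report {self.report_id}: drugs must be non-empty, non-blank")
        if not self.events or any(not e.strip() for e in self.events):
            raise ValueError(f"report {self.report_id}: events must be non-empty, non-blank")
        if self.sex not in SEX_CATEGORIES:
            raise ValueError(f"report {self.report_id}: invalid sex {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"report {self.report_id}: invalid age_band {self.age_band!r}")
        if self.region not in REGIONS:
            raise ValueError(f"report {self.report_id}: invalid region {self.region!r}")


@dataclass(frozen=True)
class HierarchyMap:
    """PT -> SOC mapping (each PT has exactly one primary SOC).

    Optional display-name dictionaries may decorate the codes.
    """

    pt_to_soc: Mapping[str, str]
    soc_names: Mapping[str, str] = field(default_factory=dict)
    pt_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pt, soc in self.pt_to_soc.items():
            if not str(soc).strip():
                raise ValueError(f"PT {pt!r} maps to an empty SOC")

    @property
    def socs(self) -> frozenset[str]:
        return frozenset(self.pt_to_soc.values())

    def soc_of(self, pt: str) -> str | None:
        return self.pt_to_soc.get(pt)

    def __len__(self) -> int:
        return len(self.pt_to_soc)


@dataclass
class ReportDatabase:
    """A collection of merged reports plus the PT->SOC hierarchy.

    ``unresolved_pts`` collects event codes that do not resolve through the
    hierarchy; they are reported, never silently dropped.
    """

    records: list[ReportRecord]
    hierarchy: HierarchyMap
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate report_id in database")
        self._index = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_reports(self) -> int:
        return len(self.records)

    @property
    def unresolved_pts(self) -> frozenset[str]:
        known = set(self.hierarchy.pt_to_soc)
        seen: set[str] = set()
        for r in self.records:
            seen.update(r.events)
        return frozenset(seen - known)

    # --- membership indexes (built once, used by contingency/descriptives) ---

    def _build_index(self) -> None:
        drug_index: dict[str, set[str]] = {}
        pt_index: dict[str, set[str]] = {}
        for r in self.records:
            for d in r.drugs:
                drug_index.setdefault(d, set()).add(r.report_id)
            for e in r.events:
                pt_index.setdefault(e, set()).add(r.report_id)
        self._index = (drug_index, pt_index)

    @property
    def drug_index(self) -> dict[str, set[str]]:
        """Drug code -> set of report_ids mentioning it."""
        if self._index is None:
            self._build_index()
        return self._index[0]

    @property
    def pt_index(self) -> dict[str, set[str]]:
        """PT code -> set of report_ids mentioning it."""
        if self._index is None:
            self._build_index()
        return self._index[1]

    def reports_for_drug(self, drug: str) -> set[str]:
        return self.drug_index.get(drug, set())

    def drugs(self) -> list[str]:
        return sorted(self.drug_index)

    def pts(self) -> list[str]:
        return sorted(self.pt_index)


def _clean(value: object) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip()


def _parse_year(value: object) -> int | None:
    s = _clean(value)
    if not s or s.lower() == UNKNOWN:
        return None
    try:
        return int(float(s))
    except ValueError as exc:
        raise SchemaError(f"unparseable year value {s!r}") from exc


def _norm_category(value: object, allowed: tuple[str, ...], column: str) -> str:
    s = _clean(value)
    if not s:
        return UNKNOWN
    if s not in allowed:
        raise SchemaError(f"invalid {column} value {s!r}; allowed: {allowed}")
    return s


def read_line_list(
    path: str | Path,
    hierarchy: HierarchyMap | None = None,
    delimiter: str | None = None,
    provenance: str = "",
) -> ReportDatabase:
    """Read a long-format line list into a merged :class:`ReportDatabase`.

    Rows sharing ``report_id`` are merged into one record whose drug and
    event sets are the unions of the rows'.  Demographics are taken from the
    first non-missing value per report; missing demographics become
    ``"unknown"``.  Exact duplicate (report_id, drug, pt) rows are
    deduplicated with a logged warning count.

    Parameters
    ----------
    path:
        Delimited text file with header; mandatory columns ``report_id``,
        ``drug``, ``pt``; optional ``sex``, ``age_band``, ``region``,
        ``year``.  Comma delimiter by default, tab accepted (or pass
        ``delimiter`` explicitly).
    hierarchy:
        PT->SOC map attached to the database (an empty map if omitted).
    """
    path = Path(path)
    if delimiter is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"line list {path} is missing mandatory column(s): {', '.join(missing)}")

    n_rows = len(df)
    for col in MANDATORY_COLUMNS:
        df[col] = df[col].map(_clean)
    blank = (df[list(MANDATORY_COLUMNS)] == "").any(axis=1)
    if blank.any():
        raise SchemaError(f"{int(blank.sum())} row(s) have blank report_id/drug/pt")

    before = len(df)
    df = df.drop_duplicates(subset=list(MANDATORY_COLUMNS))
    n_dup = before - len(df)
    if n_dup:
        logger.warning("deduplicated %d duplicate (report_id, drug, pt) row(s)", n_dup)

    records: list[ReportRecord] = []
    for report_id, grp in df.groupby("report_id", sort=False):
        first = grp.iloc[0]
        records.append(
            ReportRecord(
                report_id=str(report_id),
                drugs=frozenset(grp["drug"]),
                events=frozenset(grp["pt"]),
                sex=_norm_category(first.get("sex"), SEX_CATEGORIES, "sex"),
                age_band=_norm_category(first.get("age_band"), AGE_BANDS, "age_band"),
                region=_norm_category(first.get("region"), REGIONS, "region"),
                year=_parse_year(first.get("year")),
            )
        )
    logger.info("read %d rows -> %d merged reports from %s", n_rows, len(records), path)
    db = ReportDatabase(
        records=records,
        hierarchy=hierarchy if hierarchy is not None else HierarchyMap({}),
        provenance=provenance or str(path),
    )
    return db


def write_line_list(db: ReportDatabase, path: str | Path, delimiter: str = ",") -> None:
    """Write a database back to the long line-list format (one row per
    report-drug-event triple, demographics repeated on each row)."""
    rows = []
    for r in db.records:
        for d in sorted(r.drugs):
            for e in sorted(r.events):
                rows.append(
                    {
                        "report_id": r.report_id,
                        "drug": d,
                        "pt": e,
                        "sex": r.sex,
                        "age_band": r.age_band,
                        "region": r.region,
                        "year": "" if r.year is None else r.year,
                    }
                )
    pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS) + list(DEMOGRAPHIC_COLUMNS)).to_csv(
        path, sep=delimiter, index=False
    )


def read_hierarchy(path: str | Path, delimiter: str | None = None) -> HierarchyMap:
    """Read a two-column (pt, soc) delimited file into a :class:`HierarchyMap`.

    A PT listed under two different SOCs is a hard error naming the PT: the
    primary-SOC assignment must be a function.
    """
    path = Path(path)
    if delimiter is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    if "pt" not in cols or "soc" not in cols:
        raise SchemaError(f"hierarchy file {path} must have columns 'pt' and 'soc'")
    df.columns = cols
    mapping: dict[str, str] = {}
    for pt, soc in zip(df["pt"].map(_clean), df["soc"].map(_clean)):
        if not pt or not soc:
            raise SchemaError("blank pt or soc entry in hierarchy file")
        if pt in mapping and mapping[pt] != soc:
            raise SchemaError(f"PT {pt!r} is mapped to two SOCs: {mapping[pt]!r} and {soc!r}")
        mapping[pt] = soc
    return HierarchyMap(pt_to_soc=mapping)


def write_hierarchy(hierarchy: HierarchyMap, path: str | Path, delimiter: str = ",") -> None:
    pd.DataFrame(
        sorted(hierarchy.pt_to_soc.items()), columns=["pt", "soc"]
    ).to_csv(path, sep=delimiter, index=False)


def build_database(
    records: Iterable[ReportRecord],
    hierarchy: HierarchyMap | None = None,
    provenance: str = "",
) -> ReportDatabase:
    """Assemble a database directly from records (in-memory path)."""
    return ReportDatabase(
        records=list(records),
        hierarchy=hierarchy if hierarchy is not None else HierarchyMap({}),
        provenance=provenance,
    )
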