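"""Threshold screening, signal ranking and table inversion.

A drug-event pair is a *joint signal* when all four algorithms flag it
simultaneously:

* ROR: a >= min_a, ROR >= 1 and the lower 95% CI bound > 1;
* PRR: a >= min_a, PRR >= 2 and (by default) chi-square >= 4 — an
  alternative rule accepts "PRR CI lower bound > 1 OR chi-square >= 4";
* BCPNN: IC025 > 0;
* EBGM: EBGM05 > 2.

Undefined statistics (nan) always flag negative.  Signal tables are ranked
by the ROR point estimate, descending, with ties broken by count then PT
code; ranking by the CI lower bound or by count is also supported.

:func:`reconstruct_margins` inverts a printed signal-table row — (count,
ROR, ROR CI) — back to the 2x2 margins in the large-comparator limit, which
lets published rows be checked for internal consistency even when the
underlying database is unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .contingency import ContingencyTable, all_pairs
from .dispro_stats import (
    DEFAULT_IC_PRIOR_STRENGTH,
    DEFAULT_Z,
    DisproportionalityResult,
    PriorParams,
    compute_all,
    fit_prior,
)
from .report_model import HierarchyMap, ReportDatabase

PRR_AUX_RULES = ("chi2_and", "ci_or_chi2")
RANK_KEYS = ("ror", "ror_low", "a")


@dataclass(frozen=True)
class Thresholds:
    """Screening cutoffs for the four-algorithm joint signal rule."""

    min_a: int = 3
    ror_min: float = 1.0
    ror_ci_min: float = 1.0
    prr_min: float = 2.0
    prr_aux_rule: str = "chi2_and"
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0
    z: float = DEFAULT_Z

    def __post_init__(self) -> None:
        if self.min_a < 1:
            raise ValueError("min_a must be >= 1")
        if self.prr_aux_rule not in PRR_AUX_RULES:
            raise ValueError(f"unknown prr_aux_rule {self.prr_aux_rule!r}")
        for name in ("ror_min", "ror_ci_min", "prr_min", "chi2_min", "ic025_min", "ebgm05_min"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")


def _ge(x: float, cutoff: float) -> bool:
    return bool(x >= cutoff) if math.isfinite(x) else False


def _gt(x: float, cutoff: float) -> bool:
    return bool(x > cutoff) if not math.isnan(x) else False


@dataclass(frozen=True)
class SignalRow:
    """One screened drug-event pair with per-algorithm flags."""

    soc: str
    pt: str
    a: int
    result: DisproportionalityResult
    ror_pos: bool
    prr_pos: bool
    ic_pos: bool
    ebgm_pos: bool
    labeled: bool | None = None

    @property
    def joint(self) -> bool:
        return self.ror_pos and self.prr_pos and self.ic_pos and self.ebgm_pos


@dataclass
class SignalTable:
    """Ranked signal rows for one drug; body holds the joint-positive rows,
    ``all_rows`` keeps every screened pair retrievable."""

    rows: list[SignalRow]
    all_rows: list[SignalRow]
    drug: str
    key: str = "ror"
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self, body_only: bool = True) -> pd.DataFrame:
        rows = self.rows if body_only else self.all_rows
        records = []
        for r in rows:
            s = r.result
            records.append(
                {
                    "soc": r.soc,
                    "pt": r.pt,
                    "a": r.a,
                    "ror": s.ror,
                    "ror_low": s.ror_low,
                    "ror_high": s.ror_high,
                    "prr": s.prr,
                    "prr_low": s.prr_low,
                    "prr_high": s.prr_high,
                    "chi2": s.chi2,
                    "ic": s.ic,
                    "ic025": s.ic025,
                    "ebgm": s.ebgm,
                    "ebgm05": s.ebgm05,
                    "ror_pos": r.ror_pos,
                    "prr_pos": r.prr_pos,
                    "ic_pos": r.ic_pos,
                    "ebgm_pos": r.ebgm_pos,
                    "joint": r.joint,
                    "labeled": r.labeled,
                }
            )
        return pd.DataFrame(
            records,
            columns=[
                "soc", "pt", "a",
                "ror", "ror_low", "ror_high",
                "prr", "prr_low", "prr_high",
                "chi2", "ic", "ic025", "ebgm", "ebgm05",
                "ror_pos", "prr_pos", "ic_pos", "ebgm_pos", "joint", "labeled",
            ],
        )

    def export(self, path: str | Path, delimiter: str = ",", body_only: bool = True) -> None:
        self.to_frame(body_only=body_only).to_csv(path, sep=delimiter, index=False)


def _flags(t: ContingencyTable, s: DisproportionalityResult, th: Thresholds) -> tuple[bool, bool, bool, bool]:
    count_ok = t.a >= th.min_a
    ror_pos = count_ok and _ge(s.ror, th.ror_min) and _gt(s.ror_low, th.ror_ci_min)
    chi2_ok = _ge(s.chi2, th.chi2_min)
    if th.prr_aux_rule == "chi2_and":
        aux = chi2_ok
    else:  # ci_or_chi2
        aux = _gt(s.prr_low, 1.0) or chi2_ok
    prr_pos = count_ok and _ge(s.prr, th.prr_min) and aux
    ic_pos = _gt(s.ic025, th.ic025_min)
    ebgm_pos = _gt(s.ebgm05, th.ebgm05_min)
    return ror_pos, prr_pos, ic_pos, ebgm_pos


def screen(
    results: list[tuple[str, ContingencyTable, DisproportionalityResult]],
    th: Thresholds,
    hierarchy: HierarchyMap,
    drug: str = "",
    provenance: str = "",
) -> SignalTable:
    """Apply the four threshold rules and rank the joint signals by ROR.

    ``results`` must have been computed under a single prior and comparator.
    Rows whose PT does not resolve through the hierarchy get an empty SOC
    code.  The returned table's body holds the joint-positive rows, sorted
    by ROR point estimate descending; every screened row remains available
    via ``all_rows``.
    """
    screened: list[SignalRow] = []
    for pt, t, s in results:
        ror_pos, prr_pos, ic_pos, ebgm_pos = _flags(t, s, th)
        screened.append(
            SignalRow(
                soc=hierarchy.soc_of(pt) or "",
                pt=pt,
                a=t.a,
                result=s,
                ror_pos=ror_pos,
                prr_pos=prr_pos,
                ic_pos=ic_pos,
                ebgm_pos=ebgm_pos,
            )
        )
    tbl = SignalTable(
        rows=[r for r in screened if r.joint],
        all_rows=screened,
        drug=drug,
        provenance=provenance,
    )
    return rank(tbl, key="ror")


def _rank_value(row: SignalRow, key: str) -> float:
    if key == "a":
        return float(row.a)
    v = getattr(row.result, key)
    return v if not math.isnan(v) else -math.inf


def rank(tbl: SignalTable, key: str = "ror") -> SignalTable:
    """Stable descending sort by ``key`` ('ror', 'ror_low' or 'a'); ties
    broken by count descending, then PT code ascending."""
    if key not in RANK_KEYS:
        raise ValueError(f"unknown rank key {key!r}; expected one of {RANK_KEYS}")

    def sort_key(row: SignalRow) -> tuple:
        return (-_rank_value(row, key), -row.a, row.pt)

    return SignalTable(
        rows=sorted(tbl.rows, key=sort_key),
        all_rows=list(tbl.all_rows),
        drug=tbl.drug,
        key=key,
        provenance=tbl.provenance,
    )


def compare_to_label(
    tbl: SignalTable, label_pts: set[str]
) -> tuple[list[SignalRow], list[SignalRow]]:
    """Partition the joint-positive rows into (labeled, unlabeled) against a
    drug-label PT list, tagging each row's ``labeled`` flag in place in the
    returned table rows."""
    labeled: list[SignalRow] = []
    unlabeled: list[SignalRow] = []
    tagged = []
    for row in tbl.rows:
        is_labeled = row.pt in label_pts
        row = replace(row, labeled=is_labeled)
        tagged.append(row)
        (labeled if is_labeled else unlabeled).append(row)
    tbl.rows = tagged
    return labeled, unlabeled


class InfeasibleRowError(ValueError):
    """A printed (a, ROR, CI) row is internally inconsistent: the implied
    log-ROR variance is at or below the Poisson floor 1/a."""


@dataclass(frozen=True)
class ReconstructedMargins:
    """Margins inverted from a printed row under the large-comparator limit.

    ``rho`` = d/c; ``chi2_limit`` and ``prr_pred`` are the chi-square and
    PRR implied by the reconstruction.  ``approximate`` records that 1/c and
    1/d were neglected.
    """

    a: int
    b: float
    rho: float
    chi2_limit: float
    prr_pred: float
    approximate: bool = True


def reconstruct_margins(
    a: int, ror: float, ror_low: float, z: float = DEFAULT_Z
) -> ReconstructedMargins:
    """Invert a printed (a, ROR, ROR CI lower bound) row to its 2x2 margins.

    In the large-comparator limit (c, d >> a+b, so 1/c and 1/d are
    negligible) the Woolf variance is s^2 = 1/a + 1/b, giving::

        s^2  = (ln(ROR/ROR_low)/z)^2
        b    = 1 / (s^2 - 1/a)
        rho  = d/c = ROR * b / a
        chi2 = (a*rho - b)^2 / [(a+b) * rho]
        PRR  = a (1 + rho) / (a + b)

    Raises :class:`InfeasibleRowError` when s^2 <= 1/a (a CI tighter than
    the Poisson floor cannot arise from any table).
    """
    if a < 1:
        raise ValueError("a must be >= 1")
    if not 0 < ror_low < ror:
        raise ValueError("need 0 < ror_low < ror")
    s2 = (math.log(ror / ror_low) / z) ** 2
    if s2 <= 1.0 / a:
        raise InfeasibleRowError(
            f"implied variance {s2:.6g} is at or below the Poisson floor 1/a = {1 / a:.6g}"
        )
    b = 1.0 / (s2 - 1.0 / a)
    rho = ror * b / a
    chi2_limit = (a * rho - b) ** 2 / ((a + b) * rho)
    prr_pred = a * (1 + rho) / (a + b)
    return ReconstructedMargins(a=a, b=b, rho=rho, chi2_limit=chi2_limit, prr_pred=prr_pred)


def analyze_drug(
    db: ReportDatabase,
    drug: str,
    level: str = "pt",
    thresholds: Thresholds | None = None,
    prior: PriorParams | None = None,
    ic_mode: str = "shrunk_ratio",
    ic_prior_strength: float = DEFAULT_IC_PRIOR_STRENGTH,
) -> SignalTable:
    """End-to-end screening of one drug against the rest of the database.

    Builds all drug-event tables at the requested level, fits the
    gamma-mixture prior on the (a, E) cells of *all* drugs in the database
    (unless a fitted ``prior`` is supplied), computes the four statistics per
    pair and returns the screened, ROR-ranked signal table.
    """
    th = thresholds or Thresholds()
    if prior is None:
        cells = [
            (t.a, t.expected)
            for d in db.drugs()
            for _, t in all_pairs(db, d, level)
            if t.expected > 0
        ]
        prior = fit_prior(cells)
    results = []
    for event, t in all_pairs(db, drug, level):
        s = compute_all(t, prior, z=th.z, ic_mode=ic_mode, ic_prior_strength=ic_prior_strength)
        results.append((event, t, s))
    return screen(results, th, db.hierarchy, drug=drug, provenance=db.provenance)
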