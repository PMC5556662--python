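"""Incident-case identification on the quarterly claims grid.

An incident case requires (a) a qualifying site diagnosis in the target
year (the *index* quarter), (b) no qualifying diagnosis during a lookback
(washout) period of ``4*L`` quarters before the index quarter, and (c) a
confirmatory event — second diagnosis, death, or (in strict variants) a
site-specific surgery — within ``C`` quarters after the index quarter.
C0 variants drop requirement (c).

Diagnosis contexts differ in what qualifies: the index accepts only
outpatient diagnoses marked G (certain) and inpatient main-discharge
diagnoses; lookback and confirmation additionally accept Z (status post)
outpatient diagnoses and ancillary inpatient diagnoses.  V (suspected) and
A (excluded) markers never qualify.

Window conventions (quarter indices, inclusive):

* lookback           ``[index - 4L, index - 1]``
* second diagnosis   ``[index + 1, index + C]`` — a same-quarter record
  never confirms, since it cannot be distinguished from the index itself
* death / surgery    ``[index, index + C]`` — a person dying or operated
  in the index quarter cannot produce a later second diagnosis; excluding
  them would systematically drop fulminant cases

Inpatient events map to quarters by their discharge date (the discharge
diagnosis reflects the reason for hospitalisation); procedures and deaths
by their own dates.
"""
from __future__ import annotations

import bisect
import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import (
    CancerSite,
    ClaimsTables,
    InpatientDx,
    OutpatientDx,
    ProcedureRecord,
    Quarter,
    date_to_quarter,
    get_site,
    normalize_icd,
    quarter_index,
)
from .cohort import CohortResult
from .errors import ConfigError, IncompatibleAlgorithmError

TARGET_YEAR = 2013

INDEX_CERTAINTIES = frozenset({"G"})
LOOKCONF_CERTAINTIES = frozenset({"G", "Z"})
INDEX_DX_TYPES = frozenset({"MAIN_DISCHARGE"})
LOOKCONF_DX_TYPES = frozenset({"MAIN_DISCHARGE", "ANCILLARY"})


@dataclass(frozen=True)
class QualifyingDiagnosisRule:
    """Which records qualify as a site diagnosis in a given context."""

    context: str
    outpatient_certainties: frozenset[str]
    inpatient_dx_types: frozenset[str]


INDEX_RULE = QualifyingDiagnosisRule("INDEX", INDEX_CERTAINTIES, INDEX_DX_TYPES)
LOOKBACK_RULE = QualifyingDiagnosisRule("LOOKBACK", LOOKCONF_CERTAINTIES, LOOKCONF_DX_TYPES)
CONFIRMATION_RULE = QualifyingDiagnosisRule(
    "CONFIRMATION", LOOKCONF_CERTAINTIES, LOOKCONF_DX_TYPES
)


@dataclass(frozen=True)
class AlgorithmSpec:
    """One cell of the algorithm grid.

    ``label`` follows the ``L{lookback}-C{confirmation}`` convention with
    suffixes ``-ed`` (death excluded as confirmatory event) and ``-su``
    (surgery required as the confirmatory event).
    """

    label: str
    lookback_years: int
    confirmation_quarters: int
    require_confirmation: bool = True
    allow_death_confirm: bool = True
    require_surgery_confirm: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.lookback_years:
            raise ConfigError("lookback_years must be >= 1")
        if self.confirmation_quarters < 0:
            raise ConfigError("confirmation_quarters must be >= 0")
        if (self.confirmation_quarters == 0) == self.require_confirmation:
            raise ConfigError("C = 0 if and only if no confirmation is required")
        if self.require_surgery_confirm and not self.require_confirmation:
            raise ConfigError("surgery confirmation implies a confirmation period")


def algorithm_grid() -> list[AlgorithmSpec]:
    """The 15 algorithm variants: L1–L7 × C1, then C4/C0/ed/su at L1 and L7."""
    grid = [AlgorithmSpec(f"L{L}-C1", L, 1) for L in range(1, 8)]
    grid += [
        AlgorithmSpec("L1-C4", 1, 4),
        AlgorithmSpec("L7-C4", 7, 4),
        AlgorithmSpec("L1-C0", 1, 0, require_confirmation=False),
        AlgorithmSpec("L7-C0", 7, 0, require_confirmation=False),
        AlgorithmSpec("L1-C1-ed", 1, 1, allow_death_confirm=False),
        AlgorithmSpec("L7-C1-ed", 7, 1, allow_death_confirm=False),
        AlgorithmSpec("L1-C4-su", 1, 4, require_surgery_confirm=True),
        AlgorithmSpec("L7-C4-su", 7, 4, require_surgery_confirm=True),
    ]
    return grid


BASELINE = algorithm_grid()[0]  # L1-C1


def get_algorithms(selection: str | Sequence[str] | AlgorithmSpec | Sequence[AlgorithmSpec]) -> list[AlgorithmSpec]:
    grid = {a.label: a for a in algorithm_grid()}
    if isinstance(selection, AlgorithmSpec):
        return [selection]
    if isinstance(selection, str):
        if selection.lower() == "all":
            return list(grid.values())
        selection = [selection]
    out = []
    for item in selection:
        if isinstance(item, AlgorithmSpec):
            out.append(item)
        elif item in grid:
            out.append(grid[item])
        else:
            raise ConfigError(f"unknown algorithm label {item!r}; known: {list(grid)}")
    return out


# ---------------------------------------------------------------------------
# Per-person rule evaluation (record-level surface)
# ---------------------------------------------------------------------------

def _dx_quarters(
    outpatient: Iterable[OutpatientDx],
    inpatient: Iterable[InpatientDx],
    site: CancerSite,
    rule: QualifyingDiagnosisRule,
) -> set[int]:
    qs: set[int] = set()
    for o in outpatient:
        if o.certainty in rule.outpatient_certainties and _matches(o.icd_code, site):
            qs.add(o.quarter.index)
    for i in inpatient:
        if i.dx_type in rule.inpatient_dx_types and _matches(i.icd_code, site):
            qs.add(date_to_quarter(i.discharge_date).index)
    return qs


def _matches(code: str, site: CancerSite) -> bool:
    return normalize_icd(code)[:3] in site.icd_prefixes


def find_index_quarter(
    outpatient: Iterable[OutpatientDx],
    inpatient: Iterable[InpatientDx],
    site: CancerSite | str,
    year: int = TARGET_YEAR,
) -> Quarter | None:
    """Earliest quarter of ``year`` holding an index-qualifying diagnosis."""
    site = get_site(site)
    lo, hi = quarter_index(year, 1), quarter_index(year, 4)
    qs = [q for q in _dx_quarters(outpatient, inpatient, site, INDEX_RULE) if lo <= q <= hi]
    return Quarter.from_index(min(qs)) if qs else None


def passes_lookback(
    outpatient: Iterable[OutpatientDx],
    inpatient: Iterable[InpatientDx],
    site: CancerSite | str,
    index_q: Quarter,
    lookback_years: int,
) -> bool:
    """True iff no lookback-qualifying diagnosis in ``[index-4L, index-1]``."""
    site = get_site(site)
    lo = index_q.index - 4 * lookback_years
    hi = index_q.index - 1
    qs = _dx_quarters(outpatient, inpatient, site, LOOKBACK_RULE)
    return not any(lo <= q <= hi for q in qs)


def passes_confirmation(
    outpatient: Iterable[OutpatientDx],
    inpatient: Iterable[InpatientDx],
    site: CancerSite | str,
    index_q: Quarter,
    spec: AlgorithmSpec,
    death_date: dt.date | None = None,
    procedures: Iterable[ProcedureRecord] = (),
) -> str | None:
    """Return the confirming-event kind, or None when confirmation fails.

    Kinds: ``NONE_REQUIRED`` (C0 variants), ``SURGERY`` (surgery-required
    variants), ``SECOND_DIAGNOSIS``, ``DEATH``.
    """
    site = get_site(site)
    if not spec.require_confirmation:
        return "NONE_REQUIRED"
    i, C = index_q.index, spec.confirmation_quarters
    if spec.require_surgery_confirm:
        if not site.surgery_classes:
            raise IncompatibleAlgorithmError(
                f"no surgical confirmatory procedures defined for {site.name}"
            )
        for p in procedures:
            if p.proc_class in site.surgery_classes and i <= date_to_quarter(p.date).index <= i + C:
                return "SURGERY"
        return None
    qs = _dx_quarters(outpatient, inpatient, site, CONFIRMATION_RULE)
    if any(i + 1 <= q <= i + C for q in qs):
        return "SECOND_DIAGNOSIS"
    if spec.allow_death_confirm and death_date is not None:
        if i <= date_to_quarter(death_date).index <= i + C:
            return "DEATH"
    return None


# ---------------------------------------------------------------------------
# Vectorised engine
# ---------------------------------------------------------------------------

def _quarter_strings_to_index(q: pd.Series) -> np.ndarray:
    year = q.str.slice(0, 4).astype(int).to_numpy()
    qq = q.str.slice(5, 6).astype(int).to_numpy()
    return 4 * year + (qq - 1)


def _date_strings_to_qindex(d: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(d)
    return (4 * ts.dt.year + (ts.dt.month - 1) // 3).to_numpy()


def _per_person_sorted(person_ids: np.ndarray, values: np.ndarray) -> dict[str, np.ndarray]:
    order = np.lexsort((values, person_ids))
    pid, val = person_ids[order], values[order]
    out: dict[str, np.ndarray] = {}
    if len(pid) == 0:
        return out
    bounds = np.flatnonzero(pid[1:] != pid[:-1]) + 1
    for chunk_pid, chunk in zip(
        pid[np.concatenate(([0], bounds))], np.split(val, bounds)
    ):
        out[chunk_pid] = chunk
    return out


class SiteEventIndex:
    """Per-person sorted quarter indices of site-relevant events.

    Built once per (tables, site) pair, then shared across all algorithm
    variants; identification per variant is a handful of binary searches
    per candidate person.
    """

    def __init__(self, tables: ClaimsTables, site: CancerSite | str):
        site = get_site(site)
        self.site = site

        o = tables.outpatient
        o_match = (
            o["icd_code"].str.upper().str.replace(".", "", regex=False).str.slice(0, 3)
            .isin(site.icd_prefixes)
            if len(o)
            else pd.Series(dtype=bool)
        )
        o = o.loc[o_match] if len(o) else o
        o_q = _quarter_strings_to_index(o["quarter"]) if len(o) else np.empty(0, int)

        i = tables.inpatient
        i_match = (
            i["icd_code"].str.upper().str.replace(".", "", regex=False).str.slice(0, 3)
            .isin(site.icd_prefixes)
            if len(i)
            else pd.Series(dtype=bool)
        )
        i = i.loc[i_match] if len(i) else i
        i_q = _date_strings_to_qindex(i["discharge_date"]) if len(i) else np.empty(0, int)

        o_pid = o["person_id"].to_numpy()
        i_pid = i["person_id"].to_numpy()
        o_cert = o["certainty"].to_numpy()
        i_type = i["dx_type"].to_numpy()

        idx_mask_o = np.isin(o_cert, list(INDEX_CERTAINTIES))
        idx_mask_i = np.isin(i_type, list(INDEX_DX_TYPES))
        qual_mask_o = np.isin(o_cert, list(LOOKCONF_CERTAINTIES))
        qual_mask_i = np.isin(i_type, list(LOOKCONF_DX_TYPES))

        self.index_q = _per_person_sorted(
            np.concatenate([o_pid[idx_mask_o], i_pid[idx_mask_i]]),
            np.concatenate([o_q[idx_mask_o], i_q[idx_mask_i]]),
        )
        self.index_outpt_q = _per_person_sorted(o_pid[idx_mask_o], o_q[idx_mask_o])
        self.qual_q = _per_person_sorted(
            np.concatenate([o_pid[qual_mask_o], i_pid[qual_mask_i]]),
            np.concatenate([o_q[qual_mask_o], i_q[qual_mask_i]]),
        )

        pr = tables.procedures
        if len(pr) and site.surgery_classes:
            pm = pr["proc_class"].isin(site.surgery_classes)
            pr = pr.loc[pm]
            self.surgery_q = _per_person_sorted(
                pr["person_id"].to_numpy(), _date_strings_to_qindex(pr["date"])
            )
        else:
            self.surgery_q = {}

        pers = tables.persons
        dd = pers["death_date"]
        has_death = dd != ""
        self.death_q: dict[str, int] = {}
        if has_death.any():
            died = pers.loc[has_death]
            dq = _date_strings_to_qindex(died["death_date"])
            self.death_q = dict(zip(died["person_id"].to_numpy(), dq.tolist()))


def _any_in(sorted_arr: np.ndarray, lo: int, hi: int) -> bool:
    """Any value of a sorted int array inside [lo, hi]?"""
    j = bisect.bisect_left(sorted_arr, lo)
    return j < len(sorted_arr) and sorted_arr[j] <= hi


CASES_COLUMNS = [
    "person_id", "site", "algorithm_label", "index_quarter", "index_setting", "confirm_kind",
]


def identify_incident_cases(
    tables: ClaimsTables,
    cohort: CohortResult | pd.DataFrame,
    site: CancerSite | str,
    spec: AlgorithmSpec,
    *,
    events: SiteEventIndex | None = None,
    year: int = TARGET_YEAR,
) -> pd.DataFrame:
    """Apply one algorithm variant to one site over the whole cohort.

    Returns one row per incident case: person_id, site, algorithm_label,
    index_quarter (``YYYYQn``), index_setting (OUTPATIENT/INPATIENT) and
    confirm_kind.  A person appears at most once per site.
    """
    site = get_site(site)
    if spec.require_surgery_confirm and not site.surgery_classes:
        raise IncompatibleAlgorithmError(
            f"algorithm {spec.label} requires surgery confirmation, "
            f"which is undefined for {site.name}"
        )
    ev = events or SiteEventIndex(tables, site)
    frame = cohort.frame if isinstance(cohort, CohortResult) else cohort
    eligible = frame.loc[frame["sex"].isin(sorted(site.eligible_sexes)), "person_id"]
    eligible_set = set(eligible.to_numpy())

    lo_y, hi_y = quarter_index(year, 1), quarter_index(year, 4)
    L4 = 4 * spec.lookback_years
    C = spec.confirmation_quarters
    rows = []
    for pid, idx_arr in ev.index_q.items():
        if pid not in eligible_set:
            continue
        j = bisect.bisect_left(idx_arr, lo_y)
        if j >= len(idx_arr) or idx_arr[j] > hi_y:
            continue
        iq = int(idx_arr[j])
        qual = ev.qual_q.get(pid, _EMPTY_INT)
        if _any_in(qual, iq - L4, iq - 1):
            continue
        if not spec.require_confirmation:
            kind = "NONE_REQUIRED"
        elif spec.require_surgery_confirm:
            surg = ev.surgery_q.get(pid, _EMPTY_INT)
            if not _any_in(surg, iq, iq + C):
                continue
            kind = "SURGERY"
        elif _any_in(qual, iq + 1, iq + C):
            kind = "SECOND_DIAGNOSIS"
        elif (
            spec.allow_death_confirm
            and pid in ev.death_q
            and iq <= ev.death_q[pid] <= iq + C
        ):
            kind = "DEATH"
        else:
            continue
        outpt = ev.index_outpt_q.get(pid, _EMPTY_INT)
        setting = "OUTPATIENT" if _any_in(outpt, iq, iq) else "INPATIENT"
        rows.append(
            (pid, site.name, spec.label, str(Quarter.from_index(iq)), setting, kind)
        )
    return pd.DataFrame(rows, columns=CASES_COLUMNS)


_EMPTY_INT = np.empty(0, dtype=int)


def identify_grid(
    tables: ClaimsTables,
    cohort: CohortResult | pd.DataFrame,
    sites: Sequence[CancerSite | str] = ("breast", "prostate", "colorectal"),
    specs: Sequence[AlgorithmSpec] | str = "all",
    *,
    skip_incompatible: bool = True,
    year: int = TARGET_YEAR,
) -> pd.DataFrame:
    """Run many algorithm variants over many sites, sharing event indexing.

    Site–algorithm combinations without a defined surgical confirmatory
    event (prostate with ``-su`` variants) are skipped when
    ``skip_incompatible`` is set, mirroring the N/A cells of the grid.
    """
    specs = get_algorithms(specs)
    out = []
    for site in sites:
        site = get_site(site)
        ev = SiteEventIndex(tables, site)
        for spec in specs:
            if spec.require_surgery_confirm and not site.surgery_classes:
                if skip_incompatible:
                    continue
            out.append(
                identify_incident_cases(tables, cohort, site, spec, events=ev, year=year)
            )
    if not out:
        return pd.DataFrame(columns=CASES_COLUMNS)
    return pd.concat(out, ignore_index=True)
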