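"""Brute-force reference implementation of incident-case identification.

Deliberately independent of the package's engine: plain Python loops over
every person, quarter and record, re-deriving the qualifying rules from
first principles.  Used to cross-check the vectorised engine on small
random populations.
"""
from __future__ import annotations

import datetime as dt


def _quarter_of_date(d: dt.date) -> int:
    return 4 * d.year + (d.month - 1) // 3


def _code_in_site(code: str, prefixes) -> bool:
    c = code.replace(".", "").upper()
    return any(c.startswith(p) for p in prefixes)


SITE_DEFS = {
    "BREAST": (("C50",), ("F",), ("LUMPECTOMY", "MASTECTOMY")),
    "PROSTATE": (("C61",), ("M",), ()),
    "COLORECTAL": (("C18", "C19", "C20", "C21"), ("F", "M"), ("ENDOSCOPY", "COLORECTAL_SURGERY")),
}


def site_event_table(tables, cohort_frame, site_name: str) -> dict:
    """Per eligible person: quarter sets of index/any-qualifying dx, surgery, death."""
    prefixes, sexes, surgery_classes = SITE_DEFS[site_name]
    cohort = {r["person_id"]: r["sex"] for r in cohort_frame.to_dict("records")}
    people = {}
    for p in tables.persons.to_dict("records"):
        pid = p["person_id"]
        if pid not in cohort or cohort[pid] not in sexes:
            continue
        death = (
            _quarter_of_date(dt.date.fromisoformat(p["death_date"]))
            if p["death_date"]
            else None
        )
        people[pid] = {"index": set(), "qual": set(), "surg": set(), "death": death}
    for r in tables.outpatient.to_dict("records"):
        pid = r["person_id"]
        if pid not in people or not _code_in_site(r["icd_code"], prefixes):
            continue
        y, q = int(r["quarter"][:4]), int(r["quarter"][5])
        qi = 4 * y + q - 1
        if r["certainty"] == "G":
            people[pid]["index"].add(qi)
            people[pid]["qual"].add(qi)
        elif r["certainty"] == "Z":
            people[pid]["qual"].add(qi)
    for r in tables.inpatient.to_dict("records"):
        pid = r["person_id"]
        if pid not in people or not _code_in_site(r["icd_code"], prefixes):
            continue
        qi = _quarter_of_date(dt.date.fromisoformat(r["discharge_date"]))
        if r["dx_type"] == "MAIN_DISCHARGE":
            people[pid]["index"].add(qi)
        people[pid]["qual"].add(qi)
    for r in tables.procedures.to_dict("records"):
        pid = r["person_id"]
        if pid in people and r["proc_class"] in surgery_classes:
            people[pid]["surg"].add(_quarter_of_date(dt.date.fromisoformat(r["date"])))
    return people


def brute_force_cases(
    people: dict,
    lookback_years: int,
    confirmation_quarters: int,
    require_confirmation: bool,
    allow_death_confirm: bool,
    require_surgery_confirm: bool,
    year: int = 2013,
):
    """Return {person_id: (index_qidx, confirm_kind)} by exhaustive scanning."""
    out = {}
    for pid, ev in people.items():
        found = None
        for qi in range(4 * year, 4 * year + 4):
            if qi not in ev["index"]:
                continue
            # lookback: any qualifying diagnosis in the 4L preceding quarters
            if any(q in ev["qual"] for q in range(qi - 4 * lookback_years, qi)):
                break  # earliest index failed; any later index fails lookback too
            if not require_confirmation:
                found = (qi, "NONE_REQUIRED")
            elif require_surgery_confirm:
                if any(qi <= q <= qi + confirmation_quarters for q in ev["surg"]):
                    found = (qi, "SURGERY")
            else:
                if any(
                    q in ev["qual"]
                    for q in range(qi + 1, qi + confirmation_quarters + 1)
                ):
                    found = (qi, "SECOND_DIAGNOSIS")
                elif (
                    allow_death_confirm
                    and ev["death"] is not None
                    and qi <= ev["death"] <= qi + confirmation_quarters
                ):
                    found = (qi, "DEATH")
            break  # only the earliest 2013 index quarter is ever evaluated
        if found:
            out[pid] = found
    return out


def oracle_case_sets(tables, cohort_frame, site_name: str, specs) -> dict:
    """Case dict per algorithm label, sharing the record scan across specs."""
    people = site_event_table(tables, cohort_frame, site_name)
    return {
        spec.label: brute_force_cases(
            people,
            spec.lookback_years,
            spec.confirmation_quarters,
            spec.require_confirmation,
            spec.allow_death_confirm,
            spec.require_surgery_confirm,
        )
        for spec in specs
    }
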