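"""Study-population construction under the continuous-insurance gap rule.

The denominator cohort comprises insured persons who, on a reference date
(default 2013-01-01), have a minimum number of years of continuous
insurance, where "continuous" tolerates coverage gaps of at most 28 days.
Persons with missing or invalid sex, birth year or place of residence, or
residing outside Germany, are excluded with a reason-specific tally.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FEDERAL_STATES, FOREIGN, MISSING, CancerSite, ClaimsTables, get_site
from .errors import ConfigError

#: Fixed attribution order for mutually exclusive exclusion reasons.
EXCLUSION_REASONS = (
    "continuity",
    "missing_sex",
    "missing_birth_year",
    "missing_state",
    "foreign_residence",
)


@dataclass(frozen=True)
class CohortSpec:
    """Eligibility rule: continuous insurance before a reference date.

    ``required_years`` is 7 in the main analysis; sensitivity analyses use
    1 year or the lookback length of the algorithm under study.  A coverage
    gap is a run of wholly uncovered calendar days; runs longer than
    ``max_gap_days`` break continuity.  Coverage must include the reference
    date itself.
    """

    reference_date: dt.date = dt.date(2013, 1, 1)
    required_years: int = 7
    max_gap_days: int = 28

    def __post_init__(self) -> None:
        if self.required_years < 1:
            raise ConfigError("required_years must be >= 1")
        if self.max_gap_days < 0:
            raise ConfigError("max_gap_days must be >= 0")

    @property
    def window_start(self) -> dt.date:
        d = self.reference_date
        try:
            return d.replace(year=d.year - self.required_years)
        except ValueError:  # Feb 29 reference
            return d.replace(year=d.year - self.required_years, day=28)


def is_continuously_insured(
    spells: list[tuple[dt.date, dt.date]], spec: CohortSpec
) -> bool:
    """Evaluate the gap rule for one person's sorted, disjoint spells.

    Every uncovered run of days inside ``[window_start, reference_date]``
    must be at most ``max_gap_days`` long, and the reference date must be
    covered (a trailing uncovered run would leave it uncovered).
    """
    w0, ref = spec.window_start, spec.reference_date
    cursor = w0  # first day not yet known to be covered
    for start, end in spells:
        if end < w0 or start > ref:
            continue
        if start > cursor:
            gap_days = (start - cursor).days
            if gap_days > spec.max_gap_days:
                return False
        new_cursor = min(end, ref) + dt.timedelta(days=1)
        cursor = max(cursor, new_cursor)
    return cursor > ref  # reference date covered, no open trailing run


@dataclass
class CohortResult:
    """Eligible persons plus the reason-specific exclusion tally."""

    frame: pd.DataFrame  # person_id, sex, age, state
    exclusions: dict[str, int]
    spec: CohortSpec

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def person_ids(self) -> pd.Series:
        return self.frame["person_id"]


def _continuity_flags(tables: ClaimsTables, spec: CohortSpec) -> pd.Series:
    """Gap-rule verdict per person_id, vectorised over the spells table."""
    w0 = np.datetime64(spec.window_start)
    ref = np.datetime64(spec.reference_date)
    s = tables.spells
    all_ids = tables.persons["person_id"]
    if s.empty:
        return pd.Series(False, index=all_ids)
    df = pd.DataFrame(
        {
            "person_id": s["person_id"].to_numpy(),
            "start": pd.to_datetime(s["start"]).to_numpy().astype("datetime64[D]"),
            "end": pd.to_datetime(s["end"]).to_numpy().astype("datetime64[D]"),
        }
    )
    df = df[(df["end"] >= w0) & (df["start"] <= ref)]
    df["start"] = df["start"].clip(lower=w0)
    df["end"] = df["end"].clip(upper=ref)
    df = df.sort_values(["person_id", "start"], kind="mergesort")
    grp = df.groupby("person_id", sort=False)
    # running coverage frontier: latest end seen so far within each person
    frontier = grp["end"].cummax().groupby(df["person_id"], sort=False).shift()
    lead = frontier.isna()
    gap = (df["start"] - frontier).dt.days - 1
    gap[lead] = (df["start"] - w0).dt.days  # uncovered run from window start
    ok_gaps = gap.clip(lower=0).groupby(df["person_id"], sort=False).max() <= spec.max_gap_days
    covered_ref = grp["end"].max() == ref
    verdict = (ok_gaps & covered_ref).reindex(all_ids, fill_value=False)
    return verdict


def build_cohort(tables: ClaimsTables, spec: CohortSpec | None = None) -> CohortResult:
    """Apply eligibility rules, returning the cohort and an exclusion tally.

    Exclusion reasons are attributed first-failing-rule in the fixed order
    continuity, missing sex, missing birth year, missing/invalid state,
    foreign residence, so the tally partitions the excluded persons.
    """
    spec = spec or CohortSpec()
    persons = tables.persons
    cont = _continuity_flags(tables, spec).to_numpy()

    sex = persons["sex"].to_numpy()
    by = persons["birth_year"].to_numpy()
    state = persons["state"].to_numpy()
    has_sex = np.isin(sex, ["F", "M"])
    has_by = by != MISSING
    german = np.isin(state, list(FEDERAL_STATES))
    foreign = state == FOREIGN

    tally = dict.fromkeys(EXCLUSION_REASONS, 0)
    reason = np.full(len(persons), "", dtype=object)
    reason[~cont] = "continuity"
    m = cont & ~has_sex
    reason[m] = "missing_sex"
    m = cont & has_sex & ~has_by
    reason[m] = "missing_birth_year"
    m = cont & has_sex & has_by & ~german & ~foreign
    reason[m] = "missing_state"
    m = cont & has_sex & has_by & foreign
    reason[m] = "foreign_residence"
    for r in EXCLUSION_REASONS:
        tally[r] = int((reason == r).sum())

    eligible = reason == ""
    frame = pd.DataFrame(
        {
            "person_id": persons["person_id"].to_numpy()[eligible],
            "sex": sex[eligible],
            "age": spec.reference_date.year
            - pd.to_numeric(pd.Series(by[eligible])).to_numpy(),
            "state": state[eligible],
        }
    )
    return CohortResult(frame=frame, exclusions=tally, spec=spec)


def site_denominator(cohort: CohortResult | pd.DataFrame, site: CancerSite | str) -> int:
    """Cohort members whose sex is eligible for ``site`` (colorectal: all)."""
    site = get_site(site)
    frame = cohort.frame if isinstance(cohort, CohortResult) else cohort
    return int(frame["sex"].isin(sorted(site.eligible_sexes)).sum())
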