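"""Crude and age-standardised cumulative incidence, and benchmarking.

Cumulative incidences are person-count based: cases per 100,000 cohort
members in the target year.  Direct age standardisation uses the 1976
European Standard Population in its 18-band form (0–4, 5–9, …, 80–84,
85+), the convention of the German cancer-registry tabulations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortResult
from .data import FEDERAL_STATES, CancerSite, get_site
from .errors import DataError

# 18-band 1976 European Standard Population, weights per 100,000.
_ESP1976_WEIGHTS = (
    8000, 7000, 7000, 7000, 7000, 7000, 7000, 7000, 7000, 7000, 7000,
    6000, 5000, 4000, 3000, 2000, 1000, 1000,
)


@dataclass(frozen=True)
class StandardPopulation:
    """Ordered five-year age bands with standard weights per 100,000."""

    name: str
    weights: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.weights) != 100_000:
            raise DataError(
                f"standard population {self.name!r} weights sum to "
                f"{sum(self.weights)}, expected 100000"
            )

    @property
    def n_bands(self) -> int:
        return len(self.weights)

    def band_labels(self) -> list[str]:
        labels = [f"{5 * i}-{5 * i + 4}" for i in range(self.n_bands - 1)]
        labels.append(f"{5 * (self.n_bands - 1)}+")
        return labels

    def band_of(self, age: int) -> int:
        """Index of the band containing ``age`` (open-ended last band)."""
        if age < 0:
            raise DataError(f"negative age {age}")
        return min(age // 5, self.n_bands - 1)

    def assign(self, ages: np.ndarray) -> np.ndarray:
        if (np.asarray(ages) < 0).any():
            raise DataError("negative age encountered")
        return np.minimum(np.asarray(ages) // 5, self.n_bands - 1)


ESP1976 = StandardPopulation("esp1976", _ESP1976_WEIGHTS)

STANDARD_POPULATIONS = {"esp1976": ESP1976}


def round_report(x: float, ndigits: int = 1) -> float:
    """Half-away-from-zero rounding used only at the reporting layer."""
    factor = 10 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def crude_cumulative_incidence(numerator: int, denominator: int) -> float:
    """Cases per 100,000 persons (unrounded)."""
    if denominator <= 0:
        raise DataError("crude cumulative incidence undefined for zero denominator")
    if numerator > denominator:
        raise DataError("numerator exceeds denominator")
    return 100_000.0 * numerator / denominator


def age_standardized_cumulative_incidence(
    cases_by_band: Sequence[float],
    denominators_by_band: Sequence[float],
    std: StandardPopulation = ESP1976,
) -> float:
    """Directly standardised rate per 100,000: Σ w_g (n_g/d_g) / Σ w_g × 1e5.

    Bands with zero denominator contribute nothing and trigger a warning;
    a band with more cases than denominator raises a data error.
    """
    n = np.asarray(cases_by_band, dtype=float)
    d = np.asarray(denominators_by_band, dtype=float)
    if n.shape != (std.n_bands,) or d.shape != (std.n_bands,):
        raise DataError(
            f"expected {std.n_bands} age bands, got {n.shape[0]} cases / {d.shape[0]} denominators"
        )
    if (n > d).any():
        raise DataError("cases exceed denominator in at least one age band")
    w = np.asarray(std.weights, dtype=float)
    empty = d == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} empty age band(s) contribute 0 to the standardised rate",
            stacklevel=2,
        )
    rates = np.divide(n, d, out=np.zeros_like(n), where=~empty)
    return float(100_000.0 * np.sum(w * rates) / np.sum(w))


def percent_difference(claims_value: float, registry_value: float) -> float:
    """Relative difference of a claims estimate vs a registry benchmark, in %."""
    if registry_value == 0:
        raise DataError("percent difference undefined for zero registry value")
    return 100.0 * (claims_value - registry_value) / registry_value


# ---------------------------------------------------------------------------
# Stratified results
# ---------------------------------------------------------------------------

RESULTS_COLUMNS = [
    "site", "algorithm_label", "stratum_type", "stratum_value",
    "numerator", "denominator", "cci", "aci",
]

STRATUM_TYPES = ("overall", "sex", "state", "sex_state")


def _band_counts(ages: np.ndarray, std: StandardPopulation) -> np.ndarray:
    return np.bincount(std.assign(ages), minlength=std.n_bands).astype(float)


def _one_result(
    site: CancerSite,
    label: str,
    stratum_type: str,
    stratum_value: str,
    case_ages: np.ndarray,
    denom_ages: np.ndarray,
    std: StandardPopulation,
) -> dict:
    denom = len(denom_ages)
    num = len(case_ages)
    if denom == 0:
        cci = aci = np.nan
    else:
        cci = crude_cumulative_incidence(num, denom)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aci = age_standardized_cumulative_incidence(
                _band_counts(case_ages, std), _band_counts(denom_ages, std), std
            )
    return {
        "site": site.name,
        "algorithm_label": label,
        "stratum_type": stratum_type,
        "stratum_value": stratum_value,
        "numerator": num,
        "denominator": denom,
        "cci": cci,
        "aci": aci,
    }


def stratified_results(
    cases: pd.DataFrame,
    cohort: CohortResult | pd.DataFrame,
    std: StandardPopulation = ESP1976,
    strata: Sequence[str] = ("overall",),
    cells: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """One row per site × algorithm × stratum level.

    ``strata`` may include ``overall``, ``sex``, ``state`` and
    ``sex_state``; sex strata are restricted to the site's eligible sexes,
    state strata always cover all 16 federal states (zero rows included).
    Denominators are site-specific person counts from the cohort.

    ``cells`` optionally lists the (site, algorithm_label) combinations to
    report; combinations without any identified case then appear with a
    zero numerator.  By default only combinations present in ``cases``
    are reported.
    """
    for s in strata:
        if s not in STRATUM_TYPES:
            raise DataError(f"unknown stratum type {s!r}")
    frame = cohort.frame if isinstance(cohort, CohortResult) else cohort
    rows = []
    person = frame.set_index("person_id")
    groups = {
        key: grp for key, grp in cases.groupby(["site", "algorithm_label"], sort=True)
    }
    if cells is None:
        cells = sorted(groups)
    empty_cases = cases.iloc[0:0]
    for site_name, label in cells:
        grp = groups.get((site_name, label), empty_cases)
        site = get_site(site_name.lower())
        denom = frame[frame["sex"].isin(sorted(site.eligible_sexes))]
        joined = person.loc[grp["person_id"]]
        if "overall" in strata:
            rows.append(
                _one_result(site, label, "overall", "ALL",
                            joined["age"].to_numpy(), denom["age"].to_numpy(), std)
            )
        if "sex" in strata:
            for sex in sorted(site.eligible_sexes):
                rows.append(
                    _one_result(
                        site, label, "sex", sex,
                        joined.loc[joined["sex"] == sex, "age"].to_numpy(),
                        denom.loc[denom["sex"] == sex, "age"].to_numpy(), std,
                    )
                )
        if "state" in strata:
            for st in FEDERAL_STATES:
                rows.append(
                    _one_result(
                        site, label, "state", st,
                        joined.loc[joined["state"] == st, "age"].to_numpy(),
                        denom.loc[denom["state"] == st, "age"].to_numpy(), std,
                    )
                )
        if "sex_state" in strata:
            for sex in sorted(site.eligible_sexes):
                for st in FEDERAL_STATES:
                    rows.append(
                        _one_result(
                            site, label, "sex_state", f"{sex}|{st}",
                            joined.loc[
                                (joined["sex"] == sex) & (joined["state"] == st), "age"
                            ].to_numpy(),
                            denom.loc[
                                (denom["sex"] == sex) & (denom["state"] == st), "age"
                            ].to_numpy(), std,
                        )
                    )
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)


# ---------------------------------------------------------------------------
# Registry benchmarking
# ---------------------------------------------------------------------------

def compare_to_registry(results: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Match claims ACI against a registry table (site, sex, state, aci).

    Registry rows use state ``ALL`` for the national value and sex ``ALL``
    for both-sex (colorectal) rates.  Claims rows are looked up in
    ``results`` by the corresponding stratum; unmatched registry rows are
    silently skipped, registry zeros yield a missing percent difference.
    """
    rows = []
    for _, r in registry.iterrows():
        site, sex, state = r["site"], r["sex"], r["state"]
        sub = results[results["site"] == site]
        site_obj = get_site(site.lower())
        both_sex = sex == "ALL" or set(site_obj.eligible_sexes) == {sex}
        if state == "ALL":
            stype, sval = ("overall", "ALL") if both_sex else ("sex", sex)
        else:
            stype, sval = ("state", state) if both_sex else ("sex_state", f"{sex}|{state}")
        match = sub[(sub["stratum_type"] == stype) & (sub["stratum_value"] == sval)]
        if match.empty:
            continue
        for _, m in match.iterrows():
            claims_aci = m["aci"]
            registry_aci = float(r["aci"])
            pct = (
                percent_difference(claims_aci, registry_aci)
                if registry_aci > 0
                else np.nan
            )
            rows.append(
                {
                    "site": site,
                    "algorithm_label": m["algorithm_label"],
                    "sex": sex,
                    "state": state,
                    "claims_aci": claims_aci,
                    "registry_aci": registry_aci,
                    "pct_diff": pct,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["site", "algorithm_label", "sex", "state",
                 "claims_aci", "registry_aci", "pct_diff"],
    )


# ---------------------------------------------------------------------------
# Validation against ground truth
# ---------------------------------------------------------------------------

def validation_metrics(
    cases: pd.DataFrame,
    ground_truth: pd.DataFrame,
    cohort: CohortResult | pd.DataFrame,
    site: CancerSite | str,
    algorithm_label: str,
) -> dict:
    """Sensitivity and PPV of one algorithm against true incident status.

    TP are identified cases whose truth label is INCIDENT_2013; FP are
    identified cases with any other label; FN are truly incident cohort
    members (of eligible sex) the algorithm missed.  Undefined ratios are
    returned as NaN.
    """
    site = get_site(site)
    frame = cohort.frame if isinstance(cohort, CohortResult) else cohort
    eligible = frame.loc[frame["sex"].isin(sorted(site.eligible_sexes)), "person_id"]
    eligible_set = set(eligible.to_numpy())

    truth = ground_truth[ground_truth["site"] == site.name]
    incident = set(
        truth.loc[truth["case_type"] == "INCIDENT_2013", "person_id"].to_numpy()
    ) & eligible_set

    sel = cases[
        (cases["site"] == site.name) & (cases["algorithm_label"] == algorithm_label)
    ]
    identified = set(sel["person_id"].to_numpy())

    tp = len(identified & incident)
    fp = len(identified - incident)
    fn = len(incident - identified)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    return {"TP": tp, "FP": fp, "FN": fn, "sensitivity": sens, "ppv": ppv}
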