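"""Synthetic German-SHI-style claims populations with ground truth.

The generator emulates the structural features that lookback/confirmation
algorithms exploit in real claims data:

* disease onset on the quarterly grid with age-dependent hazards and a
  configurable prevalent-at-start fraction per site;
* recurrent disease after a latency (the onset-to-recurrence gap that
  defeats short lookback periods);
* a coding process that produces G-coded outpatient diagnoses and
  inpatient main-discharge diagnoses around onset, ancillary inpatient
  codes, status-post (Z) coding after treatment, sporadic coding of
  prevalent cases (watchful waiting / foregone treatment), suspected-only
  (V) diagnoses among the disease-free, and a small erroneous-code rate;
* site surgeries with a delay (breast and colorectal only), reduced
  coding for a watchful-waiting fraction of prostate cases;
* background (Gompertz) and post-onset excess mortality, and insurance
  spells with occasional gaps so that the continuous-insurance rule bites.

Every person owns a private random stream derived from
``SeedSequence([seed, person_index])``, so output is reproducible and
independent of iteration order.  Ground-truth labels per person × site
enable sensitivity/PPV evaluation of the identification algorithms,
something registry linkage would be needed for on real data.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .data import (
    FEDERAL_STATES,
    FOREIGN,
    MISSING,
    ClaimsTables,
    INPATIENT_COLUMNS,
    OUTPATIENT_COLUMNS,
    PERSONS_COLUMNS,
    PROCEDURES_COLUMNS,
    SPELLS_COLUMNS,
    SITES,
    get_site,
    quarter_index,
)
from .errors import ConfigError
from .incidence import ESP1976, StandardPopulation

TRUTH_COLUMNS = ["person_id", "site", "true_onset_quarter", "case_type"]
CASE_TYPES = (
    "INCIDENT_2013", "INCIDENT_OTHER_YEAR", "PREVALENT_AT_START",
    "RECURRENT", "SUSPECTED_ONLY", "NONE",
)

# Approximate resident-population shares of the 16 federal states.
_STATE_SHARES = {
    "NW": 0.215, "BY": 0.157, "BW": 0.133, "NI": 0.096, "HE": 0.075,
    "SN": 0.050, "RP": 0.049, "BE": 0.043, "SH": 0.035, "BB": 0.030,
    "ST": 0.027, "TH": 0.026, "HH": 0.022, "MV": 0.020, "SL": 0.012,
    "HB": 0.010,
}

# Birth-year bands (inclusive) with weights shaped like an insured adult
# population (mean age ~51 in 2013).
_BIRTH_BANDS = (
    (1919, 1928, 0.03), (1929, 1938, 0.08), (1939, 1948, 0.13),
    (1949, 1958, 0.17), (1959, 1968, 0.17), (1969, 1978, 0.14),
    (1979, 1988, 0.12), (1989, 1998, 0.09), (1999, 2008, 0.07),
)


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass(frozen=True)
class SiteDiseaseModel:
    """Per-site natural-history parameters on the quarterly grid."""

    #: stepwise per-quarter onset hazard: ((min_age, hazard), ...) ascending.
    hazard_by_age: tuple[tuple[int, float], ...]
    prevalence_at_start: float
    recurrence_prob: float
    recurrence_latency_mean_q: float
    case_fatality_per_quarter: float
    surgery_prob: float = 0.0
    recurrence_surgery_prob: float = 0.0
    surgery_delay_mean_q: float = 0.5
    watchful_waiting_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("prevalence_at_start", "recurrence_prob",
                     "case_fatality_per_quarter", "surgery_prob",
                     "recurrence_surgery_prob", "watchful_waiting_fraction"):
            _check_prob(name, getattr(self, name))
        for age, h in self.hazard_by_age:
            _check_prob(f"hazard at age {age}", h)
        if self.recurrence_latency_mean_q < 1:
            raise ConfigError("recurrence latency mean must be >= 1 quarter")

    def hazard(self, age: int) -> float:
        h = 0.0
        for min_age, hz in self.hazard_by_age:
            if age >= min_age:
                h = hz
        return h


@dataclass(frozen=True)
class CodingModel:
    """How true disease states translate into claims records."""

    p_index_coded: float = 0.95        # onset quarter produces a diagnosis
    p_index_inpatient: float = 0.35    # ... as inpatient main-discharge
    p_followup_g: float = 0.8          # per-quarter G during treatment
    followup_quarters: int = 4
    p_inpatient_ancillary: float = 0.08
    z_after_treatment: float = 0.4     # per-quarter Z in surveillance
    z_surveillance_quarters: int = 12
    z_long_term: float = 0.15
    prevalent_coding_rate: float = 0.12   # sporadic coding of prevalent cases
    prevalent_g_share: float = 0.5
    suspected_only_rate: float = 0.01     # per-person V among disease-free
    stray_code_rate: float = 0.001        # per-quarter erroneous site code
    ww_coding_factor: float = 0.35        # follow-up reduction, watchful waiting

    def __post_init__(self) -> None:
        for name in ("p_index_coded", "p_index_inpatient", "p_followup_g",
                     "p_inpatient_ancillary", "z_after_treatment", "z_long_term",
                     "prevalent_coding_rate", "prevalent_g_share",
                     "suspected_only_rate", "stray_code_rate", "ww_coding_factor"):
            _check_prob(name, getattr(self, name))


@dataclass(frozen=True)
class EnrollmentModel:
    """Insurance-spell generation."""

    p_full_span: float = 0.85    # enrolled for the whole calendar span
    gap_prob: float = 0.08       # one coverage gap somewhere in the spell
    gap_mean_days: float = 30.0  # geometric; a fair share exceeds 28 days

    def __post_init__(self) -> None:
        _check_prob("p_full_span", self.p_full_span)
        _check_prob("gap_prob", self.gap_prob)
        if self.gap_mean_days < 1:
            raise ConfigError("gap_mean_days must be >= 1")


def _default_disease() -> dict[str, SiteDiseaseModel]:
    return {
        "BREAST": SiteDiseaseModel(
            hazard_by_age=((0, 2e-6), (30, 1.2e-4), (50, 7.5e-4), (70, 8.5e-4)),
            prevalence_at_start=0.015,
            recurrence_prob=0.15,
            recurrence_latency_mean_q=8.0,
            case_fatality_per_quarter=0.009,
            surgery_prob=0.75,
            recurrence_surgery_prob=0.30,
        ),
        "PROSTATE": SiteDiseaseModel(
            hazard_by_age=((0, 1e-6), (50, 6.0e-4), (70, 1.1e-3)),
            prevalence_at_start=0.012,
            recurrence_prob=0.12,
            recurrence_latency_mean_q=10.0,
            case_fatality_per_quarter=0.007,
            watchful_waiting_fraction=0.25,
        ),
        "COLORECTAL": SiteDiseaseModel(
            hazard_by_age=((0, 2e-6), (50, 2.2e-4), (70, 6.5e-4)),
            prevalence_at_start=0.006,
            recurrence_prob=0.15,
            recurrence_latency_mean_q=8.0,
            case_fatality_per_quarter=0.028,
            surgery_prob=0.85,
            recurrence_surgery_prob=0.35,
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of the synthetic population."""

    n_persons: int = 50_000
    seed: int = 20130101
    first_year: int = 2006
    last_year: int = 2014
    sex_female_prob: float = 0.55
    birth_year_bands: tuple[tuple[int, int, float], ...] = _BIRTH_BANDS
    state_probs: tuple[tuple[str, float], ...] = tuple(_STATE_SHARES.items())
    p_foreign: float = 0.003
    p_missing_state: float = 0.004
    p_missing_sex: float = 0.0002
    p_missing_birth_year: float = 0.001
    enrollment: EnrollmentModel = field(default_factory=EnrollmentModel)
    coding: CodingModel = field(default_factory=CodingModel)
    disease: dict[str, SiteDiseaseModel] = field(default_factory=_default_disease)
    # Gompertz background mortality: annual q(age) = a * exp(b * age)
    mortality_a: float = 4e-5
    mortality_b: float = 0.09

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ConfigError("n_persons must be >= 1")
        if self.last_year < self.first_year:
            raise ConfigError("calendar span is inverted")
        _check_prob("sex_female_prob", self.sex_female_prob)
        for name in ("p_foreign", "p_missing_state", "p_missing_sex",
                     "p_missing_birth_year"):
            _check_prob(name, getattr(self, name))
        wsum = sum(w for _, _, w in self.birth_year_bands)
        if abs(wsum - 1.0) > 1e-9:
            raise ConfigError(f"birth-year band weights sum to {wsum}, expected 1")
        for site in self.disease:
            if site not in {s.name for s in SITES.values()}:
                raise ConfigError(f"unknown disease site {site!r}")

    # -- convenience constructors ------------------------------------------

    @classmethod
    def perfect_coding(
        cls,
        n_persons: int = 50_000,
        seed: int = 20130101,
        hazard: float = 6e-4,
    ) -> "SimulationConfig":
        """A noise-free configuration for parameter-recovery checks.

        Constant onset hazard across ages and sites, index and follow-up
        coding with probability one, no prevalence, recurrence, suspected
        or stray coding, no mortality, and full-span enrollment, so every
        true onset is identified by any confirmed algorithm and vice versa.
        """
        disease = {
            name: SiteDiseaseModel(
                hazard_by_age=((0, hazard),),
                prevalence_at_start=0.0,
                recurrence_prob=0.0,
                recurrence_latency_mean_q=8.0,
                case_fatality_per_quarter=0.0,
                surgery_prob=1.0 if name != "PROSTATE" else 0.0,
                surgery_delay_mean_q=0.0,
            )
            for name in ("BREAST", "PROSTATE", "COLORECTAL")
        }
        coding = CodingModel(
            p_index_coded=1.0, p_index_inpatient=0.0, p_followup_g=1.0,
            followup_quarters=40, p_inpatient_ancillary=0.0,
            z_after_treatment=0.0, z_long_term=0.0,
            prevalent_coding_rate=0.0, suspected_only_rate=0.0,
            stray_code_rate=0.0,
        )
        enrollment = EnrollmentModel(p_full_span=1.0, gap_prob=0.0)
        return cls(
            n_persons=n_persons, seed=seed, disease=disease, coding=coding,
            enrollment=enrollment, mortality_a=0.0,
            p_foreign=0.0, p_missing_state=0.0, p_missing_sex=0.0,
            p_missing_birth_year=0.0,
        )

    # -- YAML --------------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["disease"] = {k: asdict(v) for k, v in self.disease.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "enrollment" in d and isinstance(d["enrollment"], dict):
            d["enrollment"] = EnrollmentModel(**d["enrollment"])
        if "coding" in d and isinstance(d["coding"], dict):
            d["coding"] = CodingModel(**d["coding"])
        if "disease" in d:
            d["disease"] = {
                k: (SiteDiseaseModel(
                        **{**v, "hazard_by_age": tuple(map(tuple, v["hazard_by_age"]))})
                    if isinstance(v, dict) else v)
                for k, v in d["disease"].items()
            }
        for key in ("birth_year_bands", "state_probs"):
            if key in d:
                d[key] = tuple(map(tuple, d[key]))
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"invalid simulation config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------

def sample_recurrence_latency(rng: np.random.Generator, mean_q: float) -> int:
    """Quarters between onset and recurrence, geometric with the given mean."""
    return int(rng.geometric(1.0 / mean_q))


def _first_success(rng: np.random.Generator, hazards: np.ndarray) -> int | None:
    """Index of the first Bernoulli success along a hazard vector, or None."""
    if not hazards.any():
        return None
    hits = rng.random(hazards.shape[0]) < hazards
    idx = int(np.argmax(hits))
    return idx if hits[idx] else None


_SITE_CODES = {
    "BREAST": ("C50.1", "C50.4", "C50.8", "C50.9"),
    "PROSTATE": ("C61",),
    "COLORECTAL": ("C18.2", "C18.7", "C19", "C20", "C21.0"),
}

_QUARTER_STARTS = {1: (1, 1), 2: (4, 1), 3: (7, 1), 4: (10, 1)}


def _random_date_in_quarter(rng: np.random.Generator, qidx: int) -> dt.date:
    year, q = qidx // 4, qidx % 4 + 1
    month, day = _QUARTER_STARTS[q]
    start = dt.date(year, month, day)
    if q == 4:
        end = dt.date(year, 12, 31)
    else:
        m2, d2 = _QUARTER_STARTS[q + 1]
        end = dt.date(year, m2, d2) - dt.timedelta(days=1)
    span = (end - start).days + 1
    return start + dt.timedelta(days=int(rng.integers(0, span)))


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def _simulate_person(i: int, cfg: SimulationConfig, buf: "_Buffers") -> None:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
    pid = f"P{i:07d}"
    q0 = quarter_index(cfg.first_year, 1)
    q1 = quarter_index(cfg.last_year, 4)
    n_q = q1 - q0 + 1
    cm = cfg.coding

    # demographics -----------------------------------------------------
    sex = "F" if rng.random() < cfg.sex_female_prob else "M"
    bands = cfg.birth_year_bands
    bi = int(rng.choice(len(bands), p=[w for _, _, w in bands]))
    lo, hi, _ = bands[bi]
    birth_year: int | None = int(rng.integers(lo, hi + 1))
    u = rng.random()
    if u < cfg.p_foreign:
        state = FOREIGN
    elif u < cfg.p_foreign + cfg.p_missing_state:
        state = MISSING
    else:
        names = [s for s, _ in cfg.state_probs]
        probs = np.array([w for _, w in cfg.state_probs])
        state = str(names[int(rng.choice(len(names), p=probs / probs.sum()))])
    if rng.random() < cfg.p_missing_sex:
        sex = MISSING
    if rng.random() < cfg.p_missing_birth_year:
        birth_year = None

    # ages per simulated quarter (missing birth year: no disease model)
    years = cfg.first_year + np.arange(n_q) // 4
    ages = (years - birth_year) if birth_year is not None else None

    # disease onsets ----------------------------------------------------
    onsets: dict[str, int | None] = {}
    recurrences: dict[str, int | None] = {}
    for site_name, dm in cfg.disease.items():
        site = get_site(site_name.lower())
        onsets[site_name] = None
        recurrences[site_name] = None
        if sex not in site.eligible_sexes or ages is None:
            continue
        if rng.random() < dm.prevalence_at_start:
            onsets[site_name] = q0 - 1 - int(rng.integers(0, 40))
        else:
            hazards = np.array([dm.hazard(max(int(a), 0)) for a in ages])
            k = _first_success(rng, hazards)
            if k is not None:
                onsets[site_name] = q0 + k
        if onsets[site_name] is not None and rng.random() < dm.recurrence_prob:
            rq = onsets[site_name] + sample_recurrence_latency(
                rng, dm.recurrence_latency_mean_q
            )
            if q0 <= rq <= q1:
                recurrences[site_name] = rq

    # death -------------------------------------------------------------
    if ages is not None and (cfg.mortality_a > 0 or any(
        o is not None for o in onsets.values()
    )):
        hz = cfg.mortality_a * np.exp(cfg.mortality_b * np.maximum(ages, 0)) / 4.0
        for site_name, dm in cfg.disease.items():
            o = onsets[site_name]
            if o is not None and dm.case_fatality_per_quarter > 0:
                k_on = max(o - q0, 0)
                hz = hz.copy()
                hz[k_on:] += dm.case_fatality_per_quarter
        hz = np.clip(hz, 0.0, 1.0)
        k = _first_success(rng, hz)
        death_q: int | None = q0 + k if k is not None else None
    else:
        death_q = None

    # enrollment spells ---------------------------------------------------
    span_start = dt.date(cfg.first_year, 1, 1)
    span_end = dt.date(cfg.last_year, 12, 31)
    em = cfg.enrollment
    if rng.random() < em.p_full_span:
        enroll_start = span_start
    else:
        offset = int(rng.integers(0, (dt.date(2013, 1, 1) - span_start).days))
        enroll_start = span_start + dt.timedelta(days=offset)

    death_date: dt.date | None = None
    if death_q is not None:
        death_date = max(_random_date_in_quarter(rng, death_q), enroll_start)
        death_q = quarter_index(death_date.year, (death_date.month - 1) // 3 + 1)
    enroll_end = min(span_end, death_date) if death_date else span_end

    spells: list[tuple[dt.date, dt.date]] = []
    cov_days = (enroll_end - enroll_start).days
    if cov_days >= 0:
        if rng.random() < em.gap_prob and cov_days > 200:
            gap_len = int(rng.geometric(1.0 / em.gap_mean_days))
            gap_off = int(rng.integers(90, cov_days - 100))
            g0 = enroll_start + dt.timedelta(days=gap_off)
            g1 = min(g0 + dt.timedelta(days=gap_len - 1), enroll_end)
            spells.append((enroll_start, g0 - dt.timedelta(days=1)))
            if g1 < enroll_end:
                spells.append((g1 + dt.timedelta(days=1), enroll_end))
        else:
            spells.append((enroll_start, enroll_end))

    # observable quarters: covered by a spell and not after death
    obs = np.zeros(n_q, dtype=bool)
    for s, e in spells:
        obs[max(quarter_index(s.year, (s.month - 1) // 3 + 1) - q0, 0):
            min(quarter_index(e.year, (e.month - 1) // 3 + 1) - q0 + 1, n_q)] = True
    if death_q is not None:
        obs[max(death_q - q0 + 1, 0):] = False

    buf.persons.append((
        pid, sex, "" if birth_year is None else str(birth_year), state,
        death_date.isoformat() if death_date else "",
    ))
    for s, e in spells:
        buf.spells.append((pid, s.isoformat(), e.isoformat()))

    def emit_outpt(k: int, code: str, cert: str) -> None:
        buf.outpatient.append((pid, f"{cfg.first_year + k // 4}Q{k % 4 + 1}", code, cert))

    def emit_inpt(k: int, code: str, dx_type: str) -> None:
        d = _random_date_in_quarter(rng, q0 + k)
        adm = d - dt.timedelta(days=int(rng.integers(1, 15)))
        buf.inpatient.append((pid, adm.isoformat(), d.isoformat(), code, dx_type))

    def site_code(site_name: str) -> str:
        codes = _SITE_CODES[site_name]
        return codes[int(rng.integers(0, len(codes)))]

    # coding per site -----------------------------------------------------
    any_v: dict[str, bool] = {}
    for site_name, dm in cfg.disease.items():
        site = get_site(site_name.lower())
        any_v[site_name] = False
        if sex not in site.eligible_sexes:
            continue
        onset = onsets[site_name]
        rec = recurrences[site_name]
        ww = (
            dm.watchful_waiting_fraction > 0
            and rng.random() < dm.watchful_waiting_fraction
        )
        fup = cm.p_followup_g * (cm.ww_coding_factor if ww else 1.0)

        def code_episode(start_q: int, index_style: bool, surgery_p: float) -> None:
            k_start = start_q - q0
            if 0 <= k_start < n_q and obs[k_start] and index_style:
                if rng.random() < cm.p_index_coded:
                    if rng.random() < cm.p_index_inpatient:
                        emit_inpt(k_start, site_code(site_name), "MAIN_DISCHARGE")
                    else:
                        emit_outpt(k_start, site_code(site_name), "G")
            # treatment follow-up
            for k in range(k_start + 1, min(k_start + 1 + cm.followup_quarters, n_q)):
                if k < 0 or not obs[k]:
                    continue
                if rng.random() < fup:
                    emit_outpt(k, site_code(site_name), "G")
                if rng.random() < cm.p_inpatient_ancillary:
                    emit_inpt(k, site_code(site_name), "ANCILLARY")
            # surveillance Z coding
            k_surv = k_start + 1 + cm.followup_quarters
            for k in range(max(k_surv, 0), n_q):
                if not obs[k]:
                    continue
                rate = (
                    cm.z_after_treatment
                    if k < k_surv + cm.z_surveillance_quarters
                    else cm.z_long_term
                )
                if rng.random() < rate:
                    emit_outpt(k, site_code(site_name), "Z")
            if site.surgery_classes and rng.random() < surgery_p:
                delay = (
                    int(rng.geometric(1.0 / (1.0 + dm.surgery_delay_mean_q))) - 1
                )
                ks = k_start + delay
                if 0 <= ks < n_q and obs[ks]:
                    classes = sorted(site.surgery_classes)
                    cls = classes[int(rng.integers(0, len(classes)))]
                    d = _random_date_in_quarter(rng, q0 + ks)
                    buf.procedures.append((pid, d.isoformat(), cls))

        if onset is not None and onset >= q0:
            code_episode(onset, True, dm.surgery_prob)
        elif onset is not None:  # prevalent at start: sporadic coding
            for k in range(n_q):
                if rec is not None and k >= rec - q0:
                    break
                if obs[k] and rng.random() < cm.prevalent_coding_rate:
                    cert = "G" if rng.random() < cm.prevalent_g_share else "Z"
                    emit_outpt(k, site_code(site_name), cert)
        if rec is not None:
            code_episode(rec, True, dm.recurrence_surgery_prob)

        if onset is None:
            if rng.random() < cm.suspected_only_rate:
                ks = np.flatnonzero(obs)
                if len(ks):
                    k = int(ks[int(rng.integers(0, len(ks)))])
                    emit_outpt(k, site_code(site_name), "V")
                    any_v[site_name] = True
        # erroneous codes, disease state notwithstanding
        if cm.stray_code_rate > 0:
            hits = np.flatnonzero(rng.random(n_q) < cm.stray_code_rate)
            for k in hits:
                if obs[k]:
                    cert = "G" if rng.random() < 0.7 else "Z"
                    emit_outpt(int(k), site_code(site_name), cert)

    # ground truth --------------------------------------------------------
    y13_lo, y13_hi = quarter_index(2013, 1), quarter_index(2013, 4)
    for site_name in cfg.disease:
        onset = onsets[site_name]
        rec = recurrences[site_name]
        if onset is None:
            label = "SUSPECTED_ONLY" if any_v.get(site_name) else "NONE"
            oq = ""
        else:
            oq = f"{onset // 4}Q{onset % 4 + 1}"
            if y13_lo <= onset <= y13_hi:
                label = "INCIDENT_2013"
            elif rec is not None:
                label = "RECURRENT"
            elif onset < q0:
                label = "PREVALENT_AT_START"
            else:
                label = "INCIDENT_OTHER_YEAR"
        buf.truth.append((pid, site_name, oq, label))


class _Buffers:
    def __init__(self) -> None:
        self.persons: list = []
        self.spells: list = []
        self.outpatient: list = []
        self.inpatient: list = []
        self.procedures: list = []
        self.truth: list = []


def generate_population(config: SimulationConfig) -> tuple[ClaimsTables, pd.DataFrame]:
    """Generate claims tables plus a ground-truth table per person × site.

    Deterministic for a fixed config (including seed); every diagnosis,
    procedure and death belongs to a generated person, and no event falls
    outside that person's insurance coverage or after the death quarter.
    """
    buf = _Buffers()
    for i in range(config.n_persons):
        _simulate_person(i, config, buf)
    tables = ClaimsTables(
        persons=pd.DataFrame(buf.persons, columns=PERSONS_COLUMNS),
        spells=pd.DataFrame(buf.spells, columns=SPELLS_COLUMNS),
        outpatient=pd.DataFrame(buf.outpatient, columns=OUTPATIENT_COLUMNS),
        inpatient=pd.DataFrame(buf.inpatient, columns=INPATIENT_COLUMNS),
        procedures=pd.DataFrame(buf.procedures, columns=PROCEDURES_COLUMNS),
    )
    truth = pd.DataFrame(buf.truth, columns=TRUTH_COLUMNS)
    return tables, truth


# ---------------------------------------------------------------------------
# Registry-style benchmark from ground truth
# ---------------------------------------------------------------------------

def generate_registry_benchmark(
    truth: pd.DataFrame,
    persons: pd.DataFrame,
    std: StandardPopulation = ESP1976,
    reference_year: int = 2013,
) -> pd.DataFrame:
    """Registry-style ACI table computed directly from true 2013 onsets.

    Denominators are all generated persons with valid sex, birth year and
    a German federal state — the registry sees the whole population, not
    the insured cohort.  Rows: site × sex (eligible sexes, plus ALL for
    two-sex sites) × state (16 states plus ALL).
    """
    valid = persons[
        persons["sex"].isin(["F", "M"])
        & (persons["birth_year"] != MISSING)
        & persons["state"].isin(list(FEDERAL_STATES))
    ].copy()
    valid["age"] = reference_year - pd.to_numeric(valid["birth_year"])
    incident = truth[truth["case_type"] == "INCIDENT_2013"]
    merged = incident.merge(valid, on="person_id", how="inner")

    def band_counts(ages: np.ndarray) -> np.ndarray:
        return np.bincount(std.assign(ages), minlength=std.n_bands).astype(float)

    rows = []
    import warnings as _warnings

    for site_key, site in SITES.items():
        cases_site = merged[merged["site"] == site.name]
        sex_levels = sorted(site.eligible_sexes)
        if len(sex_levels) > 1:
            sex_levels = sex_levels + ["ALL"]
        for sex in sex_levels:
            d = valid if sex == "ALL" else valid[valid["sex"] == sex]
            c = cases_site if sex == "ALL" else cases_site[cases_site["sex"] == sex]
            for state in list(FEDERAL_STATES) + ["ALL"]:
                dd = d if state == "ALL" else d[d["state"] == state]
                cc = c if state == "ALL" else c[c["state"] == state]
                if len(dd) == 0:
                    aci = float("nan")
                else:
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore")
                        from .incidence import age_standardized_cumulative_incidence

                        aci = age_standardized_cumulative_incidence(
                            band_counts(cc["age"].to_numpy()),
                            band_counts(dd["age"].to_numpy()),
                            std,
                        )
                rows.append({"site": site.name, "sex": sex, "state": state, "aci": aci})
    return pd.DataFrame(rows, columns=["site", "sex", "state", "aci"])
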