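"""Claims-data domain types and delimited-file input/output.

German statutory health insurance (SHI) claims carry outpatient diagnoses
at calendar-quarter resolution with a mandatory diagnostic-certainty marker
(G certain, V suspected, Z status post, A excluded), dated inpatient
diagnoses flagged as main-discharge or ancillary, dated procedures, and
insurance spells per person.  The bulk in-memory representation is a bundle
of pandas DataFrames (:class:`ClaimsTables`); small frozen dataclasses give
the typed record-level surface used by the simulator, by per-person rule
evaluation and by tests.
"""
from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError

MISSING = ""  # canonical encoding of a missing categorical field

#: Two-letter codes for the 16 German federal states (Länder).
FEDERAL_STATES: dict[str, str] = {
    "BW": "Baden-Württemberg",
    "BY": "Bavaria",
    "BE": "Berlin",
    "BB": "Brandenburg",
    "HB": "Bremen",
    "HH": "Hamburg",
    "HE": "Hesse",
    "MV": "Mecklenburg-Western Pomerania",
    "NI": "Lower Saxony",
    "NW": "North Rhine-Westphalia",
    "RP": "Rhineland-Palatinate",
    "SL": "Saarland",
    "SN": "Saxony",
    "ST": "Saxony-Anhalt",
    "SH": "Schleswig-Holstein",
    "TH": "Thuringia",
}
FOREIGN = "FOREIGN"

CERTAINTY_CODES = frozenset({"G", "V", "Z", "A"})
DX_TYPES = frozenset({"MAIN_DISCHARGE", "ANCILLARY"})
PROC_CLASSES = frozenset(
    {"LUMPECTOMY", "MASTECTOMY", "ENDOSCOPY", "COLORECTAL_SURGERY", "OTHER"}
)
SEXES = frozenset({"F", "M"})


# ---------------------------------------------------------------------------
# Quarters
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Quarter:
    """A calendar quarter, totally ordered, serialised as ``YYYYQn``.

    The linear index ``4 * year + (q - 1)`` makes window arithmetic on the
    quarterly grid a plain integer subtraction.
    """

    year: int
    q: int

    def __post_init__(self) -> None:
        if self.q not in (1, 2, 3, 4):
            raise ValueError(f"quarter-of-year must be 1..4, got {self.q!r}")

    @property
    def index(self) -> int:
        return 4 * self.year + (self.q - 1)

    @classmethod
    def from_index(cls, idx: int) -> "Quarter":
        return cls(idx // 4, idx % 4 + 1)

    @classmethod
    def from_date(cls, d: dt.date) -> "Quarter":
        return cls(d.year, (d.month - 1) // 3 + 1)

    @classmethod
    def parse(cls, s: str) -> "Quarter":
        try:
            year, q = s.upper().split("Q")
            return cls(int(year), int(q))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"not a quarter string (YYYYQn): {s!r}") from exc

    def shift(self, n: int) -> "Quarter":
        return Quarter.from_index(self.index + n)

    def __str__(self) -> str:
        return f"{self.year}Q{self.q}"


def date_to_quarter(d: dt.date | str) -> Quarter:
    """Map a calendar date onto the quarterly grid of outpatient claims."""
    if isinstance(d, str):
        try:
            d = dt.date.fromisoformat(d)
        except ValueError as exc:
            raise ValueError(f"malformed ISO date: {d!r}") from exc
    if not isinstance(d, dt.date):
        raise ValueError(f"not a date: {d!r}")
    return Quarter.from_date(d)


def quarter_index(year: int, q: int) -> int:
    return 4 * year + (q - 1)


# ---------------------------------------------------------------------------
# Cancer sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CancerSite:
    """A cancer entity defined by its 3-character ICD-10 categories.

    ``surgery_classes`` lists the abstract procedure classes accepted as a
    surgical confirmatory event (empty for prostate, where no surgical
    confirmation is defined).
    """

    name: str
    icd_prefixes: frozenset[str]
    eligible_sexes: frozenset[str]
    surgery_classes: frozenset[str]


BREAST = CancerSite(
    "BREAST", frozenset({"C50"}), frozenset({"F"}),
    frozenset({"LUMPECTOMY", "MASTECTOMY"}),
)
PROSTATE = CancerSite("PROSTATE", frozenset({"C61"}), frozenset({"M"}), frozenset())
COLORECTAL = CancerSite(
    "COLORECTAL", frozenset({"C18", "C19", "C20", "C21"}), frozenset({"F", "M"}),
    frozenset({"ENDOSCOPY", "COLORECTAL_SURGERY"}),
)

SITES: dict[str, CancerSite] = {
    "breast": BREAST,
    "prostate": PROSTATE,
    "colorectal": COLORECTAL,
}


def get_site(name: str | CancerSite) -> CancerSite:
    if isinstance(name, CancerSite):
        return name
    try:
        return SITES[name.lower()]
    except KeyError as exc:
        raise KeyError(f"unknown cancer site {name!r}; known: {sorted(SITES)}") from exc


def normalize_icd(code: str) -> str:
    """Upper-case an ICD code and strip the dot: ``c50.4`` -> ``C504``."""
    return code.strip().upper().replace(".", "")


def icd_matches_site(code: str, site: CancerSite) -> bool:
    """True iff the 3-character ICD category of ``code`` belongs to ``site``.

    Matching is case- and dot-insensitive and looks only at the category,
    so any fourth-digit subdivision of C50 matches breast cancer.
    """
    if not code or not code.strip():
        return False
    return normalize_icd(code)[:3] in site.icd_prefixes


# ---------------------------------------------------------------------------
# Record dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PersonRecord:
    person_id: str
    sex: str = MISSING                  # "F", "M" or MISSING
    birth_year: int | None = None
    state: str = MISSING                # federal-state code, FOREIGN or MISSING
    spells: tuple[tuple[dt.date, dt.date], ...] = ()
    death_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES and self.sex != MISSING:
            raise ValueError(f"sex must be F, M or missing, got {self.sex!r}")
        prev_end: dt.date | None = None
        for start, end in self.spells:
            if start > end:
                raise ValueError(f"spell start {start} after end {end}")
            if prev_end is not None and start <= prev_end:
                raise ValueError("insurance spells must be sorted and disjoint")
            prev_end = end
        if self.death_date is not None and self.spells:
            if self.death_date < self.spells[0][0]:
                raise ValueError("death date precedes first insurance spell")


@dataclass(frozen=True)
class OutpatientDx:
    person_id: str
    quarter: Quarter
    icd_code: str
    certainty: str

    def __post_init__(self) -> None:
        if self.certainty not in CERTAINTY_CODES:
            raise ValueError(
                f"certainty must be one of G/V/Z/A, got {self.certainty!r}"
            )


@dataclass(frozen=True)
class InpatientDx:
    person_id: str
    admission_date: dt.date
    discharge_date: dt.date
    icd_code: str
    dx_type: str

    def __post_init__(self) -> None:
        if self.admission_date > self.discharge_date:
            raise ValueError("admission after discharge")
        if self.dx_type not in DX_TYPES:
            raise ValueError(f"dx_type must be in {sorted(DX_TYPES)}, got {self.dx_type!r}")


@dataclass(frozen=True)
class ProcedureRecord:
    person_id: str
    date: dt.date
    proc_class: str

    def __post_init__(self) -> None:
        if self.proc_class not in PROC_CLASSES:
            raise ValueError(f"unknown procedure class {self.proc_class!r}")


# ---------------------------------------------------------------------------
# Table bundle
# ---------------------------------------------------------------------------

PERSONS_COLUMNS = ["person_id", "sex", "birth_year", "state", "death_date"]
SPELLS_COLUMNS = ["person_id", "start", "end"]
OUTPATIENT_COLUMNS = ["person_id", "quarter", "icd_code", "certainty"]
INPATIENT_COLUMNS = ["person_id", "admission_date", "discharge_date", "icd_code", "dx_type"]
PROCEDURES_COLUMNS = ["person_id", "date", "proc_class"]

_FILES = {
    "persons": ("persons.csv", PERSONS_COLUMNS),
    "spells": ("spells.csv", SPELLS_COLUMNS),
    "outpatient": ("outpatient_dx.csv", OUTPATIENT_COLUMNS),
    "inpatient": ("inpatient_dx.csv", INPATIENT_COLUMNS),
    "procedures": ("procedures.csv", PROCEDURES_COLUMNS),
}


def _empty(columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class ClaimsTables:
    """The five claims tables as string-typed pandas DataFrames.

    All columns are kept as plain strings (dates ISO ``YYYY-MM-DD``,
    quarters ``YYYYQn``, empty string for missing) so that a write/read
    round trip is lossless; consumers parse what they need.
    """

    persons: pd.DataFrame
    spells: pd.DataFrame
    outpatient: pd.DataFrame
    inpatient: pd.DataFrame
    procedures: pd.DataFrame
    issues: list[str] = field(default_factory=list)

    @classmethod
    def empty(cls) -> "ClaimsTables":
        return cls(*(_empty(cols) for _, cols in _FILES.values()))

    # -- record-level construction (used by tests and the simulator) --------

    @classmethod
    def from_records(
        cls,
        persons: Iterable[PersonRecord] = (),
        outpatient: Iterable[OutpatientDx] = (),
        inpatient: Iterable[InpatientDx] = (),
        procedures: Iterable[ProcedureRecord] = (),
    ) -> "ClaimsTables":
        prow, srow = [], []
        for p in persons:
            prow.append(
                {
                    "person_id": p.person_id,
                    "sex": p.sex,
                    "birth_year": "" if p.birth_year is None else str(p.birth_year),
                    "state": p.state,
                    "death_date": "" if p.death_date is None else p.death_date.isoformat(),
                }
            )
            for start, end in p.spells:
                srow.append(
                    {"person_id": p.person_id, "start": start.isoformat(), "end": end.isoformat()}
                )
        orow = [
            {
                "person_id": o.person_id,
                "quarter": str(o.quarter),
                "icd_code": o.icd_code,
                "certainty": o.certainty,
            }
            for o in outpatient
        ]
        irow = [
            {
                "person_id": i.person_id,
                "admission_date": i.admission_date.isoformat(),
                "discharge_date": i.discharge_date.isoformat(),
                "icd_code": i.icd_code,
                "dx_type": i.dx_type,
            }
            for i in inpatient
        ]
        crow = [
            {"person_id": c.person_id, "date": c.date.isoformat(), "proc_class": c.proc_class}
            for c in procedures
        ]
        return cls(
            persons=pd.DataFrame(prow, columns=PERSONS_COLUMNS) if prow else _empty(PERSONS_COLUMNS),
            spells=pd.DataFrame(srow, columns=SPELLS_COLUMNS) if srow else _empty(SPELLS_COLUMNS),
            outpatient=pd.DataFrame(orow, columns=OUTPATIENT_COLUMNS) if orow else _empty(OUTPATIENT_COLUMNS),
            inpatient=pd.DataFrame(irow, columns=INPATIENT_COLUMNS) if irow else _empty(INPATIENT_COLUMNS),
            procedures=pd.DataFrame(crow, columns=PROCEDURES_COLUMNS) if crow else _empty(PROCEDURES_COLUMNS),
        )

    # -- I/O ---------------------------------------------------------------

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for attr, (fname, cols) in _FILES.items():
            df = getattr(self, attr)
            path = directory / fname
            df.to_csv(path, index=False, columns=list(cols))
            paths[attr] = path
        return paths


def _valid_date(s: str) -> bool:
    try:
        dt.date.fromisoformat(s)
        return True
    except (ValueError, TypeError):
        return False


_QUARTER_RE = re.compile(r"\d{4}Q[1-4]$")


def _valid_quarter(s: str) -> bool:
    return bool(_QUARTER_RE.fullmatch(s))


def _read_table(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing input file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    return df[list(columns)]


def read_claims_tables(directory: str | Path) -> ClaimsTables:
    """Read the five claims tables from ``directory``.

    Rows violating a type invariant (unknown certainty marker, unparseable
    date or quarter, inverted date interval, unknown procedure class) are
    dropped; one diagnostic per rejected row is collected on the returned
    bundle's ``issues`` list.  A missing column raises :class:`SchemaError`.
    """
    directory = Path(directory)
    raw = {attr: _read_table(directory / fname, cols) for attr, (fname, cols) in _FILES.items()}
    issues: list[str] = []

    def keep(attr: str, mask: pd.Series, reason: str) -> pd.DataFrame:
        df = raw[attr]
        bad = df.index[~mask]
        for i in bad:
            issues.append(f"{_FILES[attr][0]} row {i + 2}: {reason}")
        return df.loc[mask].reset_index(drop=True)

    p = raw["persons"]
    mask = (
        p["sex"].isin(["F", "M", MISSING])
        & (p["birth_year"].str.fullmatch(r"\d{4}") | (p["birth_year"] == MISSING))
        & (p["state"].isin(list(FEDERAL_STATES) + [FOREIGN, MISSING]))
        & (p["death_date"].map(_valid_date) | (p["death_date"] == MISSING))
    )
    raw["persons"] = keep("persons", mask, "invalid person field")

    s = raw["spells"]
    ok = s["start"].map(_valid_date) & s["end"].map(_valid_date)
    ok &= ok & (s["start"] <= s["end"])  # ISO strings sort chronologically
    raw["spells"] = keep("spells", ok, "invalid or inverted spell interval")

    o = raw["outpatient"]
    mask = o["quarter"].map(_valid_quarter) & o["certainty"].isin(list(CERTAINTY_CODES))
    raw["outpatient"] = keep("outpatient", mask, "invalid quarter or certainty marker")

    i = raw["inpatient"]
    mask = (
        i["admission_date"].map(_valid_date)
        & i["discharge_date"].map(_valid_date)
        & i["dx_type"].isin(list(DX_TYPES))
    )
    mask &= mask & (i["admission_date"] <= i["discharge_date"])
    raw["inpatient"] = keep("inpatient", mask, "invalid dates or dx_type")

    c = raw["procedures"]
    mask = c["date"].map(_valid_date) & c["proc_class"].isin(list(PROC_CLASSES))
    raw["procedures"] = keep("procedures", mask, "invalid date or procedure class")

    return ClaimsTables(**raw, issues=issues)
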