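"""Random small claims populations for oracle-equivalence testing."""
from __future__ import annotations

import datetime as dt

import numpy as np

from claimsinc.data import (
    ClaimsTables,
    InpatientDx,
    OutpatientDx,
    PersonRecord,
    ProcedureRecord,
    Quarter,
)

_CODES = ["C50.1", "C50.9", "C61", "C18.2", "C19", "C20", "C21.0", "C22.0", "I10", "E11.9"]
_CERTS = ["G", "V", "Z", "A"]
_DX_TYPES = ["MAIN_DISCHARGE", "ANCILLARY"]
_PROCS = ["LUMPECTOMY", "MASTECTOMY", "ENDOSCOPY", "COLORECTAL_SURGERY", "OTHER"]
_STATES = ["NW", "BY", "BW", "HH"]


def _rand_date(rng, y0=2006, y1=2014) -> dt.date:
    start = dt.date(y0, 1, 1).toordinal()
    end = dt.date(y1, 12, 31).toordinal()
    return dt.date.fromordinal(int(rng.integers(start, end + 1)))


def random_population(seed: int, n_persons: int = 12) -> ClaimsTables:
    """A small random population dense in boundary cases.

    Events are thrown uniformly over 2006–2014 with all certainty markers,
    dx types and procedure classes represented; everyone has full coverage
    so the identification rules, not eligibility, are exercised.
    """
    rng = np.random.default_rng(seed)
    persons, outp, inp, procs = [], [], [], []
    for i in range(n_persons):
        pid = f"R{i:03d}"
        sex = "F" if rng.random() < 0.5 else "M"
        death = _rand_date(rng, 2013, 2014) if rng.random() < 0.15 else None
        persons.append(
            PersonRecord(
                person_id=pid,
                sex=sex,
                birth_year=int(rng.integers(1930, 1990)),
                state=_STATES[int(rng.integers(0, len(_STATES)))],
                spells=((dt.date(2005, 1, 1), dt.date(2014, 12, 31)),),
                death_date=death,
            )
        )
        for _ in range(int(rng.integers(0, 9))):
            outp.append(
                OutpatientDx(
                    person_id=pid,
                    quarter=Quarter(int(rng.integers(2006, 2015)), int(rng.integers(1, 5))),
                    icd_code=_CODES[int(rng.integers(0, len(_CODES)))],
                    certainty=_CERTS[int(rng.integers(0, len(_CERTS)))],
                )
            )
        for _ in range(int(rng.integers(0, 4))):
            d = _rand_date(rng)
            inp.append(
                InpatientDx(
                    person_id=pid,
                    admission_date=d - dt.timedelta(days=int(rng.integers(0, 20))),
                    discharge_date=d,
                    icd_code=_CODES[int(rng.integers(0, len(_CODES)))],
                    dx_type=_DX_TYPES[int(rng.integers(0, 2))],
                )
            )
        for _ in range(int(rng.integers(0, 3))):
            procs.append(
                ProcedureRecord(
                    person_id=pid,
                    date=_rand_date(rng),
                    proc_class=_PROCS[int(rng.integers(0, len(_PROCS)))],
                )
            )
    return ClaimsTables.from_records(persons, outp, inp, procs)
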