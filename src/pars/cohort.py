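"""Visit/Cohort data model, CSV I/O, and the study inclusion filters.

The unit of analysis is the *visit*: one patient contact with its recorded
drug list.  Patients are longitudinal (1-13 visits in the emulated setting),
so every split and resampling scheme downstream must group by patient.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .knowledge_base import normalize_drug_name

DRUG_SEP = ";"


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class Visit:
    """A single visit: identifiers, demographics, and the unique drug set."""

    visit_id: str
    patient_id: str
    date: _dt.date
    sex: str  # "F" or "M"
    age: float
    drugs: frozenset
    diagnosis: str | None = None

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise CohortError(f"visit {self.visit_id}: sex must be F or M, got {self.sex!r}")
        if self.age < 0:
            raise CohortError(f"visit {self.visit_id}: negative age {self.age}")
        if len(self.drugs) < 1:
            raise CohortError(f"visit {self.visit_id}: empty drug list")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)


@dataclass
class Cohort:
    """An ordered collection of visits with a patient index.

    Invariants enforced on construction: visit ids unique; a patient's sex is
    constant across their visits.
    """

    visits: list = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        sex_by_patient: dict[str, str] = {}
        for v in self.visits:
            if v.visit_id in seen:
                raise CohortError(f"duplicate visit_id {v.visit_id!r}")
            seen.add(v.visit_id)
            prior = sex_by_patient.setdefault(v.patient_id, v.sex)
            if prior != v.sex:
                raise CohortError(f"patient {v.patient_id!r} has inconsistent sex")
        self._by_patient: dict[str, list] = {}
        for v in self.visits:
            self._by_patient.setdefault(v.patient_id, []).append(v)

    def __len__(self):
        return len(self.visits)

    def __iter__(self):
        return iter(self.visits)

    @property
    def patient_ids(self) -> list[str]:
        return list(self._by_patient)

    @property
    def n_patients(self) -> int:
        return len(self._by_patient)

    def patient_visits(self, patient_id: str) -> list:
        return list(self._by_patient[patient_id])

    def subset(self, visit_ids) -> "Cohort":
        keep = set(visit_ids)
        return Cohort([v for v in self.visits if v.visit_id in keep])

    def subset_patients(self, patient_ids) -> "Cohort":
        keep = set(patient_ids)
        return Cohort([v for v in self.visits if v.patient_id in keep])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "visit_id": v.visit_id,
                "patient_id": v.patient_id,
                "date": v.date.isoformat(),
                "sex": v.sex,
                "age": v.age,
                "diagnosis": v.diagnosis or "",
                "drugs": DRUG_SEP.join(sorted(v.drugs)),
            }
            for v in self.visits
        ]
        return pd.DataFrame(rows, columns=["visit_id", "patient_id", "date", "sex", "age", "diagnosis", "drugs"])


def _parse_drugs(raw: str, row_label) -> frozenset:
    parts = [p for p in str(raw).split(DRUG_SEP) if p.strip()]
    if not parts:
        raise CohortError(f"row {row_label}: empty drug list")
    return frozenset(normalize_drug_name(p) for p in parts)


def read_cohort_csv(path) -> Cohort:
    """Read a cohort table: columns visit_id, patient_id, date (ISO-8601),
    sex (F|M), age, diagnosis (optional), drugs (";"-separated).

    Drug strings are canonicalized and collapsed to a set per visit.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["visit_id", "patient_id", "date", "sex", "age", "drugs"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing columns {missing}")
    visits = []
    for idx, row in df.iterrows():
        try:
            date = _dt.date.fromisoformat(row["date"].strip())
        except ValueError:
            raise CohortError(f"{path} row {idx}: unparseable date {row['date']!r}")
        try:
            age = float(row["age"])
        except ValueError:
            raise CohortError(f"{path} row {idx}: unparseable age {row['age']!r}")
        visits.append(
            Visit(
                visit_id=row["visit_id"].strip(),
                patient_id=row["patient_id"].strip(),
                date=date,
                sex=row["sex"].strip().upper(),
                age=age,
                diagnosis=(row.get("diagnosis", "") or "").strip() or None,
                drugs=_parse_drugs(row["drugs"], idx),
            )
        )
    return Cohort(visits)


def write_cohort_csv(cohort: Cohort, path) -> None:
    cohort.to_dataframe().to_csv(path, index=False)


MIN_DRUGS = 2
MIN_AGE = 18.0


def apply_inclusion_filters(cohort: Cohort) -> tuple[Cohort, pd.DataFrame]:
    """Retain visits with >= 2 documented medications and age >= 18 years.

    Returns the filtered cohort and an exclusion log (one row per excluded
    visit with its reason).  Idempotent.
    """
    kept, log = [], []
    for v in cohort:
        if v.n_drugs < MIN_DRUGS:
            log.append({"visit_id": v.visit_id, "reason": f"fewer than {MIN_DRUGS} drugs"})
        elif v.age < MIN_AGE:
            log.append({"visit_id": v.visit_id, "reason": f"age {v.age} below {MIN_AGE}"})
        else:
            kept.append(v)
    return Cohort(kept), pd.DataFrame(log, columns=["visit_id", "reason"])


def patient_table(cohort: Cohort) -> pd.DataFrame:
    """One row per patient: sex, age at first visit (by date), visit count."""
    rows = []
    for pid in cohort.patient_ids:
        vs = sorted(cohort.patient_visits(pid), key=lambda v: (v.date, v.visit_id))
        rows.append(
            {
                "patient_id": pid,
                "sex": vs[0].sex,
                "age": vs[0].age,
                "n_visits": len(vs),
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def cohort_summary(cohort: Cohort) -> pd.Series:
    """Descriptive summary mirroring a standard cohort-characteristics table.

    Patient age is taken at the first visit; quantiles use linear
    interpolation.
    """
    if len(cohort) == 0:
        raise CohortError("empty cohort")
    pt = patient_table(cohort)
    ages = pt["age"].to_numpy(float)
    nv = pt["n_visits"].to_numpy(float)
    return pd.Series(
        {
            "n_patients": len(pt),
            "n_visits": len(cohort),
            "pct_female": 100.0 * (pt["sex"] == "F").mean(),
            "pct_male": 100.0 * (pt["sex"] == "M").mean(),
            "age_mean": ages.mean(),
            "age_sd": ages.std(ddof=1) if len(ages) > 1 else 0.0,
            "age_median": float(np.median(ages)),
            "age_q25": float(np.quantile(ages, 0.25)),
            "age_q75": float(np.quantile(ages, 0.75)),
            "visits_per_patient_median": float(np.median(nv)),
            "visits_per_patient_min": float(nv.min()),
            "visits_per_patient_max": float(nv.max()),
            "pct_patients_one_visit": 100.0 * (nv == 1).mean(),
            "pct_patients_multi_visit": 100.0 * (nv >= 2).mean(),
        }
    )
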