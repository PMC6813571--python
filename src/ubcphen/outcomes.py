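"""Death and age outcome variables."""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = ["AGE_CUTOFFS", "derive_death", "dichotomize_age", "derive_outcomes"]

AGE_CUTOFFS = (50, 55, 60, 65, 70)


def _is_ubc_cause(cause: str) -> bool:
    code = str(cause).replace(".", "").strip().upper()
    # bladder-site codes: C67* under ICD10, 188* under ICD9
    return code.startswith("C67") or code.startswith("188")


def derive_death(deaths: pd.DataFrame, patient_ids: Iterable) -> pd.DataFrame:
    """Per-patient (dead, ubc_death) flags.

    ``dead`` iff a death record exists; ``ubc_death`` iff its primary cause is
    a bladder-site code. An unparseable cause yields dead=True,
    ubc_death=False with a warning.
    """
    ids = list(patient_ids)
    by_patient = {}
    for _, row in deaths.iterrows():
        pid = row["patient_id"]
        if pid in by_patient:
            raise ValueError(f"duplicate death record for patient {pid!r}")
        cause = row["primary_cause_icd"]
        if pd.isna(cause) or not str(cause).strip():
            warnings.warn(f"patient {pid!r}: unparseable cause of death; counted as non-specific")
            by_patient[pid] = (True, False)
        else:
            by_patient[pid] = (True, _is_ubc_cause(cause))
    rows = [
        {"patient_id": pid, "dead": by_patient.get(pid, (False, False))[0],
         "ubc_death": by_patient.get(pid, (False, False))[1]}
        for pid in ids
    ]
    return pd.DataFrame(rows, columns=["patient_id", "dead", "ubc_death"])


def dichotomize_age(age: float, cutoff: int, allowed: Sequence[int] = AGE_CUTOFFS) -> bool:
    """Case definition for a dichotomised age outcome: age >= cutoff.

    Cutoffs outside ``allowed`` raise unless the caller passes a wider list.
    """
    if cutoff not in allowed:
        raise ValueError(f"unsupported age cutoff {cutoff}; allowed: {sorted(allowed)}")
    return age >= cutoff


def derive_outcomes(
    samples: pd.DataFrame,
    index_dates: pd.Series,
    deaths: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Outcome table: death flags, age at diagnosis, dichotomised ages.

    Age is the year difference between the index diagnosis and the year of
    birth (full birth dates are not available in the sample table).
    """
    ids = list(index_dates.index)
    sam = samples.set_index("patient_id")
    years = pd.to_datetime(index_dates).dt.year
    out = pd.DataFrame({"patient_id": ids})
    out["age_at_diagnosis"] = [
        float(years[pid] - int(sam.at[pid, "year_of_birth"])) for pid in ids
    ]
    if (out["age_at_diagnosis"] <= 0).any():
        raise ValueError("non-positive age at diagnosis")
    for cutoff in AGE_CUTOFFS:
        out[f"age_ge_{cutoff}"] = out["age_at_diagnosis"] >= cutoff
    death_df = derive_death(deaths if deaths is not None else pd.DataFrame(columns=["patient_id", "death_date", "primary_cause_icd"]), ids)
    out = out.merge(death_df, on="patient_id")
    return out
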