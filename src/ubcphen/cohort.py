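"""Eligibility selection for the bladder-cancer cohort.

A patient is eligible when, among their registry records, at least one
diagnosis code matches the tumour-site list for its ICD version and at least
one record carries an accepted histology code (same patient, any record),
and — when required — the precomputed White-British ancestry flag is set.
The earliest matching diagnosis is the index diagnosis, the anchor for every
downstream time window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Tuple

import pandas as pd

__all__ = ["EligibilityRules", "select_cohort"]

_DEFAULT_ICD10 = frozenset(
    {"C670", "C671", "C672", "C673", "C674", "C675", "C676", "C677", "C678", "C679", "D090"}
)
_DEFAULT_ICD9 = frozenset({"1880", "1882", "1884", "1886", "1888", "1889", "2337"})
_DEFAULT_ICDO = frozenset({"8000", "8001", "8010", "8020", "8050", "8120", "8130"})


def _norm(code: str) -> str:
    return str(code).replace(".", "").strip().upper()


@dataclass(frozen=True)
class EligibilityRules:
    """Code lists defining cohort membership (dot-insensitive matching)."""

    icd10_codes: frozenset = _DEFAULT_ICD10
    icd9_codes: frozenset = _DEFAULT_ICD9
    icdo_codes: frozenset = _DEFAULT_ICDO
    require_white_british: bool = True

    def __post_init__(self) -> None:
        for name in ("icd10_codes", "icd9_codes", "icdo_codes"):
            codes = frozenset(_norm(c) for c in getattr(self, name))
            if not codes:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, codes)

    def diagnosis_matches(self, icd_version: int, icd_code: str) -> bool:
        code = _norm(icd_code)
        if icd_version == 10:
            # bare C67 in a registry export is taken as unspecified-site C67.9
            return code in self.icd10_codes or (code == "C67" and any(c.startswith("C67") for c in self.icd10_codes))
        if icd_version == 9:
            return code in self.icd9_codes
        raise ValueError(f"unsupported ICD version {icd_version!r}")

    def histology_matches(self, icdo_histology: str) -> bool:
        return _norm(icdo_histology) in self.icdo_codes


def select_cohort(
    diagnoses: pd.DataFrame,
    samples: Optional[pd.DataFrame] = None,
    rules: EligibilityRules = EligibilityRules(),
) -> Tuple[set, pd.Series]:
    """Eligible patients and their index diagnosis dates.

    Parameters
    ----------
    diagnoses
        Validated registry records (patient_id, diag_date, icd_version,
        icd_code, icdo_histology).
    samples
        Sample table carrying ``white_british_flag``; required when the rules
        demand the ancestry restriction. Patients without genotype data are
        *not* filtered here.

    Returns
    -------
    (eligible patient ids, Series of index dates indexed by patient id)
    """
    if diagnoses.empty:
        return set(), pd.Series(dtype="datetime64[ns]", name="index_date")

    df = diagnoses.copy()
    df["code_ok"] = [
        rules.diagnosis_matches(int(v), c)
        for v, c in zip(df["icd_version"], df["icd_code"])
    ]
    df["hist_ok"] = [rules.histology_matches(h) for h in df["icdo_histology"]]

    per_patient = df.groupby("patient_id").agg(
        any_code=("code_ok", "any"), any_hist=("hist_ok", "any")
    )
    eligible = set(per_patient.index[per_patient["any_code"] & per_patient["any_hist"]])

    if rules.require_white_british:
        if samples is None:
            raise ValueError("samples table required when require_white_british is set")
        flagged = set(samples.loc[samples["white_british_flag"].astype(bool), "patient_id"])
        eligible &= flagged

    matching = df[df["code_ok"] & df["patient_id"].isin(eligible)]
    index_dates = (
        pd.to_datetime(matching["diag_date"])
        .groupby(matching["patient_id"])
        .min()
        .rename("index_date")
    )
    return eligible, index_dates
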