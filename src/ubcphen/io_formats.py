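"""Readers and writers for the pipeline's file formats.

Record tables travel as comma-separated UTF-8 files with ISO-8601 dates.
Every reader is total: a file either parses completely or raises a
:class:`SchemaError` carrying row-numbered messages — rows are never
silently dropped. Genotypes are accepted either as VCF 4.2 with ``DS``
(and optionally ``GP``) FORMAT fields, or as a wide dosage CSV with an
optional variant-metadata sidecar.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ubcphen.assoc import VariantData, info_score, maf_from_counts

__all__ = [
    "SchemaError",
    "GenotypePanel",
    "RECORD_SCHEMAS",
    "OUTCOME_LABELS",
    "SUBGROUPS",
    "read_records",
    "read_catalog",
    "read_vcf",
    "write_vcf",
    "read_dosage_csv",
    "write_dosage_csv",
]

_OPCS4_RE = re.compile(r"^[A-Z][0-9]{2,3}$")

RECORD_SCHEMAS: Dict[str, List[str]] = {
    "diagnoses": ["patient_id", "diag_date", "icd_version", "icd_code", "icdo_histology"],
    "episodes": ["patient_id", "episode_date", "opcs4_code"],
    "deaths": ["patient_id", "death_date", "primary_cause_icd"],
    "samples": ["patient_id", "sex", "year_of_birth", "white_british_flag"],
}

OUTCOME_LABELS = frozenset(
    {
        "recurrence",
        "progression",
        "overall_survival",
        "ubc_specific_survival",
        "age_continuous",
        "age_cutoff_50",
        "age_cutoff_55",
        "age_cutoff_60",
        "age_cutoff_65",
        "age_cutoff_70",
    }
)

SUBGROUPS = frozenset({"UBC", "NMIBC", "MIBC"})

#: outcome family used for the per-outcome Bonferroni denominator
OUTCOME_FAMILY = {
    "recurrence": "recurrence",
    "progression": "progression",
    "overall_survival": "survival",
    "ubc_specific_survival": "survival",
    "age_continuous": "age",
    "age_cutoff_50": "age",
    "age_cutoff_55": "age",
    "age_cutoff_60": "age",
    "age_cutoff_65": "age",
    "age_cutoff_70": "age",
}


class SchemaError(ValueError):
    """Input file violates its schema; ``messages`` are row-located."""

    def __init__(self, path, messages: Sequence[str]):
        self.path = str(path)
        self.messages = list(messages)
        preview = "\n  ".join(self.messages[:20])
        more = "" if len(self.messages) <= 20 else f"\n  ... and {len(self.messages) - 20} more"
        super().__init__(f"{self.path}: {len(self.messages)} schema error(s)\n  {preview}{more}")


@dataclass
class GenotypePanel:
    """A set of variants sharing one patient ordering."""

    patient_ids: List[str]
    variants: Dict[str, VariantData]

    def __len__(self) -> int:
        return len(self.variants)

    def dosage_frame(self) -> pd.DataFrame:
        """Wide patient x variant dosage table."""
        data = {"patient_id": self.patient_ids}
        for rsid, var in self.variants.items():
            data[rsid] = var.dosages
        return pd.DataFrame(data)


def _parse_date(value, row: int, column: str, errors: List[str]):
    try:
        ts = pd.Timestamp(str(value))
        if pd.isna(ts):
            raise ValueError
        return ts.normalize()
    except Exception:
        errors.append(f"row {row}: unparseable {column} {value!r}")
        return pd.NaT


def read_records(path, record_kind: str) -> pd.DataFrame:
    """Read and validate one of the record CSVs.

    ``record_kind`` is one of ``diagnoses``, ``episodes``, ``deaths``,
    ``samples``. Dates are normalised to pandas timestamps. Row numbers in
    error messages are 1-based data rows (header excluded).
    """
    if record_kind not in RECORD_SCHEMAS:
        raise ValueError(f"unknown record kind {record_kind!r}")
    schema = RECORD_SCHEMAS[record_kind]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != schema:
        raise SchemaError(path, [f"header {list(df.columns)} != expected {schema}"])
    errors: List[str] = []

    if record_kind == "diagnoses":
        dates, versions = [], []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            dates.append(_parse_date(row.diag_date, i, "diag_date", errors))
            try:
                v = int(row.icd_version)
                if v not in (9, 10):
                    raise ValueError
                versions.append(v)
            except ValueError:
                errors.append(f"row {i}: unknown ICD version {row.icd_version!r}")
                versions.append(0)
            if not re.fullmatch(r"[0-9]{4}", str(row.icdo_histology)):
                errors.append(f"row {i}: histology {row.icdo_histology!r} is not a 4-digit code")
        if errors:
            raise SchemaError(path, errors)
        df["diag_date"] = dates
        df["icd_version"] = versions

    elif record_kind == "episodes":
        dates = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            dates.append(_parse_date(row.episode_date, i, "episode_date", errors))
            if not _OPCS4_RE.fullmatch(str(row.opcs4_code)):
                errors.append(f"row {i}: invalid OPCS4 code {row.opcs4_code!r}")
        if errors:
            raise SchemaError(path, errors)
        df["episode_date"] = dates

    elif record_kind == "deaths":
        dates = []
        seen: Dict[str, int] = {}
        for i, row in enumerate(df.itertuples(index=False), start=1):
            dates.append(_parse_date(row.death_date, i, "death_date", errors))
            if row.patient_id in seen:
                errors.append(
                    f"row {i}: duplicate death record for patient {row.patient_id!r} "
                    f"(first at row {seen[row.patient_id]})"
                )
            else:
                seen[row.patient_id] = i
        if errors:
            raise SchemaError(path, errors)
        df["death_date"] = dates

    elif record_kind == "samples":
        years, flags = [], []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            if str(row.sex) not in ("M", "F"):
                errors.append(f"row {i}: sex must be M or F, got {row.sex!r}")
            try:
                years.append(int(row.year_of_birth))
            except ValueError:
                errors.append(f"row {i}: bad year_of_birth {row.year_of_birth!r}")
                years.append(0)
            flag = str(row.white_british_flag).strip().lower()
            if flag in ("true", "1"):
                flags.append(True)
            elif flag in ("false", "0"):
                flags.append(False)
            else:
                errors.append(f"row {i}: bad white_british_flag {row.white_british_flag!r}")
                flags.append(False)
        if errors:
            raise SchemaError(path, errors)
        df["year_of_birth"] = years
        df["white_british_flag"] = flags

    return df


_CATALOG_COLUMNS = [
    "rsid",
    "allele_ref",
    "allele_eff",
    "outcome_label",
    "subgroup",
    "original_direction",
    "original_estimate",
]


def read_catalog(path) -> pd.DataFrame:
    """Read the replication catalog (one row per rsID/outcome/subgroup).

    Rejects unknown outcome labels or subgroups and duplicate
    (rsid, outcome_label, subgroup) triples.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(path, [f"missing columns {missing}"])
    errors: List[str] = []
    seen: Dict[Tuple[str, str, str], int] = {}
    estimates: List[float] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.outcome_label not in OUTCOME_LABELS:
            errors.append(f"row {i}: unknown outcome_label {row.outcome_label!r}")
        if row.subgroup not in SUBGROUPS:
            errors.append(f"row {i}: unknown subgroup {row.subgroup!r}")
        if row.original_direction not in ("+", "-"):
            errors.append(f"row {i}: original_direction must be + or -, got {row.original_direction!r}")
        key = (row.rsid, row.outcome_label, row.subgroup)
        if key in seen:
            errors.append(f"row {i}: duplicate catalog entry {key} (first at row {seen[key]})")
        else:
            seen[key] = i
        if str(row.original_estimate).strip():
            try:
                est = float(row.original_estimate)
                if est <= 0:
                    raise ValueError
                estimates.append(est)
            except ValueError:
                errors.append(f"row {i}: original_estimate must be a positive number")
                estimates.append(np.nan)
        else:
            estimates.append(np.nan)
    if errors:
        raise SchemaError(path, errors)
    df["original_estimate"] = estimates
    return df


def read_vcf(path) -> GenotypePanel:
    """Load a VCF into a :class:`GenotypePanel`.

    The ``DS`` FORMAT field is preferred; when absent, dosages are derived
    from ``GP`` as P(het) + 2 P(hom-alt).
    """
    from cyvcf2 import VCF  # deferred: compiled dependency

    vcf = VCF(str(path))
    patient_ids = list(vcf.samples)
    variants: Dict[str, VariantData] = {}
    for record in vcf:
        rsid = record.ID or f"{record.CHROM}:{record.POS}"
        # cyvcf2 raises KeyError for FORMAT ids absent from the header
        try:
            gp = record.format("GP")
        except KeyError:
            gp = None
        try:
            ds = record.format("DS")
        except KeyError:
            ds = None
        triples = None
        if gp is not None:
            triples = np.asarray(gp, dtype=float)
            # guard against float-text round-off in hand-written VCFs
            triples = np.clip(triples, 0.0, None)
            triples /= triples.sum(axis=1, keepdims=True)
        if ds is not None:
            dosages = np.asarray(ds, dtype=float).reshape(-1)
        elif triples is not None:
            dosages = triples[:, 1] + 2.0 * triples[:, 2]
        else:
            raise SchemaError(path, [f"{rsid}: neither DS nor GP FORMAT present"])
        info = info_score(triples) if triples is not None else 1.0
        variants[rsid] = VariantData(
            rsid=rsid,
            allele_ref=record.REF,
            allele_eff=record.ALT[0] if record.ALT else ".",
            dosages=dosages,
            prob_triples=triples,
            info=info,
        )
    return GenotypePanel(patient_ids=patient_ids, variants=variants)


def write_vcf(path, panel: GenotypePanel, chrom: str = "1", start_pos: int = 10_000) -> None:
    """Write a panel as a minimal plain-text VCF 4.2 with GT:DS:GP fields."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect allele dosage">',
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.patient_ids),
    ]
    pos = start_pos
    for rsid, var in panel.variants.items():
        triples = var.prob_triples
        if triples is None:
            g = np.rint(var.dosages).astype(int)
            triples = np.zeros((g.size, 3))
            triples[np.arange(g.size), np.clip(g, 0, 2)] = 1.0
        cells = []
        for d, (paa, pab, pbb) in zip(var.dosages, triples):
            hard = int(np.argmax([paa, pab, pbb]))
            gt = ["0/0", "0/1", "1/1"][hard]
            cells.append(f"{gt}:{d:.10g}:{paa:.10g},{pab:.10g},{pbb:.10g}")
        lines.append(
            f"{chrom}\t{pos}\t{rsid}\t{var.allele_ref}\t{var.allele_eff}\t.\tPASS\t.\tGT:DS:GP\t"
            + "\t".join(cells)
        )
        pos += 1000
    Path(path).write_text("\n".join(lines) + "\n")


def write_dosage_csv(path, panel: GenotypePanel, variants_path=None) -> None:
    """Write the flat wide dosage table (patient_id + one column per rsID).

    ``variants_path``, when given, receives the allele/INFO/MAF sidecar.
    """
    panel.dosage_frame().to_csv(path, index=False)
    if variants_path is not None:
        meta = pd.DataFrame(
            [
                {
                    "rsid": v.rsid,
                    "allele_ref": v.allele_ref,
                    "allele_eff": v.allele_eff,
                    "info": v.info,
                    "maf": v.maf,
                }
                for v in panel.variants.values()
            ]
        )
        meta.to_csv(variants_path, index=False)


def read_dosage_csv(path, variants_path=None) -> GenotypePanel:
    """Read a wide dosage table written by :func:`write_dosage_csv`."""
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise SchemaError(path, ["missing patient_id column"])
    patient_ids = df["patient_id"].astype(str).tolist()
    meta = None
    if variants_path is not None:
        meta = pd.read_csv(variants_path, dtype={"rsid": str}).set_index("rsid")
    variants: Dict[str, VariantData] = {}
    errors: List[str] = []
    for rsid in [c for c in df.columns if c != "patient_id"]:
        dosages = pd.to_numeric(df[rsid], errors="coerce").to_numpy(dtype=float)
        valid = ~np.isnan(dosages)
        if valid.any() and ((dosages[valid] < 0) | (dosages[valid] > 2)).any():
            errors.append(f"{rsid}: dosages outside [0, 2]")
            continue
        ref, eff, info = "N", "N", 1.0
        if meta is not None and rsid in meta.index:
            ref = str(meta.at[rsid, "allele_ref"])
            eff = str(meta.at[rsid, "allele_eff"])
            info = float(meta.at[rsid, "info"])
        variants[rsid] = VariantData(
            rsid=rsid, allele_ref=ref, allele_eff=eff, dosages=dosages, info=info
        )
    if errors:
        raise SchemaError(path, errors)
    return GenotypePanel(patient_ids=patient_ids, variants=variants)
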