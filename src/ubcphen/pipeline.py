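"""End-to-end replication runs and report tables.

``run_replication`` chains cohort selection, phenotyping and outcome
derivation, then tests every catalog entry in the subgroup it was originally
reported for, annotating nominal and per-outcome-family Bonferroni
significance and direction consistency against the original report.
``descriptive_table`` emits the cohort-characteristics summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ubcphen import assoc
from ubcphen.assoc import AssocConfig
from ubcphen.cohort import EligibilityRules, select_cohort
from ubcphen.io_formats import OUTCOME_FAMILY, GenotypePanel
from ubcphen.outcomes import derive_outcomes
from ubcphen.phenotyping import CodeMap, WindowConfig, derive_phenotypes
from ubcphen._util import percent, round_half_up

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReplicationReport", "run_replication", "descriptive_table"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of a replication run."""

    windows: WindowConfig = WindowConfig()
    code_map: CodeMap = CodeMap()
    rules: EligibilityRules = EligibilityRules()
    assoc: AssocConfig = AssocConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Build a config from a YAML file of per-block overrides.

        Recognised blocks: ``windows``, ``code_map``, ``eligibility``,
        ``assoc``; each maps field names to values (code lists become sets).
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        windows = WindowConfig(**raw.get("windows", {}))
        cm_raw = {k: frozenset(v) for k, v in raw.get("code_map", {}).items()}
        code_map = CodeMap(**cm_raw)
        el_raw = dict(raw.get("eligibility", {}))
        for key in ("icd10_codes", "icd9_codes", "icdo_codes"):
            if key in el_raw:
                el_raw[key] = frozenset(str(c) for c in el_raw[key])
        rules = EligibilityRules(**el_raw)
        assoc_cfg = AssocConfig(**raw.get("assoc", {}))
        return cls(windows=windows, code_map=code_map, rules=rules, assoc=assoc_cfg)


@dataclass
class ReplicationReport:
    """Result bundle of one replication run."""

    rows: pd.DataFrame
    descriptive: pd.DataFrame
    phenotypes: pd.DataFrame
    family_thresholds: Dict[str, float]


def _harmonised_sign(beta: float, cat_ref: str, cat_eff: str, var_ref: str, var_eff: str):
    """(harmonised beta, strand_ambiguous flag) for direction comparison.

    The fitted beta is on the genotype file's effect allele. If the catalog's
    effect allele is the file's reference allele the sign flips; alleles are
    also matched through strand complement. A/T and C/G pairs cannot be
    disambiguated and are flagged instead of auto-flipped.
    """
    pair = {var_ref.upper(), var_eff.upper()}
    if pair in ({"A", "T"}, {"C", "G"}):
        return None, True
    cr, ce = cat_ref.upper(), cat_eff.upper()
    vr, ve = var_ref.upper(), var_eff.upper()
    if (cr, ce) == (vr, ve):
        return beta, False
    if (cr, ce) == (ve, vr):
        return -beta, False
    crc, cec = _COMPLEMENT.get(cr), _COMPLEMENT.get(ce)
    if (crc, cec) == (vr, ve):
        return beta, False
    if (crc, cec) == (ve, vr):
        return -beta, False
    return None, False  # alleles irreconcilable


def _outcome_vector(label: str, table: pd.DataFrame) -> Tuple[np.ndarray, bool]:
    """(outcome values, is_binary) for one catalog outcome label."""
    if label == "recurrence":
        return table["recurrence_flag"].to_numpy(dtype=float), True
    if label == "progression":
        return table["progression_flag"].to_numpy(dtype=float), True
    if label == "overall_survival":
        return table["dead"].to_numpy(dtype=float), True
    if label == "ubc_specific_survival":
        return table["ubc_death"].to_numpy(dtype=float), True
    if label == "age_continuous":
        return table["age_at_diagnosis"].to_numpy(dtype=float), False
    if label.startswith("age_cutoff_"):
        return table[f"age_ge_{label.rsplit('_', 1)[1]}"].to_numpy(dtype=float), True
    raise ValueError(f"unknown outcome label {label!r}")


def run_replication(
    diagnoses: pd.DataFrame,
    episodes: pd.DataFrame,
    deaths: pd.DataFrame,
    samples: pd.DataFrame,
    genotypes: GenotypePanel,
    catalog: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> ReplicationReport:
    """Run the full pipeline and produce the replication report.

    Per catalog entry the analysis sample is the eligible cohort restricted
    to the entry's subgroup (UBC = everyone, NMIBC/MIBC by baseline
    invasiveness), with sex as covariate. Rows for variants absent from the
    genotype panel are kept with status ``missing_variant``; subgroups with
    fewer cases than ``config.assoc.min_cases`` are flagged ``low_n``.
    Rows are sorted by p within outcome family; the run is deterministic.
    """
    eligible, index_dates = select_cohort(diagnoses, samples, config.rules)
    with_genotypes = [pid for pid in genotypes.patient_ids if pid in eligible]
    index_dates = index_dates.loc[with_genotypes]

    phenotypes = derive_phenotypes(
        episodes[episodes["patient_id"].isin(with_genotypes)],
        index_dates,
        config.windows,
        config.code_map,
    )
    outcome_tbl = derive_outcomes(samples, index_dates, deaths)
    table = phenotypes.merge(outcome_tbl, on="patient_id").merge(
        samples[["patient_id", "sex"]], on="patient_id"
    )
    table = table.set_index("patient_id").loc[with_genotypes].reset_index()
    pos = {pid: i for i, pid in enumerate(genotypes.patient_ids)}
    take = np.array([pos[pid] for pid in table["patient_id"]], dtype=int)
    sex_cov = (table["sex"] == "M").to_numpy(dtype=float)

    family_sizes = catalog["outcome_label"].map(OUTCOME_FAMILY).value_counts().to_dict()
    thresholds = {
        fam: assoc.bonferroni_alpha(config.assoc.alpha, m) for fam, m in family_sizes.items()
    }

    rows = []
    for entry in catalog.itertuples(index=False):
        family = OUTCOME_FAMILY[entry.outcome_label]
        row: Dict[str, object] = {
            "rsid": entry.rsid,
            "outcome_label": entry.outcome_label,
            "subgroup": entry.subgroup,
            "family": family,
            "status": "ok",
            "bonferroni_threshold": thresholds[family],
        }
        variant = genotypes.variants.get(entry.rsid)
        if variant is None:
            row["status"] = "missing_variant"
            rows.append(row)
            continue

        if entry.subgroup == "UBC":
            mask = np.ones(len(table), dtype=bool)
        elif entry.subgroup == "NMIBC":
            mask = ~table["mibc_at_baseline"].to_numpy(dtype=bool)
        else:
            mask = table["mibc_at_baseline"].to_numpy(dtype=bool)

        y, binary = _outcome_vector(entry.outcome_label, table)
        sub = replace(
            variant,
            dosages=variant.dosages[take][mask],
            prob_triples=(
                variant.prob_triples[take][mask] if variant.prob_triples is not None else None
            ),
        )
        try:
            result = assoc.associate(
                y[mask],
                sub,
                covariates=sex_cov[mask],
                binary=binary,
                outcome_label=entry.outcome_label,
                subgroup=entry.subgroup,
                config=config.assoc,
            )
        except ValueError as exc:
            row["status"] = f"error: {exc}"
            rows.append(row)
            continue

        if binary and result.n_cases is not None and result.n_cases < config.assoc.min_cases:
            row["status"] = "low_n"

        harmonised, ambiguous = _harmonised_sign(
            result.beta, entry.allele_ref, entry.allele_eff, variant.allele_ref, variant.allele_eff
        )
        direction = None
        if not ambiguous and harmonised is not None:
            original = 1.0 if entry.original_direction == "+" else -1.0
            direction = bool(np.sign(harmonised) == original)

        row.update(
            {
                "info": variant.info,
                "n_total": result.n_total,
                "n_cases": result.n_cases,
                "n_controls": result.n_controls,
                "counts_all": "/".join(f"{c:g}" for c in result.counts_all),
                "counts_cases": (
                    "/".join(f"{c:g}" for c in result.counts_cases) if result.counts_cases else ""
                ),
                "counts_controls": (
                    "/".join(f"{c:g}" for c in result.counts_controls)
                    if result.counts_controls
                    else ""
                ),
                "maf_all_pct": round_half_up(100.0 * result.maf_all),
                "maf_cases_pct": (
                    round_half_up(100.0 * result.maf_cases) if result.maf_cases is not None else None
                ),
                "maf_controls_pct": (
                    round_half_up(100.0 * result.maf_controls)
                    if result.maf_controls is not None
                    else None
                ),
                "beta": result.beta,
                "se": result.se,
                "odds_ratio": result.odds_ratio,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
                "p": result.p,
                "log10_bf": result.log10_bf,
                "converged": result.converged,
                "nominal_significant": result.p < config.assoc.alpha,
                "bonferroni_significant": result.p < thresholds[family],
                "direction_consistent": direction,
                "strand_ambiguous": ambiguous,
            }
        )
        rows.append(row)

    report = pd.DataFrame(rows)
    if len(report):
        report = (
            report.sort_values(["family", "p"], na_position="last")
            .reset_index(drop=True)
        )
    descriptive = descriptive_table(table)
    return ReplicationReport(
        rows=report, descriptive=descriptive, phenotypes=table, family_thresholds=thresholds
    )


def descriptive_table(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort-characteristics summary (counts, percentages, chi-square).

    One row per level of each binary characteristic plus a mean (SD) age row.
    The chi-square statistic is a one-sample goodness-of-fit test of the
    observed split against equal proportions — a stated interpretation of the
    summary-table footnote, not a two-variable independence test.
    """
    n = len(table)
    rows = []

    def _binary(name: str, yes: int) -> None:
        no = n - yes
        chi2, p = (np.nan, np.nan)
        if n > 0:
            chi2, p = stats.chisquare([no, yes])
        rows.append(
            {"variable": name, "level": "No", "count": no,
             "pct": percent(no, n) if n else np.nan, "chi2": chi2, "p": p}
        )
        rows.append(
            {"variable": name, "level": "Yes", "count": yes,
             "pct": percent(yes, n) if n else np.nan, "chi2": chi2, "p": p}
        )

    males = int((table["sex"] == "M").sum())
    chi2, p = stats.chisquare([n - males, males]) if n else (np.nan, np.nan)
    rows.append({"variable": "sex", "level": "Male", "count": males,
                 "pct": percent(males, n) if n else np.nan, "chi2": chi2, "p": p})
    rows.append({"variable": "sex", "level": "Female", "count": n - males,
                 "pct": percent(n - males, n) if n else np.nan, "chi2": chi2, "p": p})

    age = table["age_at_diagnosis"]
    rows.append(
        {"variable": "age", "level": "mean (SD)",
         "count": round_half_up(float(age.mean()), 1) if n else np.nan,
         "pct": round_half_up(float(age.std(ddof=1)), 1) if n > 1 else np.nan,
         "chi2": np.nan, "p": np.nan}
    )

    _binary("death", int(table["dead"].sum()))
    _binary("ubc_specific_death", int(table["ubc_death"].sum()))
    _binary("recurrence", int(table["recurrence_flag"].sum()))
    _binary("progression", int(table["progression_flag"].sum()))
    _binary("nmibc_at_baseline", int((~table["mibc_at_baseline"]).sum()))
    return pd.DataFrame(rows, columns=["variable", "level", "count", "pct", "chi2", "p"])
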