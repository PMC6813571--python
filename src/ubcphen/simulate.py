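"""Synthetic registries, episode streams, deaths and genotypes.

The generator embeds known ground truth and emits intervention codes
*through the inverse* of the phenotyping rules, so the rule engine applied
to the synthetic episodes recovers the generated labels exactly:

* a true recurrence at day ``d`` is written either as a resection (M42) at
  ``d``, as an examination (M45) at ``d`` plus an instillation 21 days
  later, or as an intravesical-chemotherapy block starting at ``d`` whose
  gap to the previous block exceeds the gap rule;
* a true progression additionally writes cystectomy/radiotherapy within the
  follow-up window of the last recurrence event;
* a true muscle-invasive baseline writes cystectomy/radiotherapy inside the
  index window.

Event days are spaced further apart than the independence window by
construction, so deduplication never collapses two true events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ubcphen.assoc import VariantData, info_score
from ubcphen.io_formats import GenotypePanel, write_dosage_csv, write_vcf

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "VariantSpec",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_genotypes",
    "write_outputs",
]

_ICD10_CODES = ["C67.0", "C67.1", "C67.2", "C67.3", "C67.4", "C67.5", "C67.9", "D09.0"]
_ICD9_CODES = ["1880", "1882", "1884", "1886", "1888", "1889", "2337"]
_HISTOLOGIES = ["8120", "8130", "8010", "8050", "8000", "8001", "8020"]
_BAD_HISTOLOGY = "8140"  # adenocarcinoma: outside the accepted list
_NOISE_CODES = ["E851", "W401", "Z926", "H223"]  # never map to a category
_NONUBC_CAUSES = ["I21.9", "J44.9", "C34.9"]


class ConfigurationError(ValueError):
    """Invalid simulation settings."""


@dataclass(frozen=True)
class VariantSpec:
    """One simulated variant: frequency, per-allele odds ratio, target outcome.

    ``outcome_label`` names the ground-truth label the effect acts on
    (``recurrence``, ``progression``, ``mibc``, ``overall_survival``,
    ``ubc_specific_survival``, an ``age_cutoff_*`` label, or ``null`` for no
    association).
    """

    rsid: str
    allele_ref: str = "A"
    allele_eff: str = "G"
    maf: float = 0.3
    odds_ratio: float = 1.0
    outcome_label: str = "recurrence"

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ConfigurationError(f"{self.rsid}: maf must be in (0, 0.5]")
        if self.odds_ratio <= 0:
            raise ConfigurationError(f"{self.rsid}: odds_ratio must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings (all rates are fractions)."""

    n_patients: int = 1534
    prop_male: float = 0.78
    age_mean: float = 61.0
    age_sd: float = 9.0
    recurrence_rate: float = 0.40
    progression_rate: float = 0.038
    mibc_rate: float = 0.074
    death_rate: float = 0.136
    ubc_death_rate: float = 0.069
    ineligible_rate: float = 0.0
    variants: Tuple[VariantSpec, ...] = ()
    prob_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        rates = {
            "prop_male": self.prop_male,
            "recurrence_rate": self.recurrence_rate,
            "progression_rate": self.progression_rate,
            "mibc_rate": self.mibc_rate,
            "death_rate": self.death_rate,
            "ubc_death_rate": self.ubc_death_rate,
            "ineligible_rate": self.ineligible_rate,
            "prob_noise": self.prob_noise,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.progression_rate > self.recurrence_rate:
            raise ConfigurationError("progression_rate must not exceed recurrence_rate")
        if self.ubc_death_rate > self.death_rate:
            raise ConfigurationError("ubc_death_rate must not exceed death_rate")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be positive")


@dataclass
class SimulatedCohort:
    """Generator output bundle; ``truth`` is for tests and audits only."""

    diagnoses: pd.DataFrame
    episodes: pd.DataFrame
    deaths: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame
    genotypes: Optional[GenotypePanel] = None


def _patient_stream(
    rng: np.random.Generator,
    recurrent: bool,
    progression: bool,
    mibc: bool,
) -> Tuple[List[Tuple[int, str]], int, bool]:
    """Episode offsets (days from index) and code for one patient.

    Returns (episodes, recurrence_count, progression).
    """
    episodes: List[Tuple[int, str]] = [(int(rng.integers(0, 21)), "M42")]  # primary resection
    if mibc:
        episodes.append((int(rng.integers(20, 81)), str(rng.choice(["M34", "X65"]))))

    count = 0
    if recurrent:
        count = 1 + int(min(rng.poisson(0.6), 3))
        days = [275 + int(rng.integers(0, 366))]
        for _ in range(count - 1):
            days.append(days[-1] + 121 + int(rng.integers(0, 241)))
        mechanism = (
            str(rng.choice(["turbt", "exam"]))
            if progression
            else str(rng.choice(["turbt", "exam", "ivc"], p=[0.6, 0.25, 0.15]))
        )
        if mechanism == "turbt":
            episodes.extend((d, "M42") for d in days)
        elif mechanism == "exam":
            for k, d in enumerate(days):
                episodes.append((d, "M45"))
                final = k == count - 1
                if not (progression and final):
                    episodes.append((d + 21, str(rng.choice(["M494", "M495"]))))
        else:  # instillation blocks; first block sits in the index window
            episodes.append((10, "M494"))
            episodes.extend((d, str(rng.choice(["M494", "M495"]))) for d in days)
        if progression:
            episodes.append((days[-1] + 30 + int(rng.integers(0, 121)), str(rng.choice(["M34", "X65"]))))

    for _ in range(int(rng.integers(0, 3))):  # uncategorised clutter
        episodes.append((int(rng.integers(0, 2001)), str(rng.choice(_NOISE_CODES))))
    return episodes, count, progression


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate registry, episode, death and sample tables plus ground truth.

    Deterministic given ``config.seed``. When ``config.variants`` is
    non-empty, a genotype panel tied to the ground-truth labels is included.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"P{i:06d}" for i in range(1, n + 1)]

    diag_rows, episode_rows, death_rows, sample_rows, truth_rows = [], [], [], [], []
    epoch = np.datetime64("1997-01-01")
    span = (np.datetime64("2011-01-01") - epoch).astype(int)

    for pid in ids:
        sex = "M" if rng.random() < config.prop_male else "F"
        age = int(np.clip(np.rint(rng.normal(config.age_mean, config.age_sd)), 30, 90))
        index_date = epoch + int(rng.integers(0, span))
        eligible = rng.random() >= config.ineligible_rate

        recurrent = rng.random() < config.recurrence_rate
        progression = recurrent and rng.random() < (
            config.progression_rate / config.recurrence_rate if config.recurrence_rate > 0 else 0.0
        )
        mibc = rng.random() < config.mibc_rate
        episodes, count, progression = _patient_stream(rng, recurrent, progression, mibc)

        if rng.random() < 0.9:
            diag_rows.append(
                {
                    "patient_id": pid,
                    "diag_date": index_date,
                    "icd_version": 10,
                    "icd_code": str(rng.choice(_ICD10_CODES)),
                    "icdo_histology": str(rng.choice(_HISTOLOGIES)) if eligible else _BAD_HISTOLOGY,
                }
            )
        else:
            diag_rows.append(
                {
                    "patient_id": pid,
                    "diag_date": index_date,
                    "icd_version": 9,
                    "icd_code": str(rng.choice(_ICD9_CODES)),
                    "icdo_histology": str(rng.choice(_HISTOLOGIES)) if eligible else _BAD_HISTOLOGY,
                }
            )

        for offset, code in sorted(episodes):
            episode_rows.append(
                {"patient_id": pid, "episode_date": index_date + offset, "opcs4_code": code}
            )

        dead = rng.random() < config.death_rate
        ubc_death = dead and rng.random() < (
            config.ubc_death_rate / config.death_rate if config.death_rate > 0 else 0.0
        )
        if dead:
            last = max(offset for offset, _ in episodes)
            death_rows.append(
                {
                    "patient_id": pid,
                    "death_date": index_date + last + 200 + int(rng.integers(0, 1501)),
                    "primary_cause_icd": "C67.9" if ubc_death else str(rng.choice(_NONUBC_CAUSES)),
                }
            )

        sample_rows.append(
            {
                "patient_id": pid,
                "sex": sex,
                "year_of_birth": int(index_date.astype("datetime64[Y]").astype(int)) + 1970 - age,
                "white_british_flag": True,
            }
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "eligible": eligible,
                "recurrence_count": count,
                "recurrence_flag": count >= 1,
                "progression_flag": progression,
                "mibc_flag": mibc,
                "dead": dead,
                "ubc_death": ubc_death,
                "age": age,
                "sex": sex,
            }
        )

    truth = pd.DataFrame(truth_rows)
    sim = SimulatedCohort(
        diagnoses=pd.DataFrame(diag_rows),
        episodes=pd.DataFrame(episode_rows),
        deaths=pd.DataFrame(death_rows, columns=["patient_id", "death_date", "primary_cause_icd"]),
        samples=pd.DataFrame(sample_rows),
        truth=truth,
    )

    if config.variants:
        variants: Dict[str, VariantData] = {}
        for spec in config.variants:
            y = _truth_outcome(truth, spec.outcome_label, rng)
            variants[spec.rsid] = simulate_genotypes(
                y,
                maf=spec.maf,
                odds_ratio=spec.odds_ratio,
                rng=rng,
                prob_noise=config.prob_noise,
                rsid=spec.rsid,
                allele_ref=spec.allele_ref,
                allele_eff=spec.allele_eff,
            )
        sim.genotypes = GenotypePanel(patient_ids=ids, variants=variants)
    return sim


def _truth_outcome(truth: pd.DataFrame, label: str, rng: np.random.Generator) -> np.ndarray:
    if label == "null":
        return rng.random(len(truth)) < 0.5
    column = {
        "recurrence": "recurrence_flag",
        "progression": "progression_flag",
        "mibc": "mibc_flag",
        "overall_survival": "dead",
        "ubc_specific_survival": "ubc_death",
    }.get(label)
    if column is not None:
        return truth[column].to_numpy(dtype=bool)
    if label.startswith("age_cutoff_"):
        return truth["age"].to_numpy() >= int(label.rsplit("_", 1)[1])
    if label == "age_continuous":  # tilt on the older half
        return truth["age"].to_numpy() >= float(np.median(truth["age"]))
    raise ConfigurationError(f"unknown simulated outcome label {label!r}")


def simulate_genotypes(
    outcome: np.ndarray,
    maf: float,
    odds_ratio: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    prob_noise: float = 0.0,
    rsid: str = "rs0",
    allele_ref: str = "A",
    allele_eff: str = "G",
) -> VariantData:
    """Draw genotypes under a per-allele odds ratio by retrospective tilting.

    Controls carry effect-allele frequency ``maf``; cases carry
    expit(logit(maf) + log(odds_ratio)), with Hardy-Weinberg genotypes within
    each group. Probability triples are one-hot at ``prob_noise == 0`` and
    otherwise drawn from a Dirichlet concentrated on the true genotype;
    dosage is the expected allele count of the triple.
    """
    if not 0.0 < maf <= 0.5:
        raise ConfigurationError("maf must be in (0, 0.5]")
    if odds_ratio <= 0:
        raise ConfigurationError("odds_ratio must be positive")
    if not 0.0 <= prob_noise <= 1.0:
        raise ConfigurationError("prob_noise must be in [0, 1]")
    if rng is None:
        # keyed sub-stream: callers often build the outcome vector from the
        # same integer seed, and sharing the raw stream would couple the
        # binomial inversion draws to the outcome
        rng = np.random.default_rng(seed if seed is None else [seed, 0x67C6])
    y = np.asarray(outcome, dtype=bool)
    n = y.size
    p_case = float(expit(logit(maf) + np.log(odds_ratio)))
    freq = np.where(y, p_case, maf)
    g = rng.binomial(2, freq)

    if prob_noise == 0.0:
        triples = np.zeros((n, 3))
        triples[np.arange(n), g] = 1.0
    else:
        # Dirichlet with per-row concentration on the true genotype,
        # vectorised through independent gamma draws
        conc = 2.0 * (1.0 - prob_noise) / prob_noise
        alpha = np.ones((n, 3))
        alpha[np.arange(n), g] += conc
        gamma = rng.gamma(alpha)
        triples = gamma / gamma.sum(axis=1, keepdims=True)

    dosages = triples[:, 1] + 2.0 * triples[:, 2]
    return VariantData(
        rsid=rsid,
        allele_ref=allele_ref,
        allele_eff=allele_eff,
        dosages=dosages,
        prob_triples=triples,
        info=info_score(triples),
    )


def write_outputs(sim: SimulatedCohort, outdir, include_truth: bool = True) -> Dict[str, str]:
    """Write the bundle as CSVs (plus VCF + dosage CSV when genotypes exist).

    Returns the mapping of logical names to file paths. Dates are ISO-8601.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}

    def _write(df: pd.DataFrame, name: str, date_cols: Sequence[str] = ()) -> None:
        frame = df.copy()
        for col in date_cols:
            frame[col] = pd.to_datetime(frame[col]).dt.strftime("%Y-%m-%d")
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = str(path)

    _write(sim.diagnoses, "diagnoses", ["diag_date"])
    _write(sim.episodes, "episodes", ["episode_date"])
    _write(sim.deaths, "deaths", ["death_date"])
    _write(sim.samples, "samples")
    if include_truth:
        _write(sim.truth, "ground_truth")
    if sim.genotypes is not None:
        vcf_path = out / "genotypes.vcf"
        write_vcf(vcf_path, sim.genotypes)
        paths["genotypes_vcf"] = str(vcf_path)
        write_dosage_csv(out / "dosages.csv", sim.genotypes, out / "variants.csv")
        paths["dosages"] = str(out / "dosages.csv")
        paths["variants"] = str(out / "variants.csv")
    return paths
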