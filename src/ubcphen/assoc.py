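"""Association statistics for dosage-coded variants.

Self-contained statistics core: logistic and linear allele-dosage
regressions (additive coding, optional covariates), Wald intervals,
an approximate Bayes factor with a Normal prior on the log-odds effect,
imputation INFO scores, allele frequencies from (possibly fractional)
genotype-count triples, dosage LD r-squared, and per-family Bonferroni
thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "AssocConfig",
    "AssociationResult",
    "FitWarning",
    "RegressionFit",
    "VariantData",
    "associate",
    "bonferroni_alpha",
    "fit_linear_dosage",
    "fit_logistic_dosage",
    "genotype_count_triples",
    "info_score",
    "ld_r2",
    "log10_abf",
    "maf_from_counts",
]


class FitWarning(UserWarning):
    """Raised as a warning when a model fit is suspect (separation etc.)."""


@dataclass(frozen=True)
class AssocConfig:
    """Constants of the statistical analysis.

    ``abf_prior_sd`` is the standard deviation W of the Normal(0, W^2)
    prior on the log-odds effect used by the approximate Bayes factor.
    """

    ci_level: float = 0.95
    abf_prior_sd: float = 0.2
    irls_tol: float = 1e-8
    irls_max_iter: int = 25
    alpha: float = 0.05
    min_cases: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.abf_prior_sd <= 0:
            raise ValueError("abf_prior_sd must be positive")


@dataclass
class VariantData:
    """One variant's per-patient genotypes on the effect-allele dosage scale.

    ``dosages`` lie in [0, 2]; ``prob_triples`` (n x 3, ordered
    hom-ref/het/hom-alt) are optional and, when present, must be consistent
    with the dosages. ``np.nan`` dosage marks a missing genotype.
    """

    rsid: str
    allele_ref: str
    allele_eff: str
    dosages: np.ndarray
    prob_triples: Optional[np.ndarray] = None
    info: float = field(default=1.0)
    maf: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        valid = ~np.isnan(self.dosages)
        if valid.any() and ((self.dosages[valid] < -1e-9) | (self.dosages[valid] > 2 + 1e-9)).any():
            raise ValueError(f"{self.rsid}: dosages outside [0, 2]")
        if self.prob_triples is not None:
            self.prob_triples = np.asarray(self.prob_triples, dtype=float)
            if self.prob_triples.shape != (self.dosages.size, 3):
                raise ValueError(f"{self.rsid}: prob_triples shape mismatch")
            implied = self.prob_triples[:, 1] + 2.0 * self.prob_triples[:, 2]
            if valid.any() and np.nanmax(np.abs(implied[valid] - self.dosages[valid])) > 1e-6:
                raise ValueError(f"{self.rsid}: dosages inconsistent with probability triples")
        if np.isnan(self.maf):
            p = np.nanmean(self.dosages) / 2.0 if valid.any() else np.nan
            self.maf = float(min(p, 1.0 - p)) if not np.isnan(p) else np.nan


@dataclass
class RegressionFit:
    """Per-fit summary for the dosage term."""

    beta: float
    se: float
    z: float
    p: float
    converged: bool
    params: np.ndarray
    cov: np.ndarray


@dataclass
class AssociationResult:
    """One tested catalog entry: estimate, uncertainty and descriptives."""

    rsid: str
    outcome_label: str
    subgroup: str
    n_total: float
    n_cases: Optional[float]
    n_controls: Optional[float]
    counts_all: tuple
    counts_cases: Optional[tuple]
    counts_controls: Optional[tuple]
    maf_all: float
    maf_cases: Optional[float]
    maf_controls: Optional[float]
    beta: float
    se: float
    z: float
    p: float
    odds_ratio: Optional[float]
    ci_low: float
    ci_high: float
    log10_bf: float
    converged: bool


def maf_from_counts(n_aa: float, n_ab: float, n_bb: float) -> float:
    """Minor-allele frequency from a (hom-ref, het, hom-alt) count triple.

    Counts may be fractional (sums of posterior genotype probabilities).
    """
    for v in (n_aa, n_ab, n_bb):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("cannot compute allele frequency from zero individuals")
    p = (2.0 * n_bb + n_ab) / (2.0 * n)
    return float(min(p, 1.0 - p))


def genotype_count_triples(
    case_mask: np.ndarray,
    prob_triples: Optional[np.ndarray] = None,
    dosages: Optional[np.ndarray] = None,
) -> tuple:
    """(all, cases, controls) genotype-count triples.

    With probability triples each cell is the per-group sum of posterior
    probabilities (fractional counts); with hard dosages genotypes are the
    rounded allele counts and the cells are integers.
    """
    if prob_triples is None and dosages is None:
        raise ValueError("one of prob_triples or dosages is required")
    case_mask = np.asarray(case_mask, dtype=bool)
    if prob_triples is not None:
        t = np.asarray(prob_triples, dtype=float)
    else:
        d = np.asarray(dosages, dtype=float)
        g = np.rint(d).astype(int)
        t = np.zeros((g.size, 3))
        t[np.arange(g.size), np.clip(g, 0, 2)] = 1.0
    total = tuple(t.sum(axis=0))
    cases = tuple(t[case_mask].sum(axis=0))
    controls = tuple(t[~case_mask].sum(axis=0))
    return total, cases, controls


def _design(g: np.ndarray, covariates: Optional[np.ndarray]) -> np.ndarray:
    cols = [np.ones_like(g), g]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    return np.column_stack(cols)


def fit_logistic_dosage(
    y: np.ndarray,
    g: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    config: AssocConfig = AssocConfig(),
) -> RegressionFit:
    """Maximum-likelihood logistic regression of a binary outcome on dosage.

    Fits logit P(y=1) = a + b*g (+ covariates) by iteratively reweighted
    least squares. Wald standard errors come from the inverse observed
    information. Non-convergence or quasi-separation is flagged via
    ``converged=False`` with a warning; estimates are still returned.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one case and one control")
    if np.ptp(g) == 0:
        raise ValueError("dosage vector is constant")
    x = _design(g, covariates)
    n, k = x.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(config.irls_max_iter):
        eta = x @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        xtw = x.T * w
        try:
            step = np.linalg.solve(xtw @ x, x.T @ (y - mu))
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix in logistic fit") from exc
        beta = beta + step
        if np.max(np.abs(step)) < config.irls_tol:
            converged = True
            break
    eta = x @ beta
    mu = special.expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.inv((x.T * w) @ x)
    if np.abs(beta).max() > 15.0:  # quasi-separation: drifting estimates
        converged = False
    if not converged:
        warnings.warn(
            "logistic fit did not converge cleanly (possible separation); "
            "estimates reported as-is",
            FitWarning,
            stacklevel=2,
        )
    se = float(np.sqrt(cov[1, 1]))
    b = float(beta[1])
    z = b / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return RegressionFit(beta=b, se=se, z=z, p=max(p, np.finfo(float).tiny), converged=converged, params=beta, cov=cov)


def fit_linear_dosage(
    y: np.ndarray,
    g: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> RegressionFit:
    """Ordinary least squares of a continuous outcome on dosage; t-based p."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    x = _design(g, covariates)
    n, k = x.shape
    if n <= k:
        raise ValueError("more parameters than observations")
    if np.linalg.matrix_rank(x) < k:
        raise ValueError("rank-deficient design (constant dosage or collinear covariates)")
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = float(np.sqrt(cov[1, 1]))
    b = float(beta[1])
    t = b / se if se > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return RegressionFit(
        beta=b, se=se, z=t, p=max(p, np.finfo(float).tiny), converged=True, params=beta, cov=cov
    )


def log10_abf(beta: float, se: float, prior_sd: float = 0.2) -> float:
    """log10 approximate Bayes factor, alternative vs null.

    The effect has a Normal(0, W^2) prior and the estimate a Normal(beta, se^2)
    likelihood, giving the closed form
    BF = sqrt(se^2/(se^2+W^2)) * exp(z^2 W^2 / (2 (se^2+W^2))).
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior sd must be positive")
    z2 = (beta / se) ** 2
    shrink = se**2 / (se**2 + prior_sd**2)
    log_bf = 0.5 * np.log(shrink) + z2 * prior_sd**2 / (2.0 * (se**2 + prior_sd**2))
    return float(log_bf / np.log(10.0))


def info_score(prob_triples: np.ndarray) -> float:
    """Imputation certainty in [0, 1] from per-patient genotype probabilities.

    1 for fully degenerate (hard-called) triples; 0 when every triple is the
    population Hardy-Weinberg expectation (no per-individual information).
    The ratio form can dip below zero for super-dispersed triples (more
    per-individual variance than the pooled binomial); it is clamped at 0.
    """
    t = np.asarray(prob_triples, dtype=float)
    if t.ndim != 2 or t.shape[1] != 3:
        raise ValueError("prob_triples must be an (n, 3) array")
    if (t < -1e-9).any() or np.abs(t.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("rows must be probability triples summing to 1")
    e = t[:, 1] + 2.0 * t[:, 2]
    f = t[:, 1] + 4.0 * t[:, 2]
    n = t.shape[0]
    theta = e.sum() / (2.0 * n)
    if theta <= 0.0 or theta >= 1.0:
        return 1.0
    raw = 1.0 - (f - e**2).sum() / (2.0 * n * theta * (1.0 - theta))
    return float(max(0.0, raw))


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors on the same patients."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must cover the same patients")
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        raise ValueError("LD undefined for a monomorphic dosage vector")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise alpha divided by the number of tests in the family."""
    if m < 1:
        raise ValueError("family size must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def associate(
    y: np.ndarray,
    variant: VariantData,
    covariates: Optional[np.ndarray] = None,
    binary: bool = True,
    outcome_label: str = "",
    subgroup: str = "UBC",
    config: AssocConfig = AssocConfig(),
) -> AssociationResult:
    """Fit one variant against one outcome and package the result row.

    Patients with missing dosage are excluded from this variant's test only.
    For binary outcomes the per-group genotype-count triples and allele
    frequencies mirror the replication-report columns; for continuous
    outcomes only the overall descriptives are defined.
    """
    y = np.asarray(y, dtype=float)
    d = variant.dosages
    keep = ~np.isnan(d) & ~np.isnan(y)
    y_k, d_k = y[keep], d[keep]
    cov_k = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        cov_k = cov[keep] if cov.ndim == 1 else cov[keep, :]
    triples = variant.prob_triples[keep] if variant.prob_triples is not None else None

    if binary:
        case_mask = y_k == 1.0
        all_t, case_t, ctrl_t = genotype_count_triples(case_mask, triples, d_k)
        fit = fit_logistic_dosage(y_k, d_k, cov_k, config)
        n_cases = float(sum(case_t))
        n_controls = float(sum(ctrl_t))
        maf_cases = maf_from_counts(*case_t)
        maf_controls = maf_from_counts(*ctrl_t)
        odds_ratio = float(np.exp(fit.beta))
        zq = stats.norm.ppf(0.5 + config.ci_level / 2.0)
        ci_low = float(np.exp(fit.beta - zq * fit.se))
        ci_high = float(np.exp(fit.beta + zq * fit.se))
    else:
        all_t, _, _ = genotype_count_triples(np.zeros(y_k.size, dtype=bool), triples, d_k)
        fit = fit_linear_dosage(y_k, d_k, cov_k)
        n_cases = n_controls = None
        case_t = ctrl_t = None
        maf_cases = maf_controls = None
        odds_ratio = None
        zq = stats.norm.ppf(0.5 + config.ci_level / 2.0)
        ci_low = float(fit.beta - zq * fit.se)
        ci_high = float(fit.beta + zq * fit.se)

    return AssociationResult(
        rsid=variant.rsid,
        outcome_label=outcome_label,
        subgroup=subgroup,
        n_total=float(sum(all_t)),
        n_cases=n_cases,
        n_controls=n_controls,
        counts_all=all_t,
        counts_cases=case_t,
        counts_controls=ctrl_t,
        maf_all=maf_from_counts(*all_t),
        maf_cases=maf_cases,
        maf_controls=maf_controls,
        beta=fit.beta,
        se=fit.se,
        z=fit.z,
        p=fit.p,
        odds_ratio=odds_ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        log10_bf=log10_abf(fit.beta, fit.se, config.abf_prior_sd),
        converged=fit.converged,
    )
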