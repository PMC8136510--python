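"""Sex-specificity (SPM) and expression-level regressions on maternal bias.

SPM maps a gene's male and female expression to [0,1], with 0 meaning
100% of expression in males, 0.5 unbiased, and 1 meaning 100% in females.
The default form is the squared-proportion specificity metric

    SPM = f^2 / (m^2 + f^2)

with the simple proportion f/(m+f) available by flag; both satisfy the
stated endpoints.

Two regressions relate expression to the maternal fraction p_m:

* an ordinary least squares fit of log(TPM) on p_m and p_m^2;
* a quasibinomial GLM (logit link, variance phi*mu*(1-mu)) of SPM on
  p_m and p_m^2, with sequential (type-I) F tests per term scaled by the
  Pearson-estimated dispersion, as in a conventional analysis of deviance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ModelFit:
    """Coefficients and test statistics of one fitted model."""

    coefficients: dict[str, float]
    r2_adjusted: float | None = None
    f_statistics: dict[str, tuple[float, int, int, float]] = field(default_factory=dict)
    dispersion: float | None = None
    fitted: np.ndarray | None = None


def compute_spm(male_tpm: float, female_tpm: float, method: str = "squared") -> float:
    """Specificity of expression toward females, in [0,1].

    ``squared`` (default): f^2/(m^2+f^2); ``proportion``: f/(m+f).
    Both inputs zero is undefined (the caller should exclude the gene).
    """
    if male_tpm < 0 or female_tpm < 0:
        raise ValueError("TPM values must be non-negative")
    if male_tpm == 0 and female_tpm == 0:
        raise ValueError("SPM undefined when both sexes have zero expression")
    if female_tpm == 0:
        return 0.0
    if male_tpm == 0:
        return 1.0
    # rescale by the larger value so squaring cannot under/overflow
    scale = max(male_tpm, female_tpm)
    m, f = male_tpm / scale, female_tpm / scale
    if method == "squared":
        return f**2 / (m**2 + f**2)
    if method == "proportion":
        return f / (m + f)
    raise ValueError(f"unknown SPM method {method!r}")


def spm_table(
    male_tpm: Mapping[str, float],
    female_tpm: Mapping[str, float],
    method: str = "squared",
) -> dict[str, float]:
    """Per-gene SPM over genes present in both tables; all-zero genes are
    excluded with a log entry."""
    out: dict[str, float] = {}
    skipped = 0
    for gene in sorted(set(male_tpm) & set(female_tpm)):
        m, f = male_tpm[gene], female_tpm[gene]
        if m == 0 and f == 0:
            skipped += 1
            continue
        out[gene] = compute_spm(m, f, method=method)
    if skipped:
        logger.info("spm_table: %d genes with zero expression in both sexes excluded", skipped)
    return out


def _design(p_m: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(p_m), p_m, p_m**2])


def fit_log_tpm_model(
    tpm: Sequence[float], p_m: Sequence[float]
) -> ModelFit:
    """OLS of log(TPM) on p_m and p_m^2 (natural logarithm).

    Genes with TPM = 0 are excluded before fitting. An all-equal p_m vector
    makes the design collinear and is a hard error.
    """
    tpm = np.asarray(tpm, dtype=float)
    p_m = np.asarray(p_m, dtype=float)
    keep = tpm > 0
    if keep.sum() < len(tpm):
        logger.info("fit_log_tpm_model: %d genes with TPM=0 excluded", int((~keep).sum()))
    tpm, p_m = tpm[keep], p_m[keep]
    if len(tpm) < 4:
        raise ValueError("need at least 4 genes with positive TPM")
    if np.ptp(p_m) == 0:
        raise ValueError("p_m is constant: quadratic design is collinear")
    X = _design(p_m)
    res = sm.OLS(np.log(tpm), X).fit()
    f_overall = (
        float(res.fvalue), int(res.df_model), int(res.df_resid), float(res.f_pvalue)
    )
    return ModelFit(
        coefficients={
            "intercept": float(res.params[0]),
            "p_m": float(res.params[1]),
            "p_m2": float(res.params[2]),
        },
        r2_adjusted=float(res.rsquared_adj),
        f_statistics={"overall": f_overall},
        fitted=np.asarray(res.fittedvalues),
    )


def fit_spm_glm(
    spm: Sequence[float],
    p_m: Sequence[float],
    tpm: Sequence[float] | None = None,
    min_tpm: float = 0.0,
    max_iter: int = 200,
) -> ModelFit:
    """Quasibinomial GLM of SPM on p_m + p_m^2.

    Logit link, variance phi*mu*(1-mu); the dispersion phi is the Pearson
    chi-square over the residual degrees of freedom of the full model.
    Per-term F statistics are sequential: each term's deviance reduction
    (added in the order p_m, then p_m^2) divided by phi, on (1, n-3)
    degrees of freedom. An optional expression filter drops genes with
    TPM < ``min_tpm`` before fitting.
    """
    spm = np.asarray(spm, dtype=float)
    p_m = np.asarray(p_m, dtype=float)
    if np.any((spm < 0) | (spm > 1)):
        raise ValueError("SPM values must lie in [0,1]")
    if min_tpm > 0:
        if tpm is None:
            raise ValueError("min_tpm filter requires TPM values")
        keep = np.asarray(tpm, dtype=float) >= min_tpm
        spm, p_m = spm[keep], p_m[keep]
        logger.info("fit_spm_glm: %d genes retained at TPM >= %g", len(spm), min_tpm)
    if len(spm) < 4:
        raise ValueError("need at least 4 genes to fit the quadratic GLM")

    X_full = _design(p_m)
    family = sm.families.Binomial()
    deviances: list[float] = []
    full_res = None
    for ncols in (1, 2, 3):
        res = sm.GLM(spm, X_full[:, :ncols], family=family).fit(maxiter=max_iter)
        if not res.converged:
            raise RuntimeError(
                f"GLM with {ncols} column(s) failed to converge after {max_iter} "
                f"iterations (deviance trace: {deviances + [float(res.deviance)]})"
            )
        deviances.append(float(res.deviance))
        full_res = res

    df_resid = int(full_res.df_resid)
    dispersion = float(full_res.pearson_chi2) / df_resid if df_resid > 0 else float("nan")
    f_stats: dict[str, tuple[float, int, int, float]] = {}
    for term, (d0, d1) in zip(("p_m", "p_m2"), zip(deviances, deviances[1:])):
        if dispersion > 0:
            f = (d0 - d1) / dispersion
            p = float(stats.f.sf(f, 1, df_resid))
        else:  # perfect fit: no residual variation to test against
            f, p = float("nan"), float("nan")
        f_stats[term] = (f, 1, df_resid, p)

    return ModelFit(
        coefficients={
            "intercept": float(full_res.params[0]),
            "p_m": float(full_res.params[1]),
            "p_m2": float(full_res.params[2]),
        },
        f_statistics=f_stats,
        dispersion=dispersion,
        fitted=np.asarray(full_res.fittedvalues),
    )
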