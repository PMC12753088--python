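"""Univariate summary-data MR estimators and diagnostics.

All estimators consume a :class:`~mrgrip.summary_data.SummaryDataset` of
per-SNP exposure associations (γ̂_j, σ_Xj) and outcome associations
(Γ̂_j, σ_Yj) and estimate the causal effect β of the exposure on the
outcome.

The mean-model estimators are:

* :func:`ivw` — inverse-variance weighted regression of Γ̂ on γ̂ through the
  origin; assumes balanced pleiotropy.
* :func:`mr_egger` — the same regression with a free intercept interpreted
  as average directional pleiotropy; requires the InSIDE assumption under
  the chosen allele coding, and is *not* invariant to recoding.
* :func:`mr_grip` — weighted regression of Γ̂γ̂ on γ̂² with a free intercept
  E(α_jγ̂_j); invariant to any recoding (GRIP) and unbiased under the VICE
  assumption (α_jγ_j independent of γ_j²).
* :func:`mr_grip_weak` — MR-GRIP with moment corrections for weak-instrument
  (regression-dilution) bias when σ_X is non-negligible.
* :func:`weighted_median`, :func:`mode_based` — order/mode statistics of the
  per-SNP ratio estimates, robust when at most half / a plurality of
  instruments are invalid.

Diagnostics: :func:`cochran_q` (heterogeneity of ratio estimates about the
IVW estimate), :func:`mean_f_statistic` (instrument strength) and
:func:`intercept_test` (directional pleiotropy).

Standard-error convention: weighted-regression coefficient standard errors
with multiplicative overdispersion whose residual scale is floored at 1.
P-values use the standard normal for IVW and a t distribution with m-2
degrees of freedom for the MR-Egger and MR-GRIP slope and intercept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._core import ConfigError, InstabilityError, ValidationError, wls_fit
from .summary_data import (
    CodingVector,
    SummaryDataset,
    all_positive_coding,
    apply_coding,
)

logger = logging.getLogger("mrgrip")

__all__ = [
    "MREstimate",
    "RatioEstimates",
    "ratio_estimates",
    "ivw",
    "mr_egger",
    "mr_grip",
    "mr_grip_weak",
    "weighted_median",
    "mode_based",
    "cochran_q",
    "mean_f_statistic",
    "intercept_test",
    "estimates_to_frame",
    "estimates_to_json",
]


@dataclass(frozen=True)
class MREstimate:
    """A fitted causal-effect result.

    ``beta`` is in outcome units per unit of exposure (log odds ratio per
    exposure unit when the outcome associations are log odds).  ``intercept``
    is present only for the two-parameter models (MR-Egger: average direct
    effect α₀; MR-GRIP: E(α_jγ̂_j)).  ``residual_scale`` is the estimated
    multiplicative overdispersion of the fitted regression (before the
    flooring at 1 used in the standard errors), NaN for non-regression
    estimators.
    """

    method: str
    beta: float
    se_beta: float
    p_beta: float
    ci_low: float
    ci_high: float
    n_snps: int
    intercept: float | None = None
    se_intercept: float | None = None
    p_intercept: float | None = None
    residual_scale: float = float("nan")
    df: int | None = None  # residual df of the t reference, None -> normal

    def __post_init__(self):
        if np.isfinite(self.se_beta) and self.se_beta > 0:
            if not (self.ci_low <= self.beta <= self.ci_high):
                raise ValidationError("confidence bounds must bracket the estimate")
        for p in (self.p_beta, self.p_intercept):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValidationError("p-values must lie in [0, 1]")

    @property
    def odds_ratio(self) -> float:
        """exp(beta): the odds ratio when beta is a log odds ratio."""
        return float(np.exp(self.beta))


@dataclass(frozen=True)
class RatioEstimates:
    """Per-SNP Wald ratios β̂_j = Γ̂_j/γ̂_j with their precision weights
    w_j = γ̂_j²/σ_Yj² (inverse variance of β̂_j when σ_X is negligible)."""

    ratio: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ratio", np.asarray(self.ratio, dtype=float))
        object.__setattr__(self, "weight", np.asarray(self.weight, dtype=float))
        if len(self.ratio) != len(self.weight):
            raise ValidationError("ratio and weight lengths differ")
        if np.any(self.weight <= 0):
            raise ValidationError("ratio weights must be strictly positive")


def _require_nonzero_exposure(ds: SummaryDataset) -> None:
    zeros = np.nonzero(ds.beta_exp == 0)[0]
    if zeros.size:
        raise ValidationError(
            "zero exposure effect for SNP(s) "
            + ", ".join(map(str, ds.snp_id[zeros]))
            + "; exclude them before ratio-based analysis"
        )


def ratio_estimates(ds: SummaryDataset) -> RatioEstimates:
    """Per-SNP ratio estimates and weights.

    Both the ratio Γ̂/γ̂ and the weight γ̂²/σ_Y² are even in the allele
    coding, so the output is invariant under any recoding.
    """
    _require_nonzero_exposure(ds)
    return RatioEstimates(ds.beta_out / ds.beta_exp, ds.beta_exp**2 / ds.se_out**2)


def _interval(beta: float, se: float, df: int | None):
    """95% CI and two-sided p for beta/se, normal or t(df) reference."""
    if se <= 0 or not np.isfinite(se):
        return float("nan"), float("nan"), float("nan")
    if df is None:
        q = stats.norm.ppf(0.975)
        p = 2.0 * stats.norm.sf(abs(beta) / se)
    else:
        q = stats.t.ppf(0.975, df)
        p = 2.0 * stats.t.sf(abs(beta) / se, df)
    return beta - q * se, beta + q * se, float(p)


def ivw(ds: SummaryDataset) -> MREstimate:
    """Inverse-variance weighted estimate of the causal effect.

    β̂ = Σ σ_Yj⁻² Γ̂_j γ̂_j / Σ σ_Yj⁻² γ̂_j² — the σ_Y⁻²-weighted
    zero-intercept regression of Γ̂ on γ̂, equivalently the w_j-weighted mean
    of the per-SNP ratios.  Invariant to allele recoding.
    """
    w = ds.se_out**-2.0
    params, se, resid_scale, dfr = wls_fit(ds.beta_exp[:, None], ds.beta_out, w)
    beta = float(params[0])
    se_beta = float(se[0])
    lo, hi, p = _interval(beta, se_beta, None)
    return MREstimate(
        "ivw", beta, se_beta, p, lo, hi, ds.m,
        residual_scale=resid_scale, df=None,
    )


def mr_egger(ds: SummaryDataset, coding: str = "all-positive") -> MREstimate:
    """MR-Egger regression: Γ̂ on γ̂ with a free intercept, σ_Y⁻² weights.

    ``coding`` is "all-positive" (conventional: orient every exposure effect
    positive before fitting) or "as-given" (use the orientation carried by
    the input).  The slope estimates β under the InSIDE assumption *for the
    chosen coding*; the estimator does not have GRIP and different codings
    generally give different answers.
    """
    if coding == "all-positive":
        ds = apply_coding(ds, all_positive_coding(ds))
        label = "mr_egger"
    elif coding == "as-given":
        label = "mr_egger_original"
    else:
        raise ConfigError(f"unknown coding {coding!r}; use 'all-positive' or 'as-given'")
    if ds.m < 3:
        raise ValidationError("MR-Egger needs at least 3 SNPs (slope, intercept, residual df)")
    X = np.column_stack([np.ones(ds.m), ds.beta_exp])
    w = ds.se_out**-2.0
    params, se, resid_scale, dfr = wls_fit(X, ds.beta_out, w)
    a0, beta = float(params[0]), float(params[1])
    lo, hi, p = _interval(beta, float(se[1]), dfr)
    _, _, p_int = _interval(a0, float(se[0]), dfr)
    return MREstimate(
        label, beta, float(se[1]), p, lo, hi, ds.m,
        intercept=a0, se_intercept=float(se[0]), p_intercept=p_int,
        residual_scale=resid_scale, df=dfr,
    )


def mr_grip(ds: SummaryDataset, fix_intercept_zero: bool = False) -> MREstimate:
    """MR-GRIP: weighted regression of Γ̂γ̂ on γ̂² with a free intercept.

    Multiplying the outcome model through by γ̂ makes both sides even in the
    allele coding, so the fit is invariant to recoding any subset of SNPs.
    The slope estimates β under the VICE assumption (α_jγ_j independent of
    γ_j²); the intercept estimates α₀ = E(α_jγ̂_j), the average contribution
    of direct effects to the genetic covariance of exposure and outcome.
    Weights are γ̂⁻²σ_Y⁻², the inverse variance of Γ̂γ̂ for fixed γ̂.

    With ``fix_intercept_zero`` the slope reduces algebraically to the IVW
    estimate.
    """
    _require_nonzero_exposure(ds)
    if not fix_intercept_zero and ds.m < 3:
        raise ValidationError("MR-GRIP with a free intercept needs at least 3 SNPs")
    y = ds.beta_out * ds.beta_exp
    x = ds.beta_exp**2
    w = ds.beta_exp**-2.0 * ds.se_out**-2.0
    if fix_intercept_zero:
        params, se, resid_scale, dfr = wls_fit(x[:, None], y, w)
        beta, se_beta = float(params[0]), float(se[0])
        lo, hi, p = _interval(beta, se_beta, None)
        return MREstimate(
            "mr_grip_null", beta, se_beta, p, lo, hi, ds.m,
            residual_scale=resid_scale, df=None,
        )
    X = np.column_stack([np.ones(ds.m), x])
    params, se, resid_scale, dfr = wls_fit(X, y, w)
    a0, beta = float(params[0]), float(params[1])
    lo, hi, p = _interval(beta, float(se[1]), dfr)
    _, _, p_int = _interval(a0, float(se[0]), dfr)
    return MREstimate(
        "mr_grip", beta, float(se[1]), p, lo, hi, ds.m,
        intercept=a0, se_intercept=float(se[0]), p_intercept=p_int,
        residual_scale=resid_scale, df=dfr,
    )


def _grip_weak_terms(ds: SummaryDataset):
    """Weighted moment sums for the bias-adjusted estimator.

    With w_j = σ_Yj⁻² (fixed weights, independent of γ), unbiased plug-ins
    for the moments of the true γ_j given γ̂_j ~ N(γ_j, σ_Xj²):

        γ̂(γ̂² - 3σ_X²)          for γ³ (times Γ̂)
        γ̂² - σ_X²               for γ²
        γ̂⁴ - 6γ̂²σ_X² + 3σ_X⁴   for γ⁴

    Odd powers of γ̂ appear only multiplied by Γ̂, so each term is even in
    the allele coding and the estimator retains GRIP.
    """
    w = ds.se_out**-2.0
    g, G, sx2 = ds.beta_exp, ds.beta_out, ds.se_exp**2
    t = {
        "w": w,
        "Gg3": w * G * g * (g**2 - 3.0 * sx2),
        "Gg": w * G * g,
        "g2": w * (g**2 - sx2),
        "g4": w * (g**4 - 6.0 * g**2 * sx2 + 3.0 * sx2**2),
    }
    return t


def _grip_weak_point(t, idx=slice(None)):
    sw = t["w"][idx].sum()
    sGg3 = t["Gg3"][idx].sum()
    sGg = t["Gg"][idx].sum()
    sg2 = t["g2"][idx].sum()
    sg4 = t["g4"][idx].sum()
    den = sw * sg4 - sg2**2
    num = sw * sGg3 - sGg * sg2
    return num, den, sGg, sg2, sw


def mr_grip_weak(ds: SummaryDataset) -> MREstimate:
    """Weak-instrument-adjusted MR-GRIP.

    Reconstructs the MR-GRIP slope that would be obtained with error-free
    exposure effects by replacing each power of γ with an unbiased moment
    estimate from γ̂ and σ_X, using fixed weights w_j = σ_Yj⁻² (the
    inverse-variance weights γ̂⁻²σ_Y⁻² depend on γ̂ and would re-introduce
    bias).  The standard error is a leave-one-out jackknife; under very weak
    instruments the corrected denominator can approach zero, in which case a
    numerical-instability error is raised rather than an unusable estimate
    returned.
    """
    if ds.m < 3:
        raise ValidationError("the weak-instrument adjustment needs at least 3 SNPs")
    t = _grip_weak_terms(ds)
    num, den, sGg, sg2, sw = _grip_weak_point(t)
    scale = float(t["w"].sum() * np.abs(t["g4"]).sum() + (np.abs(t["g2"]).sum()) ** 2)
    if den <= 0 or den < 1e-12 * scale:
        raise InstabilityError(
            f"degenerate moment-corrected denominator ({den:.3g}); instruments are "
            "too weak for a stable adjustment"
        )
    beta = float(num / den)
    a0 = float((sGg - beta * sg2) / sw)

    # leave-one-out jackknife for both coefficients
    m = ds.m
    betas = np.empty(m)
    alphas = np.empty(m)
    mask = np.ones(m, dtype=bool)
    for i in range(m):
        mask[i] = False
        num_i, den_i, sGg_i, sg2_i, sw_i = _grip_weak_point(t, mask)
        if den_i <= 0:
            raise InstabilityError(
                "degenerate leave-one-out denominator in the jackknife; "
                "instruments too weak for a stable adjustment"
            )
        betas[i] = num_i / den_i
        alphas[i] = (sGg_i - betas[i] * sg2_i) / sw_i
        mask[i] = True
    se_beta = float(np.sqrt((m - 1) / m * np.sum((betas - betas.mean()) ** 2)))
    se_a0 = float(np.sqrt((m - 1) / m * np.sum((alphas - alphas.mean()) ** 2)))

    dfr = m - 2
    lo, hi, p = _interval(beta, se_beta, dfr)
    _, _, p_int = _interval(a0, se_a0, dfr)
    return MREstimate(
        "mr_grip_weak", beta, se_beta, p, lo, hi, m,
        intercept=a0, se_intercept=se_a0, p_intercept=p_int, df=dfr,
    )


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Interpolated weighted median: linear interpolation of the ordered
    ratios against centred cumulative weights."""
    order = np.argsort(ratio)
    b = ratio[order]
    w = weight[order] / weight.sum()
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(b[0])
    if 0.5 >= cum[-1]:
        return float(b[-1])
    return float(np.interp(0.5, cum, b))


def _parametric_bootstrap(ds, point_fn, n_boot, seed):
    """SD of a ratio-based statistic under resampling of γ̂, Γ̂ from their
    sampling distributions."""
    rng = np.random.default_rng(seed)
    m = ds.m
    est = np.empty(n_boot)
    for b in range(n_boot):
        g = rng.normal(ds.beta_exp, ds.se_exp)
        G = rng.normal(ds.beta_out, ds.se_out)
        nz = g != 0
        est[b] = point_fn(G[nz] / g[nz], g[nz] ** 2 / ds.se_out[nz] ** 2)
    return float(est.std(ddof=1))


def weighted_median(ds: SummaryDataset, n_boot: int = 1000, *, seed: int) -> MREstimate:
    """Weighted median of the per-SNP ratio estimates.

    Consistent when valid instruments carry at least half the weight
    (median(α_j) = 0).  Works directly on the ratios, hence invariant to
    allele recoding; the parametric-bootstrap standard error first
    standardizes to all-positive coding so that, for a given seed, the draws
    (and thus the reported SE) are also bit-identical under recoding.
    """
    if ds.m < 3:
        raise ValidationError("weighted median needs at least 3 SNPs")
    if n_boot < 2:
        raise ConfigError("n_boot must be at least 2")
    ds = apply_coding(ds, all_positive_coding(ds))
    r = ratio_estimates(ds)
    beta = _weighted_median_point(r.ratio, r.weight)
    se = _parametric_bootstrap(ds, _weighted_median_point, n_boot, seed)
    lo, hi, p = _interval(beta, se, None)
    return MREstimate("weighted_median", beta, se, p, lo, hi, ds.m, df=None)


def _mode_point(ratio: np.ndarray, weight: np.ndarray, phi: float = 1.0) -> float:
    """Mode of the weighted normal-kernel density of the ratios, with the
    modified-Silverman bandwidth 0.9·min(sd, mad)·m^(−1/5) scaled by phi."""
    m = len(ratio)
    sd = np.std(ratio, ddof=1)
    mad = stats.median_abs_deviation(ratio, scale="normal")
    s = 0.9 * min(sd, mad) * m ** (-1.0 / 5.0)
    h = max(1e-8, phi * s)
    lo, hi = ratio.min() - 3 * h, ratio.max() + 3 * h
    grid = np.linspace(lo, hi, 1024)
    wn = weight / weight.sum()
    dens = (wn[None, :] * np.exp(-0.5 * ((grid[:, None] - ratio[None, :]) / h) ** 2)).sum(axis=1)
    k = int(np.argmax(dens))
    # parabolic refinement around the best grid point
    if 0 < k < len(grid) - 1:
        y0, y1, y2 = dens[k - 1], dens[k], dens[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            step = grid[1] - grid[0]
            return float(grid[k] + 0.5 * step * (y0 - y2) / denom)
    return float(grid[k])


def mode_based(
    ds: SummaryDataset, phi: float = 1.0, n_boot: int = 1000, *, seed: int
) -> MREstimate:
    """Mode-based estimate: the mode of the smoothed weighted density of the
    per-SNP ratios.

    Consistent when the largest group of instruments sharing a ratio value is
    the valid one (mode(α_j) = 0).  ``phi`` scales the kernel bandwidth.
    Invariant to allele recoding (see :func:`weighted_median` for the
    bootstrap seeding convention).
    """
    if ds.m < 3:
        raise ValidationError("mode-based estimator needs at least 3 SNPs")
    if phi <= 0:
        raise ConfigError("phi must be positive")
    if n_boot < 2:
        raise ConfigError("n_boot must be at least 2")
    ds = apply_coding(ds, all_positive_coding(ds))
    r = ratio_estimates(ds)
    beta = _mode_point(r.ratio, r.weight, phi)
    se = _parametric_bootstrap(
        ds, lambda b, w: _mode_point(b, w, phi), n_boot, seed
    )
    lo, hi, p = _interval(beta, se, None)
    return MREstimate("mode_based", beta, se, p, lo, hi, ds.m, df=None)


def cochran_q(ds: SummaryDataset) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic of the ratio estimates about the
    IVW estimate: Q = Σ w_j (β̂_j − β̂_IVW)², w_j = γ̂_j²/σ_Yj², with m−1
    degrees of freedom and an upper-tail chi-square p-value.  Coding
    invariant."""
    if ds.m < 2:
        raise ValidationError("Cochran's Q needs at least 2 SNPs")
    r = ratio_estimates(ds)
    beta_ivw = float(np.sum(r.weight * r.ratio) / np.sum(r.weight))
    q = float(np.sum(r.weight * (r.ratio - beta_ivw) ** 2))
    df = ds.m - 1
    return q, df, float(stats.chi2.sf(q, df))


def mean_f_statistic(ds: SummaryDataset) -> float:
    """Mean per-SNP F-statistic γ̂_j²/σ_Xj², the standard instrument-strength
    diagnostic (values below ~10 signal weak-instrument bias)."""
    return float(np.mean(ds.beta_exp**2 / ds.se_exp**2))


def intercept_test(est: MREstimate) -> tuple[float, float]:
    """Directional-pleiotropy test: intercept / se(intercept) referred to the
    estimate's own reference distribution (t(m−2) for the regression models,
    normal otherwise).  Returns (statistic, two-sided p)."""
    if est.intercept is None or est.se_intercept is None:
        raise ValidationError(f"{est.method} carries no intercept to test")
    if est.se_intercept <= 0:
        raise ValidationError("intercept standard error must be positive")
    z = est.intercept / est.se_intercept
    if est.df is not None:
        p = 2.0 * stats.t.sf(abs(z), est.df)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# result serialization

_TIDY_COLUMNS = [
    "method", "nsnp", "beta", "se", "ci_low", "ci_high", "pval",
    "intercept", "intercept_se", "intercept_pval",
]


def estimates_to_frame(estimates: Sequence[MREstimate]) -> pd.DataFrame:
    """Tidy table, one row per method."""
    rows = []
    for e in estimates:
        rows.append({
            "method": e.method, "nsnp": e.n_snps, "beta": e.beta, "se": e.se_beta,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "pval": e.p_beta,
            "intercept": e.intercept, "intercept_se": e.se_intercept,
            "intercept_pval": e.p_intercept,
        })
    return pd.DataFrame(rows, columns=_TIDY_COLUMNS)


def estimates_to_json(estimates: Sequence[MREstimate], path: str | Path | None = None) -> str:
    """Machine-readable JSON report; written to ``path`` when given."""
    records = estimates_to_frame(estimates).to_dict(orient="records")
    text = json.dumps({"results": records}, indent=2, allow_nan=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
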