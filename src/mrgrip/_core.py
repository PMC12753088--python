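"""Shared plumbing: exceptions and the weighted-least-squares backend.

Every regression-based estimator in the package funnels through
:func:`wls_fit` so that the standard-error convention (multiplicative
overdispersion with the residual scale floored at 1) is applied uniformly.
"""

from __future__ import annotations

import logging

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger("mrgrip")


class MRGripError(Exception):
    """Base class for package errors."""


class ValidationError(MRGripError, ValueError):
    """Input data violates a structural invariant (lengths, signs, finiteness)."""


class ConfigError(MRGripError, ValueError):
    """A caller-supplied option is unusable (bad flag, missing column, bad count)."""


class InstabilityError(MRGripError, ArithmeticError):
    """The requested fit is numerically degenerate (singular design, sign-flipped
    or vanishing denominator in a moment-corrected estimator)."""


# Condition-number guard for weighted designs, applied after per-column
# normalisation so that it detects genuine collinearity, not unit mismatch.
_COND_LIMIT = 1e8


def wls_fit(X: np.ndarray, y: np.ndarray, weights: np.ndarray):
    """Weighted least squares with an overdispersion-floored standard error.

    Fits ``y = X b + e`` with diagonal weights, then rescales the coefficient
    standard errors by ``sqrt(max(1, s2))`` where ``s2`` is the weighted
    residual mean square.  With weights equal to inverse sampling variances
    this reproduces the convention of reporting fixed-effect standard errors
    when the data are underdispersed and multiplicative random-effect
    standard errors when they are overdispersed.

    Returns
    -------
    (params, se, resid_scale, df_resid)
        ``resid_scale`` is ``sqrt(s2)``, the estimated residual scale before
        flooring (so an exact fit reports ~0); the standard errors use
        ``max(1, resid_scale)``.  ``df_resid`` may be 0 for a saturated fit,
        in which case ``se`` comes from the unit information matrix and
        ``resid_scale`` is reported as 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if X.shape[0] != y.shape[0] or w.shape[0] != y.shape[0]:
        raise ValidationError("design, response and weights must have equal length")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValidationError("non-finite values in regression inputs")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValidationError("weights must be positive and finite")

    n, p = X.shape
    if n < p:
        raise ValidationError(f"{n} observations cannot identify {p} parameters")

    # collinearity guard on the weighted, column-normalised design
    Xw = np.sqrt(w)[:, None] * X
    norms = np.linalg.norm(Xw, axis=0)
    if np.any(norms == 0):
        raise InstabilityError("a design column is identically zero")
    cond = np.linalg.cond(Xw / norms)
    if cond > _COND_LIMIT:
        raise InstabilityError(
            f"near-singular weighted design (condition number {cond:.3g}); "
            "the regressors carry no independent information"
        )

    res = sm.WLS(y, X, weights=w).fit()
    params = np.asarray(res.params, dtype=float)
    df_resid = n - p
    # unit-variance standard errors from the weighted information matrix
    unit_cov = np.linalg.inv(Xw.T @ Xw)
    unit_se = np.sqrt(np.diag(unit_cov))
    if df_resid > 0:
        resid_scale = float(np.sqrt(res.scale))
    else:
        resid_scale = 1.0
    se = unit_se * max(1.0, resid_scale)
    return params, se, resid_scale, df_resid
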