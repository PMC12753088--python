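"""Coding-invariant versions of collider correction and index-effect
regression.

Both procedures are, at heart, the MR-GRIP regression applied to a different
response: a per-SNP coefficient vector is multiplied by the SNP-exposure
association γ̂_j and regressed on γ̂_j², which makes the fitted slope
invariant to the arbitrary choice of effect allele for each SNP.  They are
implemented by constructing a summary dataset with the relevant response in
the outcome slot and delegating to :func:`mrgrip.estimators.mr_grip`.

* Collider correction (one-sample MR): the outcome is first regressed on
  the exposure and each SNP, giving an exposure coefficient β̂* and
  conditional SNP-outcome coefficients α̂*_j.  Because X is a collider,
  β̂* is confounded; the bias δ is recovered as the slope of α̂*_jγ̂_j on
  γ̂_j², and the causal effect is β̂ = β̂* + δ̂.

* Index-effect regression (selection-bias adjustment in GWAS): given
  conditional SNP-outcome associations Γ̂*_j (adjusted for an index trait),
  the induced proportional bias b is the slope of Γ̂*_jγ̂_j on γ̂_j², and
  the adjusted direct effects are α̂_j = Γ̂*_j − b̂γ̂_j.  The adjusted
  effects flip sign with the SNP's coding (they are per-allele effects),
  while b̂ does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._core import ValidationError
from .estimators import MREstimate, ivw, mr_grip
from .summary_data import SummaryDataset

__all__ = [
    "ColliderInput",
    "IndexEffectInput",
    "ColliderResult",
    "IndexEffectResult",
    "collider_correction_grip",
    "index_effect_grip",
]


def _check_vectors(**named):
    lengths = {k: len(np.asarray(v)) for k, v in named.items()}
    if len(set(lengths.values())) != 1:
        raise ValidationError(f"vector lengths differ: {lengths}")


@dataclass(frozen=True)
class ColliderInput:
    """Inputs for collider correction: the exposure coefficient β̂* from the
    outcome-on-exposure-and-SNP regression, the per-SNP conditional SNP-outcome
    coefficients α̂*_j with standard errors, and the SNP-exposure associations
    γ̂_j with standard errors."""

    beta_star: float
    alpha_star: np.ndarray
    se_alpha_star: np.ndarray
    gamma_hat: np.ndarray
    se_gamma: np.ndarray

    def __post_init__(self):
        for name in ("alpha_star", "se_alpha_star", "gamma_hat", "se_gamma"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        _check_vectors(alpha_star=self.alpha_star, se_alpha_star=self.se_alpha_star,
                       gamma_hat=self.gamma_hat, se_gamma=self.se_gamma)
        if np.any(self.se_alpha_star <= 0) or np.any(self.se_gamma <= 0):
            raise ValidationError("standard errors must be strictly positive")

    @property
    def m(self) -> int:
        return len(self.gamma_hat)


@dataclass(frozen=True)
class IndexEffectInput:
    """Inputs for index-effect regression: SNP-exposure associations γ̂_j and
    conditional SNP-outcome-given-exposure associations Γ̂*_j with SEs."""

    gamma_hat: np.ndarray
    gamma_star: np.ndarray
    se_gamma_star: np.ndarray

    def __post_init__(self):
        for name in ("gamma_hat", "gamma_star", "se_gamma_star"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        _check_vectors(gamma_hat=self.gamma_hat, gamma_star=self.gamma_star,
                       se_gamma_star=self.se_gamma_star)
        if np.any(self.se_gamma_star <= 0):
            raise ValidationError("standard errors must be strictly positive")

    @property
    def m(self) -> int:
        return len(self.gamma_hat)


@dataclass(frozen=True)
class ColliderResult:
    delta: MREstimate     # the collider-bias slope δ̂ (with intercept test)
    beta_hat: float       # corrected causal effect β̂* + δ̂

    @property
    def delta_hat(self) -> float:
        return self.delta.beta


@dataclass(frozen=True)
class IndexEffectResult:
    slope: MREstimate       # the index-effect slope b̂
    alpha_hat: np.ndarray   # adjusted per-SNP effects Γ̂*_j − b̂γ̂_j

    @property
    def b_hat(self) -> float:
        return self.slope.beta


def _grip_core(gamma, se_gamma, response, se_response, *, fix_intercept_zero):
    """The shared GRIP regression: response·γ̂ on γ̂², weights
    γ̂⁻²·se_response⁻², via the summary-data machinery."""
    ds = SummaryDataset(
        snp_id=np.array([f"snp{i+1}" for i in range(len(gamma))], dtype=object),
        beta_exp=gamma, se_exp=se_gamma, beta_out=response, se_out=se_response,
    )
    if fix_intercept_zero:
        return mr_grip(ds, fix_intercept_zero=True)
    return mr_grip(ds)


def collider_correction_grip(
    inp: ColliderInput, *, fix_intercept_zero: bool = False
) -> ColliderResult:
    """Coding-invariant collider correction.

    δ̂ is the slope of the weighted regression of α̂*_jγ̂_j on γ̂_j² (free
    intercept by default, mirroring the directional-pleiotropy intercept of
    MR-GRIP; ``fix_intercept_zero`` forces it through the origin).  The
    corrected causal effect is β̂ = β̂* + δ̂.
    """
    if inp.m < 3 and not fix_intercept_zero:
        raise ValidationError("collider correction needs at least 3 SNPs")
    est = _grip_core(
        inp.gamma_hat, inp.se_gamma, inp.alpha_star, inp.se_alpha_star,
        fix_intercept_zero=fix_intercept_zero,
    )
    return ColliderResult(delta=est, beta_hat=float(inp.beta_star) + est.beta)


def index_effect_grip(
    inp: IndexEffectInput, *, fix_intercept_zero: bool = False,
    se_gamma: np.ndarray | None = None,
) -> IndexEffectResult:
    """Coding-invariant index-effect regression.

    b̂ is the slope of Γ̂*_jγ̂_j on γ̂_j²; the adjusted per-SNP effects are
    α̂_j = Γ̂*_j − b̂γ̂_j.  b̂ is invariant to recoding, while the α̂_j flip
    sign with their SNP's coding, as per-allele effects must.
    """
    if inp.m < 3 and not fix_intercept_zero:
        raise ValidationError("index-effect regression needs at least 3 SNPs")
    se_g = np.ones(inp.m) if se_gamma is None else np.asarray(se_gamma, dtype=float)
    est = _grip_core(
        inp.gamma_hat, se_g, inp.gamma_star, inp.se_gamma_star,
        fix_intercept_zero=fix_intercept_zero,
    )
    return IndexEffectResult(slope=est, alpha_hat=inp.gamma_star - est.beta * inp.gamma_hat)
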