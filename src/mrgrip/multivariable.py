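"""Multivariable-exposure MR: IVW, MR-Egger and MR-GRIP for k exposures.

The outcome model for SNP j is Γ̂_j = β₁γ̂_1j + ⋯ + β_kγ̂_kj + α_j + ε_j,
so the causal effects (β₁, …, β_k) come from a weighted multiple regression
of the outcome associations on the k columns of exposure associations.

Recoding SNP j flips its whole row — every exposure association and the
outcome association together — so the no-intercept fit (:func:`mv_ivw`) is
coding-invariant.  :func:`mv_egger` adds a free intercept after orienting
all rows so a chosen *reference* exposure has positive effects; its result
depends on that choice.  :func:`mv_grip` instead multiplies the whole model
through by the reference exposure's association, making every term even in
the coding: its result is invariant to recoding for every reference,
although different references estimate under different VICE-type
assumptions and are reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._core import ValidationError, wls_fit
from .estimators import MREstimate, _interval
from .summary_data import CodingVector

logger = logging.getLogger("mrgrip")

__all__ = ["MVSummaryDataset", "mv_ivw", "mv_egger", "mv_grip", "mv_apply_coding"]


@dataclass(frozen=True)
class MVSummaryDataset:
    """m SNPs x k exposures summary statistics plus outcome associations."""

    snp_id: np.ndarray
    beta_exp: np.ndarray  # (m, k)
    se_exp: np.ndarray    # (m, k)
    beta_out: np.ndarray  # (m,)
    se_out: np.ndarray    # (m,)
    exposure_names: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "snp_id", np.asarray(self.snp_id, dtype=object))
        object.__setattr__(self, "beta_exp", np.atleast_2d(np.asarray(self.beta_exp, dtype=float)))
        object.__setattr__(self, "se_exp", np.atleast_2d(np.asarray(self.se_exp, dtype=float)))
        object.__setattr__(self, "beta_out", np.asarray(self.beta_out, dtype=float))
        object.__setattr__(self, "se_out", np.asarray(self.se_out, dtype=float))
        object.__setattr__(self, "exposure_names", tuple(self.exposure_names))
        m, k = self.beta_exp.shape
        if len(self.snp_id) != m or len(set(self.snp_id)) != m:
            raise ValidationError("snp_id must be unique and match the effect matrix")
        if self.se_exp.shape != (m, k):
            raise ValidationError("se_exp shape differs from beta_exp")
        if self.beta_out.shape != (m,) or self.se_out.shape != (m,):
            raise ValidationError("outcome vectors must have one entry per SNP")
        if len(self.exposure_names) != k:
            raise ValidationError("need one name per exposure")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValidationError("standard errors must be strictly positive")
        if not (np.all(np.isfinite(self.beta_exp)) and np.all(np.isfinite(self.beta_out))):
            raise ValidationError("effects must be finite")

    @property
    def m(self) -> int:
        return self.beta_exp.shape[0]

    @property
    def k(self) -> int:
        return self.beta_exp.shape[1]

    def exposure_index(self, reference: int | str) -> int:
        if isinstance(reference, str):
            try:
                return self.exposure_names.index(reference)
            except ValueError:
                raise ValidationError(
                    f"unknown exposure {reference!r}; have {self.exposure_names}"
                ) from None
        if not 0 <= reference < self.k:
            raise ValidationError(f"exposure index {reference} out of range")
        return int(reference)


def mv_apply_coding(mvds: MVSummaryDataset, coding: CodingVector) -> MVSummaryDataset:
    """Flip whole SNP rows (all exposure effects and the outcome effect)."""
    if len(coding) != mvds.m:
        raise ValidationError("coding length differs from dataset length")
    s = coding.signs.astype(float)
    return MVSummaryDataset(
        mvds.snp_id, mvds.beta_exp * s[:, None], mvds.se_exp,
        mvds.beta_out * s, mvds.se_out, mvds.exposure_names,
    )


def _package(params, se, dfr, resid_scale, names, m, offset=0):
    out = []
    for i, name in enumerate(names):
        b, s = float(params[offset + i]), float(se[offset + i])
        lo, hi, p = _interval(b, s, dfr if dfr is not None else None)
        out.append(MREstimate(
            name, b, s, p, lo, hi, m, residual_scale=resid_scale, df=dfr,
        ))
    return out


def mv_ivw(mvds: MVSummaryDataset) -> list[MREstimate]:
    """Multivariable IVW: σ_Y⁻²-weighted multiple regression of Γ̂ on the k
    exposure-association columns, no intercept.  Coding-invariant.  Returns
    one estimate per exposure (method label ``mv_ivw:<name>``).  P-values
    use the standard normal, as in the univariate IVW."""
    if mvds.m <= mvds.k:
        raise ValidationError(f"need more SNPs ({mvds.m}) than exposures ({mvds.k})")
    w = mvds.se_out**-2.0
    params, se, resid_scale, dfr = wls_fit(mvds.beta_exp, mvds.beta_out, w)
    return _package(
        params, se, None, resid_scale,
        [f"mv_ivw:{n}" for n in mvds.exposure_names], mvds.m,
    )


def mv_egger(mvds: MVSummaryDataset, reference: int | str) -> list[MREstimate]:
    """Multivariable MR-Egger with all-positive coding of the reference
    exposure: rows are flipped so the reference column is non-negative, then
    the regression is fitted with a free intercept.  The first returned
    element is the intercept (average directional pleiotropy under that
    coding); results generally change with the reference."""
    r = mvds.exposure_index(reference)
    if mvds.m <= mvds.k + 1:
        raise ValidationError("need more SNPs than exposures plus intercept")
    signs = np.where(mvds.beta_exp[:, r] < 0, -1, 1)
    mvds = mv_apply_coding(mvds, CodingVector(signs))
    X = np.column_stack([np.ones(mvds.m), mvds.beta_exp])
    w = mvds.se_out**-2.0
    params, se, resid_scale, dfr = wls_fit(X, mvds.beta_out, w)
    ref_name = mvds.exposure_names[r]
    names = [f"mv_egger[{ref_name}]:intercept"] + [
        f"mv_egger[{ref_name}]:{n}" for n in mvds.exposure_names
    ]
    return _package(params, se, dfr, resid_scale, names, mvds.m)


def mv_grip(mvds: MVSummaryDataset, reference: int | str) -> list[MREstimate]:
    """Multivariable MR-GRIP: multiply the outcome model through by the
    reference exposure's association γ̂_r, regressing Γ̂γ̂_r on γ̂_r²,
    γ̂_2γ̂_r, …, γ̂_kγ̂_r with a free intercept and weights γ̂_r⁻²σ_Y⁻².
    Every term is even in the allele coding, so the fit is invariant to
    recoding for any reference choice; the intercept estimates E(α_jγ̂_rj).
    The first returned element is the intercept."""
    r = mvds.exposure_index(reference)
    if mvds.m <= mvds.k + 1:
        raise ValidationError("need more SNPs than exposures plus intercept")
    g_r = mvds.beta_exp[:, r]
    zeros = np.nonzero(g_r == 0)[0]
    if zeros.size:
        raise ValidationError(
            "zero reference-exposure effect for SNP(s) "
            + ", ".join(map(str, mvds.snp_id[zeros]))
        )
    y = mvds.beta_out * g_r
    X = np.column_stack([np.ones(mvds.m), mvds.beta_exp * g_r[:, None]])
    w = g_r**-2.0 * mvds.se_out**-2.0
    params, se, resid_scale, dfr = wls_fit(X, y, w)
    ref_name = mvds.exposure_names[r]
    names = [f"mv_grip[{ref_name}]:intercept"] + [
        f"mv_grip[{ref_name}]:{n}" for n in mvds.exposure_names
    ]
    return _package(params, se, dfr, resid_scale, names, mvds.m)


def read_mv_summary_table(
    path, exposures: Sequence[str], *,
    snp_col: str = "snp", out_beta_col: str = "beta_outcome",
    out_se_col: str = "se_outcome", sep: str | None = None,
) -> MVSummaryDataset:
    """Read a wide table: one row per SNP, ``beta_<name>``/``se_<name>``
    columns per exposure, then outcome columns."""
    from pathlib import Path

    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    need = [snp_col, out_beta_col, out_se_col]
    for name in exposures:
        need += [f"beta_{name}", f"se_{name}"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s) {missing} in {path.name}")
    complete = df[need].notna().all(axis=1)
    if (~complete).sum():
        logger.info("%s: dropped %d incomplete row(s)", path.name, int((~complete).sum()))
        df = df[complete]
    return MVSummaryDataset(
        df[snp_col].astype(str).to_numpy(dtype=object),
        df[[f"beta_{n}" for n in exposures]].to_numpy(dtype=float),
        df[[f"se_{n}" for n in exposures]].to_numpy(dtype=float),
        df[out_beta_col].to_numpy(dtype=float),
        df[out_se_col].to_numpy(dtype=float),
        tuple(exposures),
    )
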