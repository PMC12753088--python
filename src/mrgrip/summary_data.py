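"""Data model, file I/O and allele-recoding transforms for two-sample MR
summary statistics.

The universal input is a table of per-SNP association estimates: an effect of
each variant on the exposure (``beta_exposure``) with its standard error, and
an effect on the outcome (``beta_outcome``) with its standard error.  The two
sets of estimates are assumed to come from non-overlapping samples of the
same population and to be pre-harmonized, i.e. both expressed per copy of the
same effect allele for each SNP.

Allele coding
-------------
For each SNP the choice of which allele counts as the "effect" allele is
arbitrary: coding the other allele flips the sign of both the exposure and
the outcome association.  :class:`CodingVector` represents such a choice as a
vector of ±1 signs, :func:`apply_coding` applies it, and
:func:`all_positive_coding` computes the conventional orientation in which
every exposure effect is non-negative.  Estimators that are unchanged under
any such recoding are said to have the genotype recoding invariance property
(GRIP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._core import ConfigError, ValidationError

logger = logging.getLogger("mrgrip")

#: default column names of the tabular dialect (tab-separated, header row,
#: '.' decimal); allele columns are optional metadata.
DEFAULT_COLUMNS: dict[str, str] = {
    "snp": "snp",
    "beta_exp": "beta_exposure",
    "se_exp": "se_exposure",
    "beta_out": "beta_outcome",
    "se_out": "se_outcome",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
}

_REQUIRED_ROLES = ("snp", "beta_exp", "se_exp", "beta_out", "se_out")


@dataclass(frozen=True)
class SummaryDataset:
    """Per-SNP summary statistics for one exposure and one outcome.

    Attributes
    ----------
    snp_id : array of str
        Unique variant identifiers.
    beta_exp, se_exp : arrays of float
        Per-allele effect on the exposure and its standard error (> 0).
    beta_out, se_out : arrays of float
        Per-allele effect on the outcome (e.g. log odds) and its standard
        error (> 0).
    effect_allele, other_allele : arrays of str or None
        Optional allele labels, carried as opaque metadata.
    """

    snp_id: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "snp_id", np.asarray(self.snp_id, dtype=object))
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        m = len(self.snp_id)
        if m < 1:
            raise ValidationError("a dataset needs at least one SNP")
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            if len(getattr(self, name)) != m:
                raise ValidationError(f"{name} has length {len(getattr(self, name))}, expected {m}")
        if len(set(self.snp_id)) != m:
            raise ValidationError("snp_id values must be unique")
        for name in ("beta_exp", "beta_out"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite values in {name}")
        for name in ("se_exp", "se_out"):
            se = getattr(self, name)
            if not np.all(np.isfinite(se)):
                raise ValidationError(f"non-finite values in {name}")
            bad = np.nonzero(se <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"non-positive {name} for SNP(s) {', '.join(map(str, self.snp_id[bad]))}"
                )
        for name in ("effect_allele", "other_allele"):
            alleles = getattr(self, name)
            if alleles is not None:
                alleles = np.asarray(alleles, dtype=object)
                if len(alleles) != m:
                    raise ValidationError(f"{name} has wrong length")
                object.__setattr__(self, name, alleles)

    @property
    def m(self) -> int:
        """Number of SNPs."""
        return len(self.snp_id)

    def __len__(self) -> int:
        return self.m

    def select(self, index) -> "SummaryDataset":
        """Subset by boolean mask or integer index array."""
        index = np.asarray(index)
        kw = {}
        for name in ("effect_allele", "other_allele"):
            a = getattr(self, name)
            kw[name] = a[index] if a is not None else None
        return SummaryDataset(
            self.snp_id[index], self.beta_exp[index], self.se_exp[index],
            self.beta_out[index], self.se_out[index], **kw,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in the default column dialect."""
        data = {
            DEFAULT_COLUMNS["snp"]: self.snp_id,
            DEFAULT_COLUMNS["beta_exp"]: self.beta_exp,
            DEFAULT_COLUMNS["se_exp"]: self.se_exp,
            DEFAULT_COLUMNS["beta_out"]: self.beta_out,
            DEFAULT_COLUMNS["se_out"]: self.se_out,
        }
        if self.effect_allele is not None:
            data[DEFAULT_COLUMNS["effect_allele"]] = self.effect_allele
        if self.other_allele is not None:
            data[DEFAULT_COLUMNS["other_allele"]] = self.other_allele
        return pd.DataFrame(data)


@dataclass(frozen=True)
class CodingVector:
    """A choice of effect allele per SNP, encoded as ±1 signs."""

    signs: np.ndarray

    def __post_init__(self):
        signs = np.asarray(self.signs, dtype=int)
        if signs.ndim != 1 or signs.size < 1:
            raise ValidationError("signs must be a non-empty 1-D vector")
        if not np.all(np.isin(signs, (-1, 1))):
            raise ValidationError("coding signs must all be +1 or -1")
        object.__setattr__(self, "signs", signs)

    def __len__(self) -> int:
        return len(self.signs)

    def compose(self, other: "CodingVector") -> "CodingVector":
        """Elementwise product of two codings (apply one after the other)."""
        if len(self) != len(other):
            raise ValidationError("coding lengths differ")
        return CodingVector(self.signs * other.signs)


def apply_coding(ds: SummaryDataset, coding: CodingVector) -> SummaryDataset:
    """Re-express the dataset under a different effect-allele choice.

    Flipping SNP j multiplies both its exposure and outcome effect by -1;
    standard errors and identifiers are unchanged, and allele labels (if
    present) are swapped.  Applying the same coding twice is the identity.
    """
    if len(coding) != ds.m:
        raise ValidationError(f"coding length {len(coding)} != dataset length {ds.m}")
    s = coding.signs.astype(float)
    kw = {}
    if ds.effect_allele is not None and ds.other_allele is not None:
        flip = coding.signs == -1
        kw["effect_allele"] = np.where(flip, ds.other_allele, ds.effect_allele)
        kw["other_allele"] = np.where(flip, ds.effect_allele, ds.other_allele)
    else:
        kw["effect_allele"] = ds.effect_allele
        kw["other_allele"] = ds.other_allele
    return SummaryDataset(
        ds.snp_id, ds.beta_exp * s, ds.se_exp, ds.beta_out * s, ds.se_out, **kw
    )


def all_positive_coding(ds: SummaryDataset, reference: str = "exposure") -> CodingVector:
    """Coding that orients every reference effect to be non-negative.

    ``reference`` selects the column driving the orientation: "exposure"
    (the convention) or "outcome".  SNPs whose reference effect is exactly
    zero keep sign +1 and trigger a warning, since their orientation is
    undefined; ratio-based downstream analyses should exclude them.
    """
    if reference == "exposure":
        ref = ds.beta_exp
    elif reference == "outcome":
        ref = ds.beta_out
    else:
        raise ConfigError(f"unknown reference {reference!r}; use 'exposure' or 'outcome'")
    zeros = np.nonzero(ref == 0)[0]
    if zeros.size:
        logger.warning(
            "all_positive_coding: %d SNP(s) with exactly zero %s effect kept at +1: %s",
            zeros.size, reference, ", ".join(map(str, ds.snp_id[zeros])),
        )
    signs = np.where(ref < 0, -1, 1)
    return CodingVector(signs)


def exclude_zero_exposure(ds: SummaryDataset) -> SummaryDataset:
    """Drop SNPs whose exposure effect is exactly zero, with a log entry.

    Ratio-based operations are undefined for such SNPs; this is the
    standard pre-filter for them.
    """
    keep = ds.beta_exp != 0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "excluding %d SNP(s) with zero exposure effect: %s",
            n_drop, ", ".join(map(str, ds.snp_id[~keep])),
        )
        if not keep.any():
            raise ValidationError("all SNPs have zero exposure effect")
        return ds.select(keep)
    return ds


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    sheet: str | int | None = None,
) -> SummaryDataset:
    """Read a delimited text file (TSV/CSV) or XLSX sheet of summary statistics.

    Parameters
    ----------
    path : str or Path
        ``.csv`` is read comma-separated, ``.xlsx`` via openpyxl (``sheet``
        selects the worksheet), anything else tab-separated.
    column_map : mapping, optional
        Maps roles (``snp``, ``beta_exp``, ``se_exp``, ``beta_out``,
        ``se_out``, and optionally ``effect_allele``/``other_allele``) to the
        column names in the file.  Defaults to :data:`DEFAULT_COLUMNS`.

    Rows with any missing required value are dropped and counted in the log.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigError(f"unknown column roles: {sorted(unknown)}")
        cols.update(column_map)

    suffix = path.suffix.lower()
    if suffix == ".xlsx":
        df = pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
    else:
        df = pd.read_csv(path, sep="," if suffix == ".csv" else "\t")

    missing = [cols[r] for r in _REQUIRED_ROLES if cols[r] not in df.columns]
    if missing:
        raise ConfigError(
            f"required column(s) {missing} not found in {path.name}; "
            f"available: {list(df.columns)}"
        )

    required = [cols[r] for r in _REQUIRED_ROLES]
    complete = df[required].notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("%s: dropped %d row(s) with missing required values", path.name, n_drop)
        df = df[complete]
    if df.empty:
        raise ValidationError(f"{path.name}: no complete rows")

    kw = {}
    for role in ("effect_allele", "other_allele"):
        name = cols[role]
        if name in df.columns:
            kw[role] = df[name].astype(object).to_numpy()
    return SummaryDataset(
        df[cols["snp"]].astype(str).to_numpy(dtype=object),
        df[cols["beta_exp"]].to_numpy(dtype=float),
        df[cols["se_exp"]].to_numpy(dtype=float),
        df[cols["beta_out"]].to_numpy(dtype=float),
        df[cols["se_out"]].to_numpy(dtype=float),
        **kw,
    )


def write_summary_table(ds: SummaryDataset, path: str | Path) -> None:
    """Write the dataset in the default dialect (tab-separated, header row)."""
    ds.to_frame().to_csv(path, sep="\t", index=False)
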