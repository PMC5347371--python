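"""Reading, validating and writing GWAS summary-statistic tables.

Input is a delimited text table with one row per SNP: an identifier column
and one p-value column per phenotype.  p-values are clamped away from 0/1
and probit-transformed to scores y = Phi^-1(1 - p), on which the mixture
model operates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStatMatrix",
    "read_summary_stats",
    "probit_transform",
    "write_table",
    "DEFAULT_EPS",
]

DEFAULT_EPS = 1e-12


def probit_transform(p):
    """Probit score y = Phi^-1(1 - p), strictly decreasing in p on (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p-values must lie strictly inside (0, 1)")
    out = -ndtri(p)  # Phi^-1(1-p) = -Phi^-1(p)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class SummaryStatMatrix:
    """T x n p-value matrix with SNP identifiers, phenotype names and scores.

    ``y`` is the probit-transformed score matrix; ``truth`` optionally
    carries a known ground-truth association field (simulation only).
    """

    snp_ids: list[str]
    phenotypes: list[str]
    pvals: np.ndarray
    y: np.ndarray = field(default=None)  # type: ignore[assignment]
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pvals = np.asarray(self.pvals, dtype=float)
        T, n = self.pvals.shape
        if T < 1:
            raise ValueError("need at least one SNP")
        if n < 2:
            raise ValueError("need at least two phenotypes")
        if len(self.snp_ids) != T or len(set(self.snp_ids)) != T:
            raise ValueError("snp_ids must be unique and match the row count")
        if len(self.phenotypes) != n or len(set(self.phenotypes)) != n:
            raise ValueError("phenotype names must be unique and match the column count")
        if not np.isfinite(self.pvals).all():
            raise ValueError("p-values must be finite with no missing entries")
        if np.any(self.pvals <= 0) or np.any(self.pvals >= 1):
            raise ValueError("p-values must lie in (0, 1) after clamping")
        if self.y is None:
            self.y = probit_transform(self.pvals)

    @classmethod
    def from_pvalues(cls, snp_ids, phenotypes, pvals, eps: float = DEFAULT_EPS,
                     truth=None) -> "SummaryStatMatrix":
        """Build from raw p-values in [0, 1], clamping into [eps, 1-eps]."""
        pvals = np.asarray(pvals, dtype=float)
        if np.any(pvals < 0) or np.any(pvals > 1):
            bad = np.argwhere((pvals < 0) | (pvals > 1))[0]
            raise ValueError(f"p-value outside [0, 1] at row {bad[0]}, column {bad[1]}")
        n_clamped = int(np.sum((pvals < eps) | (pvals > 1 - eps)))
        if n_clamped:
            logger.warning("clamped %d p-values into [%g, %g]", n_clamped, eps, 1 - eps)
        pvals = np.clip(pvals, eps, 1 - eps)
        return cls(list(snp_ids), list(phenotypes), pvals,
                   truth=None if truth is None else np.asarray(truth, dtype=np.int8))

    @property
    def T(self) -> int:
        return self.pvals.shape[0]

    @property
    def n(self) -> int:
        return self.pvals.shape[1]


def read_summary_stats(
    path,
    snp_col: str = "snp_id",
    phenotype_cols: list[str] | None = None,
    delimiter: str | None = None,
    eps: float = DEFAULT_EPS,
) -> SummaryStatMatrix:
    """Read a delimited p-value table into a validated :class:`SummaryStatMatrix`.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    snp_col
        Name of the SNP-identifier column.
    phenotype_cols
        p-value columns to use; default: every column except ``snp_col``.
    delimiter
        Field separator; auto-detected (tab or comma) when None.
    eps
        Clamping bound for p-values of exactly 0 or 1.

    Rows with missing or unparseable p-values are dropped with a logged
    count; a p-value outside [0, 1] is an error naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        header = path.open().readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=delimiter, dtype={0: str}, float_precision="round_trip")
    if snp_col not in df.columns:
        raise KeyError(f"SNP identifier column {snp_col!r} not found in {path.name}")
    if phenotype_cols is None:
        phenotype_cols = [c for c in df.columns if c != snp_col]
    missing = [c for c in phenotype_cols if c not in df.columns]
    if missing:
        raise KeyError(f"phenotype columns not found: {missing}")
    if len(phenotype_cols) < 2:
        raise ValueError("need at least two phenotype columns")

    raw = df[phenotype_cols]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    # a column that is entirely unparseable is a schema problem, not missing data
    for c in phenotype_cols:
        if numeric[c].isna().all() and not raw[c].isna().all():
            raise ValueError(f"phenotype column {c!r} is not numeric")
    keep = numeric.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d rows with missing/unparseable p-values", n_dropped)
    pvals = numeric.loc[keep].to_numpy(dtype=float)
    if pvals.shape[0] == 0:
        raise ValueError("no complete rows left after filtering")
    bad = np.argwhere((pvals < 0) | (pvals > 1))
    if bad.size:
        t, i = bad[0]
        snp = df.loc[keep, snp_col].iloc[t]
        raise ValueError(
            f"p-value outside [0, 1] for SNP {snp!r}, column {phenotype_cols[i]!r}"
        )
    snp_ids = df.loc[keep, snp_col].astype(str).tolist()
    return SummaryStatMatrix.from_pvalues(snp_ids, list(phenotype_cols), pvals, eps=eps)


def write_table(records: pd.DataFrame, path, delimiter: str = "\t",
                float_format: str | None = "%.6g") -> None:
    """Write a result table as delimited text.

    Result tables default to 6 significant digits; pass
    ``float_format=None`` for full-precision output (exact round-trips).
    """
    if list(records.columns) == []:
        raise ValueError("records must have a header schema")
    records.to_csv(path, sep=delimiter, index=False, float_format=float_format)
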