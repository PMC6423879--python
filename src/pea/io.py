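"""Loading expression data, gene sets; normalization and FDR control.

Expression matrices are genes x samples TSV/CSV with a header row of sample
ids and gene ids in the first column; phenotype and covariate tables are
indexed by sample id.  Samples with any missing value are dropped at load
time (with a logged count), matching a complete-case analysis.  Before
testing, expression is min-max normalized per gene to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .errors import InputError

__all__ = ["ExpressionData", "load_expression", "load_gene_set", "minmax_normalize", "bh_fdr"]

logger = logging.getLogger("pea")


@dataclass
class ExpressionData:
    """Aligned expression matrix (genes x samples), binary phenotype and
    optional per-sample covariates."""

    matrix: pd.DataFrame
    phenotype: pd.Series
    covariates: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


def _read_table(path, **kw) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0, **kw)


def load_expression(path, phenotype_path, covariate_path=None) -> ExpressionData:
    """Load and align expression, phenotype and covariates by sample id.

    Samples absent from any table or carrying missing values are dropped
    (logged); duplicated gene ids or an empty sample overlap are input
    errors.
    """
    mat = _read_table(path)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    dup = mat.index[mat.index.duplicated()].unique().tolist()
    if dup:
        raise InputError(f"duplicated gene id(s) in expression matrix: {dup}")

    pheno_tab = _read_table(phenotype_path)
    pheno_tab.index = pheno_tab.index.astype(str)
    pheno = pheno_tab.iloc[:, 0]
    cov = None
    if covariate_path is not None:
        cov = _read_table(covariate_path)
        cov.index = cov.index.astype(str)

    samples = [s for s in mat.columns if s in pheno.index]
    if cov is not None:
        samples = [s for s in samples if s in cov.index]
    if not samples:
        raise InputError(
            "no overlapping sample ids between expression matrix and "
            f"phenotype/covariate tables (matrix samples: {list(mat.columns)[:5]}...)"
        )
    n_unmatched = mat.shape[1] - len(samples)

    keep = []
    for s in samples:
        if mat[s].isna().any() or pd.isna(pheno.loc[s]):
            continue
        if cov is not None and cov.loc[s].isna().any():
            continue
        keep.append(s)
    n_dropped = len(samples) - len(keep)
    if n_unmatched or n_dropped:
        logger.warning(
            "load_expression: dropped %d unmatched and %d incomplete sample(s); %d retained",
            n_unmatched, n_dropped, len(keep),
        )
    if not keep:
        raise InputError("no complete samples after missing-data filtering")

    mat = mat[keep].astype(float)
    pheno = pheno.loc[keep]
    vals = set(pd.unique(pheno))
    if not vals <= {0, 1, 0.0, 1.0}:
        raise InputError(f"phenotype must be coded 0/1, found values {sorted(vals)}")
    pheno = pheno.astype(int)
    if cov is not None:
        cov = cov.loc[keep]
    return ExpressionData(matrix=mat, phenotype=pheno, covariates=cov)


def load_gene_set(gmt_path, set_name: str | None = None) -> list[str]:
    """Members of one gene set from a GMT file (name, description, members),
    order-preserving and de-duplicated."""
    sets: dict[str, list[str]] = {}
    with open(gmt_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            members = [g for g in parts[2:] if g]
            sets[parts[0]] = list(dict.fromkeys(members))
    if not sets:
        raise InputError(f"no gene sets found in {gmt_path}")
    if set_name is None:
        if len(sets) != 1:
            raise InputError(
                f"GMT contains {len(sets)} sets; specify one of {sorted(sets)}"
            )
        set_name = next(iter(sets))
    if set_name not in sets:
        raise InputError(f"gene set {set_name!r} not in {gmt_path}; available: {sorted(sets)}")
    members = sets[set_name]
    if not members:
        raise InputError(f"gene set {set_name!r} is empty")
    return members


def minmax_normalize(data: ExpressionData | pd.DataFrame, genes=None) -> pd.DataFrame:
    """Per-gene (x - min) / (max - min) across samples, mapping each selected
    gene's expression into [0, 1].  A constant gene carries no contrast and
    is mapped to 0.5 everywhere (logged)."""
    mat = data.matrix if isinstance(data, ExpressionData) else data
    if genes is not None:
        missing = [g for g in genes if g not in mat.index]
        if missing:
            raise InputError(f"gene(s) not in expression matrix: {missing}")
        mat = mat.loc[list(genes)]
    vals = mat.to_numpy(dtype=float)
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    if flat.any():
        logger.warning("minmax_normalize: %d constant gene(s) mapped to 0.5", int(flat.sum()))
    span[span == 0] = 1.0
    out = (vals - lo) / span
    out[flat, :] = 0.5
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


def bh_fdr(p_values) -> NDArray:
    """Benjamini-Hochberg step-up q-values (monotone), original order."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise InputError("P values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
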