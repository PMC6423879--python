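"""Screen a list of candidate external genes against one pathway.

One permutation score test per external gene; P values across the screen
are adjusted by Benjamini-Hochberg FDR.  Per-gene permutation seeds are
spawned deterministically from the master seed and the gene's position in
the candidate list, so a screen is byte-reproducible and safe to shard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, NumericalError
from .io import ExpressionData, bh_fdr, minmax_normalize
from .kernel import pathway_kernel
from .pql import FitControl, fit_null_model
from .score import permutation_test

__all__ = ["ScreenConfig", "run_screen"]

logger = logging.getLogger("pea")


@dataclass
class ScreenConfig:
    n_perm: int = 1000
    seed: int = 0
    # kernel-only null by default: with permutation-without-refitting, a null
    # design containing G residualises only the observed statistic against G
    # and the test loses calibration and power (see api module).
    include_gene_main: bool = False
    tail: str = "upper"
    alpha: float = 0.05


def _child_seed(master: int, index: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _design(data: ExpressionData) -> np.ndarray:
    N = data.n_samples
    X = np.ones((N, 1))
    if data.covariates is not None and data.covariates.shape[1] > 0:
        enc = pd.get_dummies(data.covariates, drop_first=True, dtype=float)
        X = np.column_stack([X, enc.to_numpy(dtype=float)])
    return X


def run_screen(
    data: ExpressionData,
    pathway_genes: list[str],
    external_genes: list[str],
    config: ScreenConfig | None = None,
    control: FitControl | None = None,
) -> pd.DataFrame:
    """Test each external gene against the pathway; returns a table with
    columns gene_id, U, p_value, fdr_q, n_perm, flag, sorted by P value
    (stable).  External genes that are pathway members or absent from the
    matrix are skipped with a flag; per-gene failures are flagged and the
    screen continues."""
    config = config or ScreenConfig()
    if not external_genes:
        logger.warning("run_screen: empty external gene list")
        return pd.DataFrame(columns=["gene_id", "U", "p_value", "fdr_q", "n_perm", "flag"])

    present = [g for g in pathway_genes if g in data.matrix.index]
    absent = [g for g in pathway_genes if g not in data.matrix.index]
    if absent:
        logger.warning("run_screen: %d pathway gene(s) missing from matrix: %s",
                       len(absent), absent[:10])
    if not present:
        raise InputError("no pathway genes present in the expression matrix")

    norm_path = minmax_normalize(data, present)
    P = norm_path.to_numpy(dtype=float).T  # samples x v
    y = data.phenotype.to_numpy(dtype=float)
    X = _design(data)
    K0 = pathway_kernel(P)
    pathway_set = set(pathway_genes)

    shared_fit = None
    if not config.include_gene_main:
        shared_fit = fit_null_model(y, X, K0, control)

    testable = [g for g in external_genes
                if g not in pathway_set and g in data.matrix.index]
    norm_ext = minmax_normalize(data, testable) if testable else None

    rows = []
    for idx, gid in enumerate(external_genes):
        row = dict(gene_id=gid, U=np.nan, p_value=np.nan, fdr_q=np.nan,
                   n_perm=config.n_perm, flag="ok")
        if gid in pathway_set:
            row["flag"] = "pathway_member"
        elif gid not in data.matrix.index:
            row["flag"] = "missing_from_matrix"
        else:
            G = norm_ext.loc[gid].to_numpy(dtype=float)
            try:
                if config.include_gene_main:
                    fit = fit_null_model(y, np.column_stack([X, G]), K0, control)
                else:
                    fit = shared_fit
                res = permutation_test(
                    fit, G, P, n_perm=config.n_perm,
                    seed=_child_seed(config.seed, idx), tail=config.tail,
                )
                row["U"] = res.U_obs
                row["p_value"] = res.p_value
                if not fit.converged:
                    row["flag"] = "fit_not_converged"
            except (NumericalError, InputError) as exc:
                row["flag"] = f"error:{exc}"
        rows.append(row)

    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    if ok.any():
        out.loc[ok, "fdr_q"] = bh_fdr(out.loc[ok, "p_value"].to_numpy())
    return out.sort_values("p_value", kind="stable", na_position="last").reset_index(drop=True)
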