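"""High-level one-call interface: fit the null model and run the permutation test."""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray

from .kernel import pathway_kernel
from .pql import FitControl, NullModelFit, fit_null_model
from .score import TestResult, permutation_test

__all__ = ["test_gene_pathway_interaction"]


def test_gene_pathway_interaction(
    y: NDArray,
    G: NDArray,
    P: NDArray,
    X: NDArray | None = None,
    include_gene_main: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "upper",
    control: FitControl | None = None,
) -> tuple[NullModelFit, TestResult]:
    """Test one external gene against one pathway.

    Builds the null design (intercept plus optional covariates ``X``), fits
    the null kernel-machine model with K0 = 1*1' + PP', and returns the fit
    together with the permutation test result.

    ``include_gene_main`` appends the gene's main effect to the null design.
    The default leaves it out (kernel-only null): because permutations
    re-evaluate the statistic without re-fitting, a null fit that depends on
    G residualises the *observed* statistic against G but not the permuted
    ones, which biases the test conservative and costs nearly all power.
    The adjusted variant is retained for sensitivity analyses only.
    """
    y = np.asarray(y, dtype=float).ravel()
    G = np.asarray(G, dtype=float).ravel()
    N = y.shape[0]
    design = np.ones((N, 1)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    if include_gene_main:
        design = np.column_stack([design, G])
    K0 = pathway_kernel(P)
    fit = fit_null_model(y, design, K0, control)
    result = permutation_test(fit, G, P, n_perm=n_perm, seed=seed, tail=tail)
    return fit, result
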