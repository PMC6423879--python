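"""Likelihood-ratio comparator: parametric logistic test of all v interaction terms.

Full model regresses the binary phenotype on [X | P | G | P∘G] (every
pathway gene, the external gene, and all v elementwise gene-by-pathway
products); the reduced model drops the products.  chi2 = 2(l_full - l_red)
is referred to a chi-square with v degrees of freedom.  With v approaching
N/3 the ML fit becomes unstable (separation, flat likelihood); the fit is
still attempted and instability is surfaced via the `unreliable` flag so
that simulation studies exhibit the LRT's miscalibration rather than mask it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import stats
import statsmodels.api as sm

from .errors import InputError

__all__ = ["LRTResult", "lrt_interaction"]


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float
    unreliable: bool = False
    flags: list[str] = field(default_factory=list)


def _fit_logit(y: NDArray, M: NDArray) -> tuple[float, bool, list[str]]:
    """ML logistic fit returning (llf, converged, flags); Newton first,
    L-BFGS fallback on separation or failure."""
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, M).fit(method="newton", maxiter=100, disp=0)
            conv = bool(res.mle_retvals.get("converged", False))
            if conv and np.isfinite(res.llf):
                return float(res.llf), True, flags
            flags.append("newton_not_converged")
        except Exception:
            flags.append("newton_failed")
        try:
            res = sm.Logit(y, M).fit(method="lbfgs", maxiter=2000, disp=0)
            conv = bool(res.mle_retvals.get("converged", False))
            if not conv:
                flags.append("lbfgs_not_converged")
            llf = float(res.llf) if np.isfinite(res.llf) else -np.inf
            return llf, conv, flags
        except Exception:
            flags.append("lbfgs_failed")
            return -np.inf, False, flags


def lrt_interaction(
    y: NDArray, X: NDArray, P: NDArray, G: NDArray
) -> LRTResult:
    """LRT of H0: no gene-by-pathway interaction in the parametric model."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    P = np.asarray(P, dtype=float)
    G = np.asarray(G, dtype=float).ravel()
    N = y.shape[0]
    if X.shape[0] != N or P.shape[0] != N or G.shape[0] != N:
        raise InputError("inconsistent sample dimensions in LRT inputs")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise InputError("phenotype must be binary 0/1")
    if y.min() == y.max():
        raise InputError("phenotype has a single class")

    v = P.shape[1]
    reduced = np.column_stack([X, P, G])
    if v == 0:
        return LRTResult(chi2=0.0, df=0, p=1.0)
    full = np.column_stack([reduced, P * G[:, None]])

    llf_red, conv_red, flags_red = _fit_logit(y, reduced)
    llf_full, conv_full, flags_full = _fit_logit(y, full)
    flags = [f"reduced:{f}" for f in flags_red] + [f"full:{f}" for f in flags_full]

    chi2 = 2.0 * (llf_full - llf_red)
    unreliable = not (conv_red and conv_full)
    if not np.isfinite(chi2):
        chi2 = np.nan
        unreliable = True
        flags.append("nonfinite_chi2")
    elif chi2 < -1e-6:
        unreliable = True
        flags.append("negative_chi2")
    p = float(stats.chi2.sf(max(chi2, 0.0), v)) if np.isfinite(chi2) else np.nan
    return LRTResult(chi2=float(chi2), df=v, p=p, unreliable=unreliable, flags=flags)
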