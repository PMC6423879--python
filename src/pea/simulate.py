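"""Synthetic-data generator and simulation experiments (type I error, AUC).

Study conditions
----------------
Pathway expression for N individuals and v genes is drawn from a Gaussian
copula with exchangeable correlation c and uniform(0,1) margins; the
external gene is i.i.d. uniform(0,1).  The linear predictor is built from a
function g of the expression values,

    g_i = 1 + beta_P * sum_j P_ij + beta_G * G_i + xi_G * G_i * sum_{j in S} P_ij

with odds-ratio parameterisation beta_P = log(1.2), beta_G = log(s) and
xi_G = log(exp(s)/2) = s - log 2 for signal strength s > 0 (s = 0 is the
null: no gene main effect and no interaction).  S is the first
ceil(p_interact * v) pathway genes.  The predictor h is g (linear setting)
or g**2 (nonlinear), and y_i ~ Bernoulli(expit(h_i - median(h))): centering
at the median keeps cases and controls near 1:1 for both h forms, matching
a case-control design.

Experiments
-----------
``run_type1_experiment`` simulates null datasets (s = 0) and records the
permutation-score-test and LRT P values; the type-I-error rate is the
fraction at or below the nominal level.  ``run_auc_experiment`` simulates
alternative datasets (s > 0) and combines their P values with a companion
null run's (at full scale, 900 subsampled null + 100 alternative) into a
rank (Mann-Whitney) AUC with score 1 - p.  Defaults are desk scale
(500 null / 100 alternative replicates, 1000 permutations); the full-scale
study (1000 / 100 / 50000) is available through the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.special import expit, ndtr
from sklearn.metrics import roc_auc_score

from .errors import InputError, NumericalError
from .kernel import pathway_kernel
from .lrt import lrt_interaction
from .pql import FitControl, fit_null_model
from .score import permutation_test

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "SimulationResult",
    "simulate_pathway",
    "simulate_gene",
    "linear_predictor_g",
    "simulate_phenotype",
    "simulate_dataset",
    "run_type1_experiment",
    "run_auc_experiment",
    "run_grid",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """One grid point of the simulation study.

    s is the odds-ratio signal of the external gene (0 = null); the
    interaction odds ratio is exp(s)/2 and the per-gene pathway odds ratio
    is ``or_pathway``.  ``include_gene_main`` controls whether the gene's
    main effect enters the null design of the score test; the default False
    is the kernel-only null under which permuting the gene leaves the fit
    untouched.
    """

    N: int = 100
    v: int = 10
    c: float = 0.0
    p_interact: float = 1.0
    s: float = 0.0
    or_pathway: float = 1.2
    h_form: str = "linear"
    n_null_reps: int = 500
    n_alt_reps: int = 100
    n_perm: int = 1000
    alpha_level: float = 0.05
    seed: int = 0
    center: str = "median"
    include_gene_main: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.c < 1):
            raise InputError("pathway correlation c must be in [0, 1)")
        if not (0 < self.p_interact <= 1):
            raise InputError("p_interact must be in (0, 1]")
        if self.h_form not in ("linear", "nonlinear"):
            raise InputError(f"unknown h_form {self.h_form!r}")
        if self.center not in ("median", "none"):
            raise InputError(f"unknown center {self.center!r}")

    @property
    def beta_P(self) -> float:
        return math.log(self.or_pathway)

    @property
    def beta_G(self) -> float:
        return math.log(self.s) if self.s > 0 else 0.0

    @property
    def xi_G(self) -> float:
        # interaction odds ratio exp(s)/2
        return self.s - math.log(2.0) if self.s > 0 else 0.0


@dataclass
class SimulatedDataset:
    P: NDArray
    G: NDArray
    y: NDArray
    g: NDArray
    h: NDArray
    config: SimulationConfig


@dataclass
class SimulationResult:
    method: str
    type1_rate: float | None
    auc: float | None
    n_reps_used: int
    n_failed: int
    p_values: NDArray = field(repr=False, default=None)

    def rejection_rate(self, alpha: float) -> float:
        p = self.p_values[np.isfinite(self.p_values)]
        return float(np.mean(p <= alpha)) if p.size else float("nan")


def simulate_pathway(N: int, v: int, c: float, seed=0) -> NDArray:
    """N x v pathway expression from a Gaussian copula with exchangeable
    correlation c and uniform(0,1) margins."""
    if not (0 <= c < 1):
        raise InputError("c must be in [0, 1): the exchangeable correlation "
                         "matrix loses positive definiteness at c >= 1 for v > 1")
    if N < 1 or v < 1:
        raise InputError("N and v must be >= 1")
    rng = _rng(seed)
    z = rng.standard_normal((N, v))
    if c > 0:
        shared = rng.standard_normal((N, 1))
        z = math.sqrt(c) * shared + math.sqrt(1.0 - c) * z
    return ndtr(z)


def simulate_gene(N: int, seed=0) -> NDArray:
    """External-gene expression: N i.i.d. uniform(0,1) draws."""
    if N < 1:
        raise InputError("N must be >= 1")
    return _rng(seed).random(N)


def linear_predictor_g(
    P: NDArray, G: NDArray, config: SimulationConfig
) -> tuple[NDArray, NDArray]:
    """The generating function g and the predictor h (g or g**2)."""
    P = np.asarray(P, dtype=float)
    G = np.asarray(G, dtype=float).ravel()
    v = P.shape[1]
    k = math.ceil(config.p_interact * v)
    g = (
        1.0
        + config.beta_P * P.sum(axis=1)
        + config.beta_G * G
        + config.xi_G * G * P[:, :k].sum(axis=1)
    )
    h = g if config.h_form == "linear" else g**2
    return g, h


def simulate_phenotype(h: NDArray, seed=0, center: str = "median") -> NDArray:
    """y_i ~ Bernoulli(expit(h_i - center)); median-centering keeps the
    case:control ratio near 1:1 regardless of the h form.  Redraws a
    degenerate single-class outcome up to 10 times."""
    h = np.asarray(h, dtype=float).ravel()
    if not np.all(np.isfinite(h)):
        raise InputError("non-finite linear predictor")
    mu = np.median(h) if center == "median" else 0.0
    prob = expit(h - mu)
    rng = _rng(seed)
    for _ in range(10):
        y = (rng.random(h.shape[0]) < prob).astype(int)
        if 0 < y.sum() < y.shape[0]:
            return y
    raise NumericalError("degenerate phenotype: single class in 10 consecutive draws")


def simulate_dataset(config: SimulationConfig, seed=0) -> SimulatedDataset:
    """One complete dataset (pathway, gene, phenotype) from a single stream."""
    rng = _rng(seed)
    P = simulate_pathway(config.N, config.v, config.c, rng)
    G = simulate_gene(config.N, rng)
    g, h = linear_predictor_g(P, G, config)
    y = simulate_phenotype(h, rng, config.center)
    return SimulatedDataset(P=P, G=G, y=y, g=g, h=h, config=config)


def _pea_pvalue(ds: SimulatedDataset, n_perm: int, perm_seed: int,
                include_gene_main: bool, control: FitControl | None) -> float:
    N = ds.y.shape[0]
    X = np.ones((N, 1))
    if include_gene_main:
        X = np.column_stack([X, ds.G])
    fit = fit_null_model(ds.y, X, pathway_kernel(ds.P), control)
    return permutation_test(fit, ds.G, ds.P, n_perm=n_perm, seed=perm_seed).p_value


def _replicate_pvalues(
    config: SimulationConfig,
    n_reps: int,
    seed_seq: np.random.SeedSequence,
    methods: tuple[str, ...],
    control: FitControl | None,
) -> dict[str, NDArray]:
    out = {m: np.full(n_reps, np.nan) for m in methods}
    children = seed_seq.spawn(n_reps)
    for i, child in enumerate(children):
        sim_seed, perm_seed = (int(x) for x in child.generate_state(2) % (2**31))
        try:
            ds = simulate_dataset(config, sim_seed)
        except NumericalError:
            continue
        if "PEA" in methods:
            try:
                out["PEA"][i] = _pea_pvalue(
                    ds, config.n_perm, perm_seed, config.include_gene_main, control
                )
            except (NumericalError, InputError):
                pass
        if "LRT" in methods:
            try:
                out["LRT"][i] = lrt_interaction(ds.y, np.ones((config.N, 1)), ds.P, ds.G).p
            except (NumericalError, InputError):
                pass
    return out


def run_type1_experiment(
    config: SimulationConfig,
    methods: tuple[str, ...] = ("PEA", "LRT"),
    control: FitControl | None = None,
) -> dict[str, SimulationResult]:
    """Type-I-error study at the null (s = 0): per-method empirical
    rejection rate at config.alpha_level over n_null_reps datasets."""
    if config.s != 0:
        raise InputError("type I error experiment requires the null configuration s = 0")
    ss = np.random.SeedSequence(config.seed, spawn_key=(0,))
    pvals = _replicate_pvalues(config, config.n_null_reps, ss, methods, control)
    results = {}
    for m in methods:
        p = pvals[m]
        ok = np.isfinite(p)
        results[m] = SimulationResult(
            method=m,
            type1_rate=float(np.mean(p[ok] <= config.alpha_level)) if ok.any() else float("nan"),
            auc=None,
            n_reps_used=int(ok.sum()),
            n_failed=int((~ok).sum()),
            p_values=p,
        )
    return results


def run_auc_experiment(
    config: SimulationConfig,
    null_p_values: dict[str, NDArray],
    methods: tuple[str, ...] = ("PEA", "LRT"),
    max_null: int = 900,
    control: FitControl | None = None,
) -> dict[str, SimulationResult]:
    """AUC study at an alternative (s > 0), discriminating alternative from
    null P values with score 1 - p.  ``null_p_values`` is the companion null
    run's per-method P values (``run_type1_experiment(...)[m].p_values``);
    when more than ``max_null`` are available, that many are subsampled, per
    the 900-null + 100-alternative design."""
    if config.s <= 0:
        raise InputError("AUC experiment requires an alternative configuration s > 0")
    for m in methods:
        if m not in null_p_values:
            raise InputError(f"missing companion null P values for method {m!r}")
    ss = np.random.SeedSequence(config.seed, spawn_key=(1,))
    alt = _replicate_pvalues(config, config.n_alt_reps, ss, methods, control)
    results = {}
    sub_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    for m in methods:
        p_alt = alt[m][np.isfinite(alt[m])]
        p_null = np.asarray(null_p_values[m], dtype=float)
        p_null = p_null[np.isfinite(p_null)]
        if p_null.size == 0 or p_alt.size == 0:
            results[m] = SimulationResult(m, None, float("nan"), 0, config.n_alt_reps, alt[m])
            continue
        if p_null.size > max_null:
            p_null = sub_rng.choice(p_null, size=max_null, replace=False)
        labels = np.r_[np.zeros(p_null.size), np.ones(p_alt.size)]
        scores = 1.0 - np.r_[p_null, p_alt]
        auc = float(roc_auc_score(labels, scores))
        results[m] = SimulationResult(
            method=m,
            type1_rate=None,
            auc=auc,
            n_reps_used=int(p_alt.size),
            n_failed=int(config.n_alt_reps - p_alt.size),
            p_values=alt[m],
        )
    return results


def run_grid(
    base: SimulationConfig,
    N: tuple[int, ...] = (100,),
    v: tuple[int, ...] = (10,),
    c: tuple[float, ...] = (0.0,),
    p_interact: tuple[float, ...] = (1.0,),
    s: tuple[float, ...] = (0.0,),
    h_form: tuple[str, ...] = ("linear",),
    methods: tuple[str, ...] = ("PEA", "LRT"),
) -> pd.DataFrame:
    """Run a grid of settings; one row per grid point x method.

    Null points (s = 0) report the type-I-error rate; alternative points
    report the AUC against the matching null point's P values (the null
    point is run automatically for each (N, v, c, h_form) group).
    """
    rows = []
    for Ni in N:
        for vi in v:
            for ci in c:
                for hf in h_form:
                    null_cfg = replace(base, N=Ni, v=vi, c=ci, s=0.0, h_form=hf)
                    null_res = run_type1_experiment(null_cfg, methods=methods)
                    for m in methods:
                        r = null_res[m]
                        rows.append(dict(N=Ni, v=vi, c=ci, p_interact=np.nan, s=0.0,
                                         h_form=hf, method=m, metric="type1_rate",
                                         value=r.type1_rate, n_reps=r.n_reps_used,
                                         n_failed=r.n_failed, seed=base.seed))
                    for pi in p_interact:
                        for si in s:
                            if si == 0:
                                continue
                            alt_cfg = replace(base, N=Ni, v=vi, c=ci, s=si,
                                              p_interact=pi, h_form=hf)
                            alt_res = run_auc_experiment(
                                alt_cfg,
                                {m: null_res[m].p_values for m in methods},
                                methods=methods,
                            )
                            for m in methods:
                                r = alt_res[m]
                                rows.append(dict(N=Ni, v=vi, c=ci, p_interact=pi,
                                                 s=si, h_form=hf, method=m,
                                                 metric="auc", value=r.auc,
                                                 n_reps=r.n_reps_used,
                                                 n_failed=r.n_failed, seed=base.seed))
    return pd.DataFrame(rows)
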