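# Methods

## The model

We test whether one *external* gene's expression interacts with a functional
pathway in shaping a binary phenotype (case/control).  The parametric form of
this gene–pathway interaction (GPI) model is a logistic regression

logit P(y_i = 1) = X_i β_C + Σ_j P_ij β_Pj + G_i β_G + Σ_j (P_ij · G_i) ξ_Gj,

with covariates X (intercept, and e.g. age/sex in real data), pathway
expression P (N × v), and external-gene expression G.  Testing the v
interaction coefficients ξ_G jointly by a likelihood-ratio test (the
comparator implemented in `pea.lrt`) costs v degrees of freedom and becomes
unstable when v is an appreciable fraction of N.

The kernel-machine formulation collapses those v parameters into one.  All
gene effects are absorbed into a smooth function h modelled as a Gaussian
random effect, h ~ N(0, τ·K(δ)), with the garrote kernel

K(δ)_{kl} = (1 + δ G_k G_l)(1 + ⟨P_k, P_l⟩).

The scalar garrote parameter δ carries the entire contribution of the
external gene, so the interaction null hypothesis is H₀: δ = 0, and the null
model is the kernel machine with K(0) = 1·1ᵀ + PPᵀ — a pathway-only model.
Expression is min-max normalized per gene to [0, 1] before entering the
kernel, so kernel entries are bounded and δ is comparable across genes.

## Null-model fitting (PQL + REML)

`pea.pql.fit_null_model` fits logit P(y=1) = Xβ_C + h, h = K0·α, by
penalized quasi-likelihood.  Each outer iteration performs:

1. **Coefficient step.**  With γ = expit(Xβ + K0α), D = diag(γ(1−γ)) and
   working response ỹ = η + D⁻¹(y − γ), solve the mixed-model normal
   equations

       [ XᵀDX     XᵀDK0     ] [β]   [XᵀDỹ]
       [ DX    τ⁻¹I + DK0   ] [α] = [ Dỹ ]

   by Schur-complement elimination of the α block (an explicitly assembled
   dense solve is kept as a test oracle).  This is the classical
   working-linear-model step: β equals the GLS estimate under
   V = D⁻¹ + τK0 and h = τK0V⁻¹(ỹ − Xβ).

2. **Variance-component step.**  τ is updated by damped Fisher scoring on
   the restricted likelihood of the Gaussian working model,
   L_REML(τ) = −½(log|V| + log|XᵀV⁻¹X| + rᵀV⁻¹r) with r the GLS residual.
   The step is ω^t · [rᵀV⁻¹K0V⁻¹r − tr(QK0)] / [tr(QK0QK0)/2], with
   Q = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹, ω = 0.5 and t the outer iteration
   index, taken in the direction that increases L_REML and halved until the
   restricted likelihood does not decrease; the result is floored at
   τ ≥ 1e-8 (`tau_floor`) to keep V invertible.  Note the REML adjustment
   uses log|XᵀV⁻¹X|; one sometimes sees the |XᵀVX| variant printed in this
   literature, which we regard as a typo — only the V⁻¹ form makes the
   update a likelihood ascent.

Convergence requires the sup-norm changes of β, of h = K0α, and of τ to fall
below 1e-5 (defaults `tol_beta`, `tol_tau`); the geometric damping ω^t makes
the τ sequence contract regardless, so the iteration cap of 50 is rarely
reached.  Under the null, τ̂ frequently lands on the floor — the REML
estimate of a variance component is 0 with positive probability — which is
harmless for the test below because τ rescales the observed and permuted
statistics identically.

Defaults (`FitControl`): tau_init = 0.1, tau_floor = 1e-8,
tol_beta = tol_tau = 1e-5, max_outer_iter = max_tau_iter = 50,
damping = 0.5, prob_clamp = 1e-6.  The probability clamp bounds fitted γ
away from 0/1 so that D⁻¹ stays finite on separation-prone small samples.

## The score test and its permutation null

The variance-component score statistic for δ at the null fit is

U = ½ rᵀ V⁻¹ (∂V/∂δ) V⁻¹ r,   ∂V/∂δ = τ·dK,   dK = (GGᵀ) ⊙ (1·1ᵀ + PPᵀ),

with r = ỹ − Xβ_C.  Writing r̃ = V⁻¹r and u = r̃ ⊙ G, the affine structure of
the garrote kernel collapses U to

U = (τ/2)·[(Σ_i u_i)² + ‖Pᵀu‖²],

an O(Nv) evaluation.  The null distribution of U is awkward analytically
(the relevant matrix need not be definite once residual signs enter), so the
P value is obtained by permutation: G is shuffled across individuals and U
re-evaluated **without re-fitting** β_C, α, τ — the null fit does not involve
G, so under H₀ (G independent of y and P) the observed and permuted
statistics are exchangeable and the test is exact up to Monte-Carlo error.
The add-one estimator p = (1 + #{U_b ≥ U_obs})/(B + 1) keeps p ≥ 1/(B+1).
Permutations are drawn in fixed-size vectorised blocks from a seeded
generator, so results are bit-reproducible; in a screen, per-gene seeds are
spawned from the master seed and the gene's list position.

**Why the null design excludes the gene's main effect by default.**  One
might append G as a fixed covariate to X so the score statistic targets the
interaction specifically.  Under this permutation scheme that is
self-defeating: the fitted GLS residual then satisfies Gᵀr̃ = 0, which
annihilates the (Σu)² component of the *observed* statistic while permuted
statistics keep it, so U_obs is stochastically dragged below its own
permutation null.  Empirically (see the screen tests) a strongly planted
interactor's median P value was ≈ 0.7 with G in the null design versus
≈ 0.005 without; the adjusted variant is therefore exposed only as a
sensitivity option (`include_gene_main=True`, `--gene-main-effect`), and the
default is the kernel-only null, under which the permutation argument is
exact.  Tests that want a main-effect-free interpretation should note that
with the kernel-only null, a pure main effect of G also contributes to U —
the alternative is "the phenotype is affected by the external gene and/or
its interactions with the pathway".

One-tailed rejection for large U is the default (`tail="upper"`): U is a
non-negative quadratic form whenever τ > 0 and inputs are non-negative, so
large positive values are the natural alternative direction; a two-sided
option on |U| is available.

## The LRT comparator

`lrt_interaction` fits the full and reduced parametric models by maximum
likelihood (Newton, with an L-BFGS fallback on separation or
non-convergence) and refers 2(ℓ_full − ℓ_reduced) to χ²_v.  In the v = 30,
N = 100 regime the fit is still attempted and instability is reported
through an `unreliable` flag and per-fit flags rather than by altering the
statistic — the simulation study is supposed to exhibit the LRT's
miscalibration, not mask it.  The reduced model keeps the G main effect, so
the LRT tests interactions only.

## Synthetic data

`simulate_pathway` draws P from a Gaussian copula with exchangeable
(compound-symmetric) correlation c and uniform margins: z_i = √c·w·1 +
√(1−c)·ε_i, mapped through the standard-normal CDF.  The Gaussian family is
the natural single-parameter reading of "a copula with correlation c"; its
pairwise Spearman correlation has the closed form (6/π)·asin(c/2), which
the tests verify.  `simulate_gene` draws G i.i.d. uniform(0,1).

The phenotype is Bernoulli with success probability expit(h − median(h)).
The median-centering is our choice where the generating intercept is
otherwise unconstrained: without it the nonlinear form h = g² pushes
prevalence towards 1 and null fits degenerate; centering keeps a ≈ 1:1
case:control ratio for both h forms (`center="none"` disables it).  The
interacting subset S is the first ⌈p_interact·v⌉ pathway genes — a fixed
prefix keeps runs reproducible.  s = 0 sets both β_G and ξ_G to zero (the
null is "no gene effect of any kind", not an odds ratio of literally 0).
Simulated designs are intercept-only: the simulation study involves no
additional covariates.

What the generator does *not* emulate about real RNA-seq: count noise and
library-size effects (expression enters already normalized to [0,1]),
gene-gene correlation structure beyond exchangeable, covariate confounding,
and case:control imbalance.  Passing simulations therefore certify the
statistical machinery under idealised sampling, not robustness to upstream
normalisation choices.

## Experiment scales

The full-scale study in this design uses 1000 null replicates, 100
alternative replicates and 50,000 permutations per dataset, with AUC
computed from 900 subsampled null + 100 alternative P values (score 1 − p,
rank/Mann–Whitney formula).  The package's defaults are a desk scale chosen
to keep a complete calibration run in minutes on one core: 500 null
replicates × 1000 permutations for type I error (exact-binomial 99% band
around 0.05 for 500 trials: [0.028, 0.078]), 200 null + 50 alternative
replicates × 500 permutations for AUC comparisons.  Both scales are plain
`SimulationConfig` settings; nothing in the code depends on the scale.

## Numerical choices and edge cases

- V and XᵀV⁻¹X are factorised by Cholesky; failure raises `NumericalError`
  (the working covariance must be PD — a larger `tau_floor` or a rank check
  on X is the usual remedy).
- A zero kernel gives zero REML gradient and information; the τ update
  treats this as stationary, and the fit then reproduces plain logistic
  regression.
- Constant genes min-max-normalize to 0.5 everywhere (flagged), carrying no
  signal rather than an error.
- External genes that are members of the tested pathway are skipped with a
  `pathway_member` flag in screens; testing a gene against a set containing
  itself conflates main effect and interaction.
- BH-FDR q-values are computed by the step-up construction with enforced
  monotonicity and cross-checked against statsmodels in the tests.
- Degenerate single-class phenotype draws in the simulator are redrawn up to
  10 times, then raised.

## Known limitations

- PQL is a first-order approximation; for rare phenotypes or tiny N the
  working-model REML τ̂ is biased (a known property of PQL), which the
  permutation calibration absorbs but parameter interpretation should not
  lean on.
- The score test with the kernel-only null does not separate the gene's
  main effect from its interactions; use the sensitivity option (and
  interpret its conservatism) or the LRT when that separation is essential.
- Permutation exchangeability assumes individuals are independent; related
  individuals or batch structure in G would require restricted permutations
  that are not implemented.
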