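# Methods

## The model

`qdgame` converts static, cross-sectional expression measurements of
interacting biological units into quasi-dynamic ODE (qdODE) systems.  The
trick that makes dynamics possible without time series is an
expression-derived ordering axis:

* **Niche index (NI)** — for one gene observed in two interacting cell
  types (e.g. fetal germ cells and their somatic niche) across n units
  (embryos), the NI of a unit is the sum of the gene's expression over the
  two types.  It measures the unit's overall capacity to express the gene.
* **Expression index (EI)** — for networks, a sample's EI is its total
  expression over all genes (gene networks), or a gene's EI is its total
  over all cells (cell-cell networks).

Units serialized by ascending index provide the grid on which a coupled ODE
is integrated.  Each node v (cell type, gene, module or cell) obeys

    dg_v/dN = q_v(N) + Σ_{u→v} q_{v←u}(g_u)

with an *independent* rate q_v — the derivative of an allometric power curve
α_v N^{β_v}, reflecting the part–whole scaling of a component with the total
— and one *dependent* rate per incoming edge, a Legendre polynomial series
(orders 1..r, default r = 3) in the source node's state mapped affinely onto
[−1, 1].  The constant Legendre term is excluded: a constant dependent rate
cannot be told apart from the independent power term.  Integrating each rate
term separately decomposes a node's fitted trajectory into an independent
curve P plus one dependent curve per edge; the decomposition is conservative
by construction (mean ≡ P + Σ dependent curves).  The sign of a dependent
curve says whether the source activates (+) or inhibits (−) the target, its
net value at the largest index is the edge's signed strength, and the
qualitative pattern of the two pairwise signs maps to an eleven-class
taxonomy (symmetric/asymmetric synergism, directional synergism either way,
altruism/exploitation, symmetric/asymmetric antagonism, directional
antagonism either way, coexistence), aggregated into five regulator
categories.

## Likelihood and estimation

The paired profile (y1, y2) of a gene across n units is modeled as a
2n-dimensional Gaussian.  The mean is the qdODE trajectory evaluated at the
observed index points (RK4 with sub-stepping, ≤ span/100 per step for the
reference path); the initial value at the smallest index point is the
observed value there, attributed entirely to the independent component.  The
covariance is a stationary bivariate AR(1): blocks σ_k² ρ_k^|i−i′| per type
and a cross block ρ12 σ1 σ2 (√(ρ1 ρ2))^|i−i′|.  The cross-decay choice
keeps the two-type structure a single-parameter family; when ρ1 ρ2 < 0 the
decay keeps the product's sign.

Parameters (α, β per node; both edge coefficient vectors; σ1, σ2, ρ1, ρ2,
ρ12) are estimated by maximum likelihood on an unconstrained transform
(log for scales, scaled atanh for correlations).  Two estimation details
matter and were found the hard way:

* **Bounded correlations.**  NI-indexed pairs have a near-deterministic
  residual sum (the index is the pair sum), which drives ρ12 toward −1
  where the covariance is singular and the likelihood unbounded.  The
  fitted correlations are therefore bounded (|ρ| ≤ 0.99, |ρ12| ≤ 0.95) and
  a soft quadratic barrier activates beyond |atanh| > 2; moment-based
  starting points are additionally shrunk until the covariance factorizes.
* **Alternating optimization.**  Plain Nelder–Mead in the full parameter
  space stalls: moving an edge coefficient requires compensating power-curve
  moves (a curved valley), and a serial-correlation basin absorbs smooth
  dependent signal before the coefficients can claim it.  The optimizer
  therefore alternates (i) Nelder–Mead over power/AR(1) parameters, (ii) a
  generalized-least-squares update of the edge coefficients given the
  current trajectories — the RK4 kernel accumulates per-basis-term integrals
  along the trajectory, making the mean locally linear in the coefficients —
  and (iii) a joint Nelder–Mead polish, from multiple starts including a
  "signal-first" start (ordinary-least-squares coefficients with AR(1)
  moments re-estimated from post-OLS residuals) and, for the full model, the
  null solution (which guarantees the nested-model likelihood ordering).
  The performance-critical pieces (RK4, covariance, Cholesky log-likelihood,
  the simplex loop) are numba-compiled and cross-checked in the test suite
  against dense scipy implementations.

## Interaction test

`LR = −2 log(L0 / L1)` compares the no-interaction (non-game) fit against
the full (game) fit.  The null distribution of LR is built by Monte-Carlo
resampling under the fitted no-interaction model: replicates redraw the
residual field around the null fit's mean curves using the *full* fit's
AR(1) parameters (the null fit's own scale and serial correlation absorb
any dependent signal, which would push the threshold to the signal scale;
with ρ near 1 the AR(1)-plus-power likelihood is also nearly flat in
constant offsets, making null fits unstable under the alternative).  Both
models are refit on each replicate, and significance uses the finite-sample
convention p = (1 + #{LR_rep ≥ LR_obs})/(n_rep + 1).  No explicit
degrees-of-freedom inflation is applied to the replicate scale: the exact
p-value convention plus full refitting absorb the MLE's small-sample scale
bias, and on repeated null-data batches an explicit correction made the
test measurably conservative.

A data-level reshuffle between the two cell types was implemented first and
abandoned for cause: the types have different mean curves, so label-swapped
(or cross-unit shuffled) datasets are far off-model and their LRs dominate
the observed one — the dependent component lives in curve shapes, not in the
pairing of observations, so no rearrangement of the data removes it.
Residual-level swaps fail more subtly (null-fit residuals retain the
dependent shape; full-fit residuals are over-smoothed).  Model-based
resampling is the design that is actually exchangeable in this setting.

Crucially, the observed statistic and every replicate are computed by the
*same* independent fitting protocol (same starts and iteration budgets, no
shared warm starts); a more thorough fit of the observed data supplies the
reported parameters and decomposition.  Two protocols are provided:
`default`, and `fast` for large Monte-Carlo studies (fewer starts and
iterations, coarser sub-stepping).  Both are symmetric, which is what
calibration requires; the fast protocol simply yields a noisier — but
identically distributed under the null — statistic.

## Networks

For m-node systems (genes, modules, cells) the system is fit *decoupled*:
each node conditions on its sources' observed series (linear interpolation).
The dependent component is then exactly linear in the Legendre coefficients,
so they and the residual scale profile out of an AR(1) Gaussian likelihood
in closed form and only (log α, β, atanh ρ) are searched numerically.
Candidate regulators are screened per node by cross-validated LASSO plus an
adaptive (reweighted) pass, applied to the per-source basis-integral columns
(grouped per source) against the node's power-detrended series, truncated to
`max_predictors`.  Edges carry the dependent curve, a sign (net area), a
weight (absolute net area) and a sign-change flag; outgoing hubness sums
|dependent area| / (target's independent area) over a node's out-edges.
Roles: out-degree > 0 with in-degree 0 is a primary hub, out and in > 0 a
secondary hub, out-degree 0 a subordinate.

Two deliberate deviations from the obvious design, both forced by
identifiability analysis:

* Sources are pinned to observations, not to fitted power curves.  A power
  smoother's mapped state depends only on the exponent, so all
  same-direction sources collapse onto essentially one regressor shape.
* Selection regresses on basis-integral columns, not raw candidate values —
  raw series all share the monotone allometric trend and LASSO then picks
  arbitrary smooth predictors (one third of the possible edges appeared on
  pure-noise networks).

**Known limitation — regulator identity.**  Even with those fixes, the
columns contributed by different smooth monotone sources span nearly
identical subspaces (canonical correlation ≈ 1 after projecting out the
power family).  An exhaustive best-subset BIC oracle tops out near F1 ≈
0.3–0.5 against simulated ground truth regardless of noise level, coupling
strength or generator design; the LASSO estimator matches that ceiling.  In
this model family the *existence* and *sign* of incoming dependent structure
is recoverable, and false edges on null data are rare (≲ 5%), but *which*
smooth source drives it is close to unidentifiable.  Conclusions about
specific regulator identities from such networks should be treated as
hypotheses, not findings.

Module-level networks collapse genes to unweighted module means per sample
(subpopulation weighting is unavailable in the processed-means setting) and
fit one network per stage × group stratum, skipping strata with fewer than
five samples.  Cell-cell networks transpose a genes × cells table, order
genes by their total expression, and reuse the same machinery byte for byte;
phase labels are annotations only.

## Functional clustering

Genes are grouped into modules by an EM-fitted mixture whose component means
are power curves of EI (one per group per module) with independent Gaussian
residuals — independence rather than the AR(1) used in qdODE likelihoods,
because clustering is a screening step.  Initialization: k-means on per-gene
log–log slope/intercept features; 5 restarts; convergence at |Δloglik| <
1e-6 within 200 iterations (non-convergence is reported and the best iterate
kept).  Model choice: AIC = −2 loglik + 2p with p = 2KG power parameters +
K variances + (K−1) mixing proportions.  The weighted power-curve M-step
fits the responsibility-weighted mean curve, which is the exact minimizer of
the weighted least-squares criterion.

## The synthetic-data generator

The generator defines the study conditions under which the method is
validated; the real study's parameter values were never published, so the
defaults were chosen once, for realism, and frozen:

* Pairwise: power pairs (0.25, 1.4) and (0.8, 0.7) — two visibly different
  allometric forms, as reported for the two cell types; NI span 2–12; edge
  coefficient shape [0.25, −0.5, 0.45] scaled by a signed strength (the
  higher-order content matters: a mostly-linear dependent rate integrates to
  a power-like curve that the independent term absorbs); residual sd
  0.05/0.06 with ρ = 0.3 and ρ12 = 0.2, emulating subpopulation means that
  average away most single-cell noise (the study's reduced-variance arm).
  Strength 3 in both directions is the "strong symmetric coupling"
  condition; sample sizes 15 and 50 are the study design.
* Index handling: the default mode treats the drawn NI grid as *given*
  (expression is generated at known index values and refit — the natural
  reading of a simulation that reuses estimated qdODE parameters), and the
  profile records that its index is not the pair sum.  A "consistent" mode
  instead relabels the index with the noise-free totals so NI ≡ g1+g2
  exactly; this is a monotone reparameterization of the latent axis.  The
  prescribed alternative — iterating grid ← totals(grid) to a fixed point —
  is unstable: exact convergence would force the total rate to be
  identically 1, and in practice the iteration collapses or diverges.
* Networks: nodes draw α, β from ranges that include decreasing curves
  (35% of nodes, as real modules decrease with EI in one cell type);
  exactly `regulators_per_node` incoming edges with random signs and
  jittered coefficient shapes; per-edge amplitude normalized to 25% of the
  target's power span times `coupling_scale`; AR(1) noise at 2% of each
  node's span.  The default "conditional" dynamics generate the table as
  the fixed point of the regression decomposition itself (each node = power
  curve + dependent integrals of its regulators' *observed* series +
  noise), the data-generating process the decoupled estimator formalizes; a
  "coupled" mode integrates the joint ODE instead.

What passing simulation-based tests do **not** show: robustness to
count-distributed single-cell noise (the model is Gaussian on processed
expression), to mis-assigned cell types, to unequal subpopulation sizes
behind the means, or to index construction from normalization-sensitive
totals.  And per the identifiability limitation above, edge-level recovery
statements are conditional on sources being distinguishable.

## Numerical choices

* RK4 sub-stepping ≤ span/100 (reference); Monte-Carlo protocols use
  span/40 or span/24 — fourth-order error is negligible at these scales
  for the smooth rates involved.
* Tied index values: stable sort, later duplicates jittered by 1e-9 of the
  span so the grid is strictly increasing.
* Units with zero total expression are dropped per gene (a power law with
  negative exponent is undefined at 0); all-zero samples keep EI 0 with a
  warning.
* Zeros during log–log initialization are offset by half the smallest
  positive value; the final power fit is on the original scale, so the
  estimate is offset-insensitive.
* Edge basis domain = observed source range (clamped during integration);
  degenerate ranges are padded.
* Nelder–Mead: ftol 1e-8 (reference), 2000 iterations, 5 starts; Monte-
  Carlo protocols are documented in `TEST_PROTOCOLS`.
* Study sizes in the acceptance suite (number of replicate datasets and
  resamples per study) are the package's chosen simulation scales for each
  experiment and are recorded in the scripts themselves.

## Open design calls

* Eq.-level ambiguity on whether the independent rate is a function of the
  index or of the node's own state: the index-derivative reading is
  implemented, making the power curve the exact no-interaction solution.
* Whether subpopulation means should be cell-count-weighted is unknowable
  from processed means; unweighted means are used.
* The sample-size cap on regulators (`max_predictors`) necessarily caps a
  node's regulators even though the conceptual constraint is on regulated
  genes; the selection direction follows the regression decomposition.
* The five-category gene screen requires the interaction test per gene; the
  neutrality call combines non-significance with a relative-magnitude
  threshold τ (default 0.05 of the independent range), since a fitted
  integral is never exactly zero.
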