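# Methods

## Model

Regional brain activity is modelled as a zero-field Ising system: each of
`N` regions carries a binary state `s_i = ±1` (active/inactive), and a
configuration `s` has energy

    H(s) = − Σ_{i<j} J_ij s_i s_j

with Boltzmann probability `Pr(s) = exp(−β H(s)) / Z`. This is the
pairwise maximum-entropy model (pMEM): the least-biased distribution over
binary states matching first- and second-order moments. The external-field
term is fixed at zero — resting-state series are z-scored, so no region has
a net activation bias by construction.

The package's central object is the *function-by-structure embedding*: the
couplings `J` are estimated from binarized activity under a penalty that
ties their magnitudes to a structural connectome `W` (`|J_ij| ≈ μ W_ij`,
`μ = 1` after normalizing `W` to a unit maximum), while the data choose
each edge's sign. The result is a hybrid "resting-state structural
connectome": structural topology with inferred excitatory (+) /
inhibitory (−) edge roles.

## Inference

Couplings are fitted by maximizing the penalized log-pseudolikelihood

    ℓ(J) = (1/t_max) Σ_t Σ_i [ C_i(t) s_i(t) − ln(e^{C_i(t)} + e^{−C_i(t)}) ]
           − (λ/2) Σ_{i<j} (J_ij − sgn(J_ij) W_ij)²,

with local fields `C_i(t) = β Σ_m J_im s_m(t)` and `λ = A/β`.
Pseudolikelihood replaces the intractable joint likelihood (whose partition
function sums 2^N states) by per-region conditionals, and is consistent for
large samples. Ascent uses the exact gradient

    ∂ℓ/∂J_ij = (β/t_max) Σ_t s_j(t) (s_i(t) − tanh C_i(t)) − λ (J_ij − sgn(J_ij) W_ij)

(verified against central finite differences to 1e−5). Numerical choices:

- **Symmetrization.** The conditional for region i and for region j give
  different (i, j) entries; each step averages the (i, j) and (j, i)
  contributions, which is a positive rescaling of the gradient restricted
  to symmetric matrices, so ascent directions are preserved.
- **sgn(0) = 0.** An exactly-zero coupling is pulled toward 0, not toward
  ±W — no sign is injected that the data did not choose. A consequence is
  that the penalty is discontinuous at J = 0: from an exactly-zero start
  the very first step would create the full penalty and be rejected.
  Default initialization is therefore small uniform noise in [−0.01, 0.01]
  (seeded), which lets the data break sign symmetry; `init="zeros"` is
  available for the unconstrained model, where the issue does not arise.
- **Step control.** `J ← J + γ ∂ℓ/∂J` with `γ = 0.05` initially, halved
  whenever a step would lower the objective (so the objective trace is
  non-decreasing), mildly re-grown after accepted steps. Convergence when
  the max-norm of the update falls below `tol = 1e−6`; cap 5,000
  iterations with an explicit non-convergence warning. None of these
  values affect the optimum, only the path to it.
- **β during fitting** is a fixed hyperparameter (chosen by the grid
  search), never optimized jointly.
- The log-sum-exp is evaluated as `|C| + log1p(exp(−2|C|))`, so large
  fields cannot overflow.

Limits (both tested): `A → 0` reproduces the unconstrained pMEM;
`A → ∞` pins `|J|` to `W` exactly (`r(|J|, W) → 1`).

A practical regime note: the sign-locked penalty makes large `A` degrade
*sign* recovery — near `J = 0` the pull `λW` toward the current sign can
exceed the data gradient, freezing initialization signs. On synthetic data
with `|J| = W`, moderate penalties (`A ≈ 0.2–0.5` at `β = 0.8`) recover
couplings almost perfectly (r ≈ 0.99, sign agreement ≈ 1.0 from 5,000
samples at N = 20), while `A ≥ 1` visibly erodes both.

## Monte Carlo simulation

Metropolis dynamics: a "run" is a sweep of N single-site proposals, each
picking a site uniformly at random (with replacement) and flipping it if
the energy change `ΔE = 2 s_i Σ_j J_ij s_j` is ≤ 0, else with probability
`exp(−β ΔE)`. Random site selection (rather than a without-replacement
permutation) matters: visiting every site exactly once per sweep flips any
decoupled spin deterministically each sweep — a periodic chain whose pair
correlations never decay. Chains are never restarted between recorded runs;
burn-in defaults to 10% of the recorded runs. The sweep kernel is
JIT-compiled over a CSR view of `J`, so sparse lattices and dense
connectomes cost the same per actual interaction. An alternative
`local_energy` rule (flip when the site's local energy is ≤ 0, or with
probability `exp(β H_i)`) is provided for comparison; it does not satisfy
detailed balance and its stationary distribution is verifiably far from
Boltzmann (total-variation distance ≈ 1 at N = 4 where standard Metropolis
achieves 0.001).

Correctness is anchored to exact enumeration (`exact_moments`, N ≤ 15):
pair moments from 200,000 sweeps at N = 8 agree to < 0.01; configuration
frequencies over 10⁶ sweeps at N = 4 are within total-variation distance
0.01 of the Boltzmann distribution.

Observables per simulated β: per-site magnetization `m` per sweep;
`|M| = ⟨|m|⟩`; susceptibility `χ = (1/β)(⟨m²⟩ − ⟨|m|⟩²)`. The absolute
value inside the variance is the standard finite-size estimator: in a
small ordered system the chain occasionally reverses its global
magnetization, and without the absolute value those reversals masquerade
as enormous variance and drag the apparent peak far below the transition
(we measured the complete-graph peak at T ≈ 0.71 instead of ≈ 0.95).
The critical temperature is `T = 1/β` at the χ peak (ties toward higher
T). Oracle checks: complete graph `J = 1/N` peaks at T ≈ 0.91–0.95
(mean-field T_c = 1, finite-size shifted at N = 64); a 32×32 periodic
lattice peaks at T ≈ 2.27 (Onsager: 2/ln(1+√2) ≈ 2.269). Phase scans use
the nonnegative part of a signed network — the full signed system is a
frustrated spin glass whose thermodynamics this package does not attempt.

## Hyperparameter grid search

For each subject, `(β, A)` is chosen by maximizing
`f(β, A) = max f_c + S_m` over a grid (default 0.2–3.0, step 0.2 on both
axes), where `S_m = r(|J|, W)` over distinct pairs and `f_c(β_sim)` is the
correlation between observed FC and the FC reconstructed by simulating the
fitted system across a β_sim grid (default the same grid; 2,000 recorded
sweeps per cell, `max f_c` averaged over 3 MCMC seeds). Observed FC
defaults to the Pearson FC of the continuous z-scored series (the binary
FC is available via a flag). Ties break toward smaller A, then smaller β —
the least-constrained model at equal fit. Frozen simulation cells
(constant spins) are recorded as missing and excluded from the maximum.

**Identifiability caveat** (measured, and worth knowing before trusting
`β*` on any data): when the structural prior is exactly proportional to
the generating couplings, `f(β, A)` is nearly invariant along the `β·J`
scale degeneracy — `S_m` is a Pearson correlation (scale-free) and
`max f_c` re-absorbs any global scale error through the β_sim
maximization. The surface then shows a flat ridge from (β ≈ β_true,
small A) out to large (β, A), with spread below MCMC noise, and the argmax
lands on the ridge essentially at random: β_true was recovered within one
grid step in only 5/10 desk-scale replicates. On real data the prior is
misspecified (|J| is not exactly ∝ W) and large A genuinely costs
reconstruction quality, which is what makes interior optima observable.
The selected `A*` is better identified than `β*`.

## Excitation/inhibition balance and group comparison

The E/I ratio of a region is positive/negative over its off-diagonal row;
the global ratio counts each edge once. Default mode is `count`
(the convention of the worked example 45/34 = 1.32); `weight` mode uses
summed magnitudes. Exact zeros belong to neither side. A region with no
negative edges has an undefined ratio: error by default, NaN (treated as
missing in cohort averages) on request. Positive rescaling of `J` leaves
both modes unchanged; negating `J` inverts weight-mode ratios.

Groups are compared region-wise: subject-level ratios are averaged per
region within each group (not edge-pooled), then `delta = 1 − r_A/r_B`
per region, the cross-group R², and a two-sided paired t test across
regions (no multiplicity correction). **Caveat** (measured): each edge
sign contributes to both endpoint regions' ratios, so the region-wise
differences are positively correlated and the across-region paired t test
is anticonservative — its empirical size at nominal α = 0.05 is ≈ 13% on
null cohorts (38 subjects/group, 80 regions). Group-level P values from
this design should be read accordingly.

## Synthetic data

The generators emulate the full data-generating process of a two-group
resting-state study; all are pure functions of (spec, seed). Defaults are
the study conditions: N = 80 regions, t_max = 236 time points (8-minute
scan at TR = 2 s), structural edge density 0.3 with lognormal(0, 1)
weights normalized to max 1 (heavy-tailed, as tractography streamline
counts are) and bridged into a single component; couplings `|J| = W`
(μ = 1 convention) with per-edge excitatory probability 0.5; Boltzmann
sampling at β_true = 0.8 by thinned Metropolis chains (burn-in 20 N,
thinning N, so samples are approximately independent — matching the
exchangeability the pseudolikelihood assumes; a `trace` mode yields
autocorrelated consecutive sweeps); continuous observations add Gaussian
noise of 0.5 SD to the ±1 states (sign recovery after z-score/binarize
≈ 0.98). Cohorts share one anatomy with per-subject lognormal weight
jitter (σ = 0.1) and one regional excitability profile (SD 0.05 around
the base fraction, shared across groups).

`group_shift` injects the group difference on the scale it is measured
on: group B's regional E/I odds are scaled by `1/(1 − shift)`, so the
expected region-wise delta equals the shift (a +6% shift yields measured
mean delta ≈ 0.04–0.08 at 38 subjects/group). Defining the shift
additively on the excitatory fraction instead would make a "+6%" shift
produce delta ≈ 0.21, conflating the two scales.

What the generator does **not** emulate: hemodynamics (no HRF convolution
or autocorrelated scanner noise), motion/artifact gaps (series are
gap-free), distance-dependent coupling decay, and any real anatomical
topology (community structure beyond random graphs). Passing recovery
tests therefore demonstrate correctness of the estimator under the
model's own assumptions, not robustness to fMRI-specific confounds.

## Problem sizes used in the test suite

Oracle and recovery experiments are run at sizes chosen so each check is
statistically decisive: exact-enumeration comparisons at N = 4–8;
coupling recovery at N = 20 with 5,000 samples; grid-search replicates at
N = 15 with grids 0.4–2.8 (step 0.4); cohort statistics at the full
N = 80 with 38 subjects/group (100 null replicates for the size of the
t test); the full fitted pipeline at 38 subjects/group over 3 replicates.
The whole suite runs in a few minutes on one core.
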