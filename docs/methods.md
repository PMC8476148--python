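# Methods

`jointdfe` infers the *joint distribution of fitness effects* (joint DFE)
of new mutations between two diverged populations from their joint
allele frequency spectrum (AFS), and in particular the DFE correlation
`w` — the probability that a new mutation has the same population-scaled
selection coefficient in both populations rather than independent ones.
This note records the model, the numerical scheme, the synthetic-data
conditions, and the design choices that were genuinely open.

## Model

### Spectra and units

For samples of `n1` and `n2` chromosomes, the joint AFS `X[i, j]` counts
variants at derived-allele count `i` in population 1 and `j` in
population 2. The absorbing corners `(0, 0)` and `(n1, n2)` are always
masked. Units follow the standard diffusion convention: sizes relative
to the ancestral size `N_a`, time in `2·N_a` generations, migration
`M = 2·N_a·m`, selection `γ = 2·N_a·s` with diploid fitnesses
`1, 1+2hs, 1+2s`, and mutation rate `θ = 4·N_a·μ`. `γ1` acts in the
ancestral population and population 1; `γ2` acts in population 2 from
the split onward. Consequently `F(γa, γb)` is *not* the transpose of
`F(γb, γa)` even under a symmetric demography — swapping the coefficients
changes the ancestral equilibrium.

### Expected spectra

The engine computes `F(γ1, γ2 | Θdemo)` at `θ = 1`; the expected neutral
spectrum is `θ_neu · F(0, 0)` and the expected selected spectrum is the
DFE-weighted integral `θ_sel · ∬ F(γ1, γ2) G(γ1, γ2) dγ1 dγ2` over the
deleterious quadrant. `θ_sel` is always `ratio_NS × θ_neu`
(never free; presets 2.31 human, 2.85 *D. melanogaster*, 2.5 tomato,
5.21 GC-conservative human).

### Joint-DFE families

* **Mixture** (lognormal or gamma marginal): weight `w` on a perfectly
  correlated component (`γ1 = γ2 ~ G1d`) and `1−w` on independent draws
  from the same marginal. Because the two components share the marginal,
  the correlation of the mixture equals `w`. The correlated component is
  singular (a diagonal line mass) and is never represented as a 2D
  density: integration treats it as a 1D integral over the diagonal of
  the cache.
* **Bivariate lognormal**: `(log|γ1|, log|γ2|)` bivariate normal with
  log-scale correlation `ρ`, optionally asymmetric marginals. `ρ` is
  reported as the log-scale correlation; the raw-scale correlation of a
  bivariate lognormal differs from `ρ` and is not what this package
  reports. Numerical integration of this family degrades as `ρ → 1`
  (density concentrates between grid nodes); the mixture model is the
  primary parameterization.

### Ancestral misidentification

Mispolarized variants move AFS mass to mirrored frequencies:
`F'(i,j) = (1−p)·F(i,j) + p·F(n1−i, n2−j)`. Separate probabilities are
fitted for the neutral and selected classes; the transform conserves the
unmasked total and is applied after DFE integration and `θ` scaling (the
order is mathematically irrelevant for fixed `p`; fixed for
reproducibility).

### Likelihood and staging

AFS entries are modeled as independent Poisson counts (Poisson Random
Field), giving the composite log-likelihood
`Σ (−λ_ij + S_ij·log λ_ij − log S_ij!)` over unmasked entries. Because
every DFE evaluation integrates over a cache that is specific to the
demographic parameters, demography and DFE are inferred in stages:
demography from the neutral spectrum (with `θ_neu` profiled analytically
as `Σ data / Σ model`), then the DFE from the selected spectrum with the
demography held fixed.

## Numerics

### Diffusion engine

The two-population forward diffusion is solved on a phase-space grid
over `[0, 1]²`:

* **Grid**: tanh-crowded toward 0 and 1 (crowding 4.0), where the
  equilibrium density has its `1/x` singularity and strong selection
  forms boundary layers. Default base resolution `max(n1, n2) + 20`
  points.
* **Flux form**: discretized in the product variable `u = x(1−x)·φ`,
  i.e. `J = (1/2ν)·[B·u − ∂u/∂x]` with the bounded effective drift
  `B = 2ν·M/(x(1−x))`. `u` vanishes identically at the boundaries, so
  fixed/lost density accumulates in boundary cells and never diffuses
  back (exact absorbing behaviour), while boundary rows keep evolving
  along the free axis — a variant lost in one population continues to
  drift in the other.
* **Migration re-seeding**: a variant completely lost (or fixed) in the
  recipient population re-enters it through migrants exactly like a
  mutation source with `θ_eff = 2·ν·M·x` (respectively `2·ν·M·(1−x)`),
  where `x` is its frequency in the donor population. Each step the
  boundary mass escapes into the adjacent interior node at the
  correspondingly calibrated rate; the implicit sweep returns the
  non-establishing share to the boundary. Without migration the
  boundaries are strictly absorbing. This term is what reproduces the
  Wright–Fisher chain's doubly-rare shared variants under gene flow
  (without it the engine underestimates the (1,1) entry by ~25% at
  `M = 1`). The escape is applied explicitly within the operator
  splitting, so it carries an `O(dt)` bias concentrated on the
  doubly-rare shared entries (~2–3% at the default step, <1% at
  `dt_fac = 0.05`); oracle-grade comparisons use the finer step.
* **Interface weighting**: Chang–Cooper exponential fitting, exact for
  steady two-point problems and positivity preserving; this keeps
  mutation–selection–drift equilibria accurate up to `|γ| ~ 2000`
  without special-casing stiffness.
* **Time stepping**: fully implicit (backward Euler) with direction
  splitting, alternating the sweep order each step to cancel the leading
  splitting asymmetry. The step schedule is continuous in the epoch
  length (fixed steps plus one smoothly shrinking remainder), so the
  likelihood is smooth in `T` and finite-difference gradients are
  reliable. Target step `0.2/pts`, shrunk to `2/(1+|γ|)` under strong
  selection, between 25 and 400 steps per epoch.
* **Mutation influx**: a point mass at the first interior frequency on
  each axis, calibrated against the discrete chain's absorption
  probability so the neutral substitution flux is exactly `θ/2`
  (reproducing `φ = θν/x`). The calibration is neutral because selection
  is negligible at the injection frequency.
* **Extrapolation**: the whole computation runs on three grids
  (`pts`, `pts+10`, `pts+20`) and is Richardson-extrapolated entrywise in
  the first interior grid point to zero spacing.
* **1D problems** (ancestral equilibrium, pre-split epochs) use the same
  operator; the equilibrium is obtained by a direct steady-state solve,
  valid for any dominance coefficient.

Against the independent Wright–Fisher transition-matrix oracle
(extrapolated in `1/N`), the engine agrees to ~0.1% on neutral scenarios
and within 3% per unmasked entry across split, asymmetric-size,
IM-growth and migration scenarios at `|γ| ≤ 10`.

### Wright–Fisher oracle

An explicit expected-count propagation through binomial Wright–Fisher
kernels on the joint frequency state space, with per-generation
selection (exact post-selection frequencies, not linearized), migration,
growth (per-generation size rounding), mutation influx `ν·θ/2` per
population per generation, and binomial downsampling to the sample. The
joint update is an outer-product kernel (`~(2N)^4` per generation with
migration; separable matrix products without), so only small `N` are
tractable; a state-space guard refuses configurations beyond ~260k joint
states. Finite-`N` bias is `O(1/N)` and is removed in tests by Richardson
extrapolation over two or three chain sizes.

### Selection cache and DFE integration

Expected spectra are cached on a log-spaced grid of `γ` magnitudes
(full-scale default 50 points in `[1e-4, 2000]`, i.e. 2,500 spectra;
desk-scale default 25 points). DFE integration uses the trapezoid rule
on the raw (linear) γ abscissae of that grid — deliberately *not* a
transformed log-variable rule — with the singular mixture component as a
1D trapezoid along the cache diagonal. DFE mass outside the cached
domain is computed exactly from the distribution functions and assigned
to the nearest boundary cached spectrum; mass on the `γ → 0` side uses
the neutral spectrum (the smallest cached magnitude, `1e-4`, is
numerically neutral to ~1e-4 relative). The two candidate treatments of
the `γ → 0` tail (neutral spectrum vs smallest-magnitude node) differ by
less than the cache tolerance, so the choice is immaterial; the neutral
spectrum is used because it is exact in the limit.

The linear-abscissa trapezoid carries a known total-mass error for very
broad DFEs: ~6% at 25 grid points, ~2% at 50, shrinking quadratically
under refinement. This error acts almost uniformly across entries and is
absorbed by the marginal parameters during fitting: the fitted `w` moves
by <0.01 between 25- and 50-point caches while `μ̂` shifts visibly. A
runtime accounting check (trapezoid node masses + exact tail mass vs 1)
warns beyond 10% as a guard against domain mismatches.

### Optimization

Bounded local search (L-BFGS-B) on transformed parameters — log for
positive quantities, logit for `w`, `ρ`, `p_misid` and `s_frac` — with
`N` perturbed restarts (default 5; scaled-down studies use 2),
convergence at relative log-likelihood change `1e-10`, and
finite-difference gradient step `1e-6` (above the solver's residual
discretization noise). Ties between equal-likelihood optima resolve to
the lexicographically smallest transformed vector. Boundary-pinned
estimates of `w`, `ρ` or `p_misid` are flagged in the fit diagnostics.

### Godambe uncertainty

The sandwich variance `H⁻¹ J H⁻¹` is evaluated in transformed parameter
space at the MLE: `H` is the central-finite-difference Hessian of the
composite log-likelihood on the original data and `J` the empirical
covariance of bootstrap score vectors, each bootstrap's `θ_sel` scaled
by its segregating-sites ratio to the data. SEs are mapped to the
natural scale through the transform Jacobian; the default relative step
`1e-2` is automatically cross-checked at `1e-3` with a warning beyond a
20% shift. Because the printed `±` convention varies across studies,
both the SE and `1.96·SE` are always reported. `z`-tests of `w = 1` are
two-tailed normal tests; the Benjamini–Hochberg adjustment is applied to
exactly the family of p-values the caller passes (pooling across data
subsets is the caller's responsibility).

### θ partitioning between SIFT classes

`θ_NS` is split between deleterious- and tolerated-class sites by the
rate-weighted proportions `p_del = Σ u_i·d_i / Σ u_i·(d_i + t_i)` (and
analogously for tolerated), where `u_i` are the 12 nucleotide-change
mutation rates and `d_i`, `t_i` the per-type class counts. A published
variant of this formula with denominator `Σu_i · Σ(d_i + t_i)` does not
yield proportions summing to one; the rate-weighted form is used here.

## Synthetic-data conditions

The generator's defaults define the study conditions used throughout the
tests and the acceptance script:

* **Truth demography**: human-like IM — `s_frac = 0.8`, exponential
  growth to `ν1 = 2.5`, `ν2 = 3.0` over `T = 0.15`, migration
  `m12 = 1.0`, `m21 = 0.8`. Chosen once as a plausible
  Yoruba/European-like history (split ~`0.15·2·N_a` generations ago with
  post-split growth and asymmetric gene flow).
* **Truth DFE**: symmetric lognormal mixture `μ = 3.6`, `σ = 5.1`, and
  correlation sweeps over `w ∈ {0.8, 0.9, 1.0}`; gamma-marginal truth
  `α = 0.4`, `β = 1400`; bivariate truths symmetric `(3.6, 5.1)` and
  asymmetric `(μ2, σ2) = (4.5, 6.8)`.
* **Mutation rate**: `θ_NS = 13842.5` for the selected class.
* **Scale**: 20+20 chromosomes and 25-point caches by default — a
  desk-scale configuration preserving the qualitative regime of the
  full-scale design (216/198 samples, 50-point caches), which remains
  available through the same APIs.
* Observed data are independent Poisson draws per unmasked entry;
  robustness studies use the noise-free expectations directly, so
  deviations measure bias, not variance. Per-replicate seeds spawn
  deterministically from one base seed.

What the generator does **not** emulate: linkage (and hence background
selection), finite-sites effects, variable coverage or genotyping error,
real mutation-rate heterogeneity, and positive selection. Passing tests
therefore demonstrate statistical correctness of the estimator under the
PRF model, not robustness to those real-data complications; the
composite-likelihood machinery (Godambe SEs) is the designed mitigation
for linkage.

## Known limitations

* Deleterious-only DFEs; `γ = 0` is accepted only as a boundary.
* Two populations; no three-population extension.
* The bivariate lognormal's integration accuracy degrades for `ρ ≳ 0.9`
  at coarse caches; at desk scale the mixture fit to symmetric bivariate
  truth tracks `ρ` within 0.1 but can land slightly below it, so the
  one-sided "`ŵ ≥ ρ`" pattern should not be over-interpreted at 25-point
  resolution.
* Godambe SEs do not propagate demographic-parameter uncertainty into
  the DFE stage; uncertainties are therefore somewhat anticonservative.
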