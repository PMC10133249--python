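# Methods

## Model

Species abundances in a well-mixed chemostat follow

    dn_i/dt = n_i ( Σ_μ R_iμ s_μ / h_μ − (d + d_i) ),    h_μ = Σ_k n_k R_kμ,

with consumption rates `R_iμ ≥ 0` (every species consumes at least one
resource), supply rates `s_μ ≥ 0` with total `S > 0`, dilution rate `d > 0`,
and bactericidal death rates `d_i ≥ 0`. Resources are substitutable and
quasi-static: the availability of resource μ is `c_μ = s_μ / h_μ`, the
supplied flux divided by the community's total consumption pressure.

A bacteriostatic antibiotic divides a species' consumption rates by a
susceptibility `b_i ≥ 1`. With `b_i = (d + d_i)/d` the two representations
have identical survivor sets, and abundances map as
`n_static,i = b_i · n_cidal,i` (substitute `ñ_k = n_k/b_k` into the
bacteriostatic fixed point). `Community` stores one representation;
everything downstream works in the bactericidal form and converts on input.

Dimensionless units `t' = t d`, `n' = n d/S`, `R' = R S/d²`, `s' = s/S`
reduce the model to `d = S = 1`; all defaults and thresholds below are in
these units. Time in trajectories is reported in units of `1/d`.

## Steady states

**Geometric (direct) route.** The uninvadable steady state maximizes the
strictly concave potential `F(n) = Σ_μ s_μ ln h_μ − Σ_i (d + d_i) n_i` over
`n ≥ 0`, so it is unique and characterized by: survivors satisfy
`Σ_μ R_iμ c*_μ = d + d_i` exactly; non-survivors satisfy
`Σ_μ R_jμ c*_μ ≤ d + d_j` (they cannot invade). `coexisting_set` enumerates
species subsets from largest to smallest (at most `p` survivors generically)
and returns the first subset with an all-positive steady state that no
outsider can invade:

* |subset| = p — one `p×p` linear solve for `c*`, one for the abundances;
  the abundance positivity is exactly the condition that the normalized
  supply lies in the convex hull of the subset's rescaled consumption rates.
* |subset| = 2, any p — the balance equations reduce to a scalar root
  problem in the abundance share `t = n_2/(n_1+n_2)` (availabilities depend
  on `t` only); concavity of `F` makes the interior root unique, so a sign
  check of the reduced equation at the interval ends decides feasibility and
  Brent's method localizes the root to machine precision. This exactness
  matters: equal-budget sampling (below) routinely produces pairs whose
  interior fixed point has one component of order 1e−4, where damped Newton
  iterations stall on the boundary.
* 2 < |subset| < p — multiplicative updates `n_i ← n_i · growth_i/(d+d_i)`
  (monotone ascent of `F`, positivity-preserving), a Newton finish inside
  the quadratic basin, and, on stalls, an exact boundary diagnosis: drop the
  species with the worst growth deficit, solve the face recursively, and
  test whether the dropped species re-invades the face state. No re-invasion
  proves the potential peaks on the boundary (subset infeasible); re-invasion
  proves an interior point exists, which is then found by a root finder
  seeded from the face solution.

Hyperplane-side and hull-boundary comparisons use a 1e−9 tolerance, with
boundary cases counted as contained, so ties are deterministic.

**Dynamical route.** `integrate` runs an explicit adaptive Runge–Kutta
(SciPy RK45, rtol 1e−8, atol 1e−10). A species crossing below the
extinction threshold 1e−7 (dimensionless abundance) is clamped to zero and
removed for the rest of the run. `steady_state` starts all present species
at equal abundances (the steady state is independent of positive initial
conditions for this model class — a checked property, not an assumption),
integrates in windows of 20 time units, estimates `d ln n/dt` and
`d² ln n/dt²` by finite differences over three window samples, and stops
when every species either has |curvature| < 1e−6 or is extinct. Richness
counts species with `n > 1e−7` and `d ln n/dt > −1e−3`.

Two refinements keep the dynamical route asymptotically faithful:

* *Doomed-decliner removal.* A species can decline log-linearly at a rate
  slower than the 1e−3 cutoff (e.g. 7e−4) — it satisfies the stopping
  criteria while it is, in fact, headed to extinction over ~1e4 time units.
  Once the rest of the community is stationary, a decliner is removed iff it
  could not grow even at the availabilities computed with its own biomass
  deleted (the most favorable environment it can ever see). A decliner that
  could re-grow is merely relaxing toward a positive equilibrium and is kept.
* *Fixed-point polish.* The stopping rule accepts states whose slow modes
  are still ~1e−4 from the fixed point. Survivor abundances are refined with
  a root finder (SciPy hybr) seeded by the ODE endpoint; survivor
  *identification* remains purely dynamical, so cross-checks against the
  geometric solver remain a genuine dual-route test.

`t_max` defaults to 1e4 with up to 3 same-length extensions; non-convergence
is flagged, not raised.

## Synthetic communities

The generators reproduce two sampling schemes:

* **Random ensembles** — each consumption row uniform on the unit simplex
  (normalized exponentials; all enzyme budgets exactly 1), equal supply with
  S = 1, d = 1. Death rates either (a) i.i.d. U(0,1) on two designated
  target species — the scheme behind the combination/sequence ensembles — or
  (b) a simplex-uniform vector over all species — the dose-response scheme.
* **Structured three-species family** — species i's consumption vector on
  the segment from the simplex centroid (the supplied-resource point under
  equal supply) toward vertex i, at Euclidean distance `D ∈ (0, √(2/3))`
  (the centroid-to-vertex distance). Species 1 and 2 are targeted at
  distances `D_T1`, `D_T2` with death rates `d_1, d_2 ∈ (0,1)`; the
  untargeted species sits at `D_N`. Each species gets its own vertex; this
  is the one placement for which the stated distance domain is exactly the
  geometric range.

Uniform-simplex rows make all budgets equal, so before treatment every
species lies on the same hyperplane (`c* = 1`) and full coexistence is
exactly hull containment of the supply point (probability ≈ 0.25 for three
random rows against centered supply). What the generators do **not**
emulate: unequal enzyme budgets in the random scheme, correlated
(broad-spectrum) death rates, non-substitutable resources, or dynamic
supply — conclusions from passing tests carry to real communities only to
the extent those idealizations hold.

## Treatment protocols

All protocol steady states use the geometric solver; the test suite
spot-checks it against the ODE route on hundreds of random communities.

**Dose scan.** Death rates `c · profile` with `c` on a grid (default 401
points), richness evaluated with reservoir semantics (coexisting set over
the full pool at every dose, modeling an external species pool that
re-seeds extinct species). Change points are refined by recursive bisection
to 1e−4 in `c`; `n_changes` counts richness transitions up to and including
the extinction dose of the targeted species. Grids cannot see coexistence
windows narrower than the spacing; the bundled non-monotonic examples were
validated with fine grids.

**Sequential treatment.** (i) steady state of the full pool with no
antibiotic → pre-treatment survivors; (ii) first antibiotic applied to
those survivors (no reservoir — extinctions are permanent); (iii) the
antibiotics are swapped directly, with no drug-free interlude. `delta_rho`
is the absolute richness difference between the two orders; it is 0 or 1
throughout the structured family.

**Mechanism classification.** Each antibiotic is applied in two contexts
during the order swap: first (pre-treatment pool) or second (survivors of
the other antibiotic). Comparing its extinction sets between the two
contexts, restricted to species present in both: a species killed in the
fuller first-position context but spared second-position witnesses
competition *promoting* the antibiotic's action; a species spared
first-position but killed second-position witnesses *neutralization*. With
`delta_rho > 0` exactly one signal type occurs in practice; mixed or absent
signals return `"unclassified"` and are logged rather than guessed. The
witnessed extinction is usually the antibiotic's own target but can be
collateral — restricting the comparison to targets alone leaves a few
percent of order-dependent cases unclassified, while the extinction-set
comparison classifies them all without disturbing the target-driven cases.
The per-target context flags (extinct in the full pool vs extinct with the
other target removed) are still reported for diagnostics.

**Combination treatment.** From the pre-treatment survivor pool, extinction
sets under A alone, B alone, and A+B. The additive baseline is the
pre-treatment richness minus the size of the union of the single-drug
extinction sets; combined richness above the baseline is antagonism, below
is synergism. Using the pre-treatment richness (rather than `m`) as the
baseline reference keeps the comparison self-consistent when the community
did not fully coexist before treatment; the two coincide when it did.

**Ensembles.** `ensemble_scan` tabulates the 3×3 mechanism-by-additivity
table over a sampled ensemble, deterministic given the seed. The ensemble
conditions on full pre-antibiotic coexistence when
`require_full_coexistence=True` (rejected draws are resampled); the
cross-occurrence statistics shipped in `scripts/acceptance.py` use the
conditioned ensemble at n = 20,000, and the structured-family scan at
n = 50,000 — sizes chosen so binomial error is well below the reported
effects while the whole script runs in minutes on one CPU.

**Aggregation of symmetric species.** For m = p communities in which a
group of untargeted species is invariant under jointly permuting the group
members and their private resources (species i's private resource is
resource i), the group collapses exactly to one species and one merged
resource: shared-column rates are preserved, private-column rates and
supplies are summed, and by symmetry of the unique steady state the merged
species carries the group's combined abundance, so survivor sets and
treatment classifications are unchanged. Small symmetry violations (within
a caller-chosen tolerance, relative to the largest consumption rate) are
symmetrized by averaging; classification agreement then holds with high
probability rather than exactly.

## Cross-feeding

During consumption a fraction `l_μ ∈ [0, 1)` of resource μ's mass is
excreted as byproducts, redistributed over resources by a row-stochastic
matrix (uniform by default, `1/p` everywhere); the remaining `1 − l_μ`
fuels growth. Under the quasi-static resource balance the recycled flux
forms a geometric series with fixed point
`s_eff = (I − Bᵀ diag(l))⁻¹ s`, and the dynamics coincide with the
leakage-free model driven by supply `(1 − l) ∘ s_eff`.
`reduce_to_effective_supply` applies the closed form (valid for uniform
byproducts and species-independent leakage); `integrate_with_leakage`
accumulates the series pass by pass instead, so the equivalence test between
the two routes is a numerical check, not an identity. Mass accounting holds
for any row-stochastic byproduct matrix: `Σ_μ (1 − l_μ) s_eff,μ = S`.

## Numerical choices and limitations

* Extinction (1e−7), curvature (1e−6), decay (−1e−3) and stationarity
  (1e−6) thresholds apply to dimensionless abundances and rates.
* Coexistence-region sizes are exact for p = 2 (the survivor positivity
  region is an interval in the supply share) and seeded Monte Carlo with
  20,000 uniform simplex samples otherwise; no exact hull volumes for
  p > 3.
* The model assumes a unique uninvadable state (guaranteed by the concave
  potential for full-row-rank consumption matrices); multistability,
  toxin-mediated interactions, dynamic supply, and species-specific or
  non-uniform leakage are out of scope.
* Exactly degenerate subsets (rank-deficient, or tangent to the feasibility
  boundary) are skipped or counted as boundary-contained with the 1e−9
  tolerance; they are measure-zero under all samplers used here.
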