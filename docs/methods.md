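# Methods

## Binding scheme and the relaxation rate

The package models interfacial membrane binding as one reversible
bimolecular step, E + S ⇌ ES, with complex concentration x obeying

    dx/dt = k_on (E₀ − x)(S₀ − x) − k_off x,     x(0) = 0.

S₀ = C₁·f·[L]_total is the binding-site concentration: f is the leaflet
accessibility factor (default 0.5 — an externally added protein reaches
only the outer leaflet of a unilamellar vesicle, and lipid partitions
nearly equally between leaflets), and C₁ converts accessible lipid to
sites, so 1/C₁ is the number of lipids engaged per bound protein.
Linearising the ODE around its equilibrium gives the relaxation rate

    k_obs = k_on(E₀ − x_eq) + k_on(S₀ − x_eq) + k_off
          = √( k_on²(E₀ − S₀)² + k_off² + 2 k_on k_off (E₀ + S₀) ),

the closed form used throughout. It is written with the square root over
the whole right-hand side: that is the only reading with units of s⁻¹ and
the standard relaxation-kinetics result, and the package verifies it two
independent ways — algebraically against the equilibrium route (identity
holds to 1e−10 relative) and numerically against the integrated ODE
(log-linear tail slope matches within 0.5% over random parameter grids).
The expression is symmetric in E₀ and S₀, reduces to k_on·c + k_off when
either species is dilute, has its minimum at S₀ = E₀ − K_D, and never
falls below k_off.

Assumptions: one class of independent, non-interacting sites; no
cooperativity, surface crowding or saturation corrections; constant
temperature; fluorescence linear in bound complex. These are reasonable
when only a marginal fraction of the vesicle surface is occupied, which
the geometry module quantifies (≈0.3% under the study conditions).

## Trace stage

Replicate traces sharing a lipid concentration are averaged pointwise (a
shared instrument time base is required; mismatched grids are an error,
not an interpolation). The averaged trace is fitted with
F(t) = F∞ − ΔF·e^(−k t), amplitude constrained non-negative by default
because binding raises the fluorescence yield. The rate is
log-parameterised (k > 0 by construction) and the optimiser is started
from a data-driven guess (F∞ ← last-decile mean, ΔF ← F∞ − F(0),
k ← 2/span) plus eight log-spaced rates; the standard error of k comes
from the linearised covariance at the optimum.

**Second-order transient.** The exact x(t) of the bimolecular scheme is
monoexponential only asymptotically; a full-window monoexponential fit of
a noiseless synthetic trace overestimates the relaxation rate by 14–30%
under the study design (protein and site concentrations comparable). The
`settle_decades` option therefore re-fits with the window opened
`settle_decades/k̂` after mixing, iterating until the window is
self-consistent. At the default of 3 fitted time constants the residual
bias is ≤1.2% across the six study concentrations, which is why the
trace-stage checks use a 2% tolerance. Real instrument traces that are
already effectively first-order can be fitted over the full window
(`settle_decades=None`, the default of `fit_monoexponential`); a
configurable absolute window accommodates instrument dead time, though no
dead-time deconvolution is attempted.

## Global fit and conventions

(k_on, k_off, C₁) are fitted to the k_obs-vs-lipid table by least squares
in log-parameter space, multi-started from a seeded Latin hypercube over
k_on ∈ [0.1, 10] μM⁻¹s⁻¹, k_off ∈ [0.01, 2] s⁻¹, C₁ ∈ [0.005, 0.1] (16
starts plus one start on the pseudo-first-order line), because the
surface has a ridge where k_on and C₁ trade off. Ties between optima
(ΔRSS < 1e−10) are broken by smallest k_off for determinism. Fits are
unweighted by default — printed per-point standard errors are not
necessarily the weights the original analysis used — with
inverse-variance weighting available.

Two conventions are genuinely ambiguous in the source data and are swept
rather than guessed:

- **Protein concentration**: the experimental description gives 0.78 μM
  post-mixing while the occupancy argument uses ~0.2 μM. Both are fitted.
  The 0.78 μM fit reproduces the quoted k_on = 2.06 μM⁻¹s⁻¹,
  k_off = 0.37 s⁻¹ and K_D = 180 nM; the 0.2 μM fit gives the same RSS
  with k_on rescaled (≈8.0 μM⁻¹s⁻¹), reflecting an approximate k_on·E
  degeneracy of the six-point design.
- **Lipid basis of C₁**: applied to accessible (leaflet-corrected) or
  total lipid. The two fits are identical up to C₁ ↔ C₁/f, so both
  stoichiometries are always reported: 1:47 on outer-leaflet lipid,
  1:94 on total lipid. The quoted 1:94 corresponds to the total-lipid
  basis, which the acceptance script and the README example report as
  the headline stoichiometry.

Parameter uncertainty is by residual-resampling bootstrap (percentile
intervals, refits started at the point estimate; failed refits counted
and excluded), since the source analysis reports no uncertainties.

## Vesicle geometry

Lipids per vesicle = leaflets × 4πr²/a with diameter 150 nm and head-group
area a = 0.6 nm² by default, giving ≈235,600 — whereas a vesicle molarity
of 50 nM at 1 mM lipid implies an aggregation number of 20,000. These two
routes are mutually inconsistent and the module computes both, via the
geometric formula and an explicit `lipids_per_vesicle_override`; nothing
silently prefers one. The occupancy fraction uses the outer spherical
surface only, since bound protein sits outside. Polydispersity, curvature
corrections and bilayer thickness are out of scope.

## Synthetic data

The generator emulates the study design: 0.78 μM protein, six total lipid
concentrations 45.5–273 μM, leaflet factor 0.5, five replicates per
concentration. Trajectories come from LSODA at rtol 1e−9 (the quadratic
ODE also has a closed-form solution, used as an independent oracle in the
tests); traces are offset + gain·x(t) plus additive homoscedastic
Gaussian noise, and k_obs datasets are the closed-form curve plus
Gaussian noise (σ = 0.03 s⁻¹ in the recovery studies, comparable to the
scatter of the measured table). All noise is seeded and bit-reproducible.
Not emulated: photon-counting statistics, mixing dead time, photobleaching
and inner-filter effects — so passing tests demonstrate correctness of
the estimators under the stated noise model, not robustness to every
instrument artefact.

## Numerical choices

- Equilibrium x_eq uses the stable quadratic root
  2k_on E S/(b + √disc) with the discriminant expanded to its
  cancellation-free form, exact even at the degenerate point k_off = 0,
  E = S.
- Optimiser tolerances are 1e−14 (xtol/ftol/gtol) so noiseless parameter
  recovery is at 1e−6 relative and fits are invariant to point order.
- The ODE relaxation rate regresses log(x_eq − x) on the trailing 25% of
  a horizon of eight relaxation times; longer horizons underflow the tail
  residual and raise a window error rather than returning noise.
- Monte-Carlo sizes in the test suite (200 recovery replicates, 200
  oracle draws, 30×200 bootstrap coverage repeats) were chosen to give
  stable medians and coverage estimates at interactive runtimes.

## Known limitations

Single-exponential traces only (no bi-exponential or stretched models);
one-step binding (no docking/insertion sequences); no global simultaneous
fitting of raw traces across concentrations; no Bayesian posterior; the
k_on·E degeneracy of narrow titration designs means the absolute k_on
inherits the uncertainty of the protein concentration.
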