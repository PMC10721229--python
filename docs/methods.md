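# Methods

`mabsolkit` analyses the solution behaviour of ellipsoidal ~50 kDa proteins
(Fab/Fc-like antibody fragments) in a 1:1 electrolyte. This note documents the
models, the estimators, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Unit convention

All distances are nm, energies kJ/mol, charges multiples of the elementary
charge e, temperatures K, masses g/mol, concentrations mol/L (electrolyte) or
mg/mL (protein, SLS interface), B22 in mol·mL/g². Physical constants are
pinned to CODATA 2018 exact values in `mabsolkit.constants`:
e = 1.602176634×10⁻¹⁹ C, k_B = 1.380649×10⁻²³ J/K, N_A = 6.02214076×10²³,
ε₀ = 8.8541878128×10⁻¹² F/m. The default temperature everywhere is 300 K.

## Size and shape metrics

**Radius of gyration.** Rg² = Σᵢ mᵢ(rᵢ − R)²/Σᵢ mᵢ with the mass-weighted
center of mass R. No periodic wrapping is applied across the selection: the
protein is assumed whole. Rg² equals the trace of the mass-weighted gyration
tensor; both code paths exist and are cross-validated in the tests. Rg
distributions are density-normalised histograms with a default bin width of
0.01 nm, fine enough to resolve bimodal conformational populations separated
by ~0.15 nm.

**Anatomical dimensions (LA/W/H).** Per frame, the mass-weighted gyration
tensor of the selection is diagonalised; eigenvectors sorted by descending
eigenvalue define PA1 (long axis), PA2 (width) and PA3 (height). Each
dimension is the absolute component along its assigned axis of the vector
between the centers of mass of a marker-residue pair. Axes are *not* sorted
per frame by length of the marker vectors — they are anatomical. When two
eigenvalues are degenerate within a relative tolerance (default 10⁻⁸) the
assignment is tie-broken by maximal overlap with the previous frame's axes
and a warning is emitted; for distinct eigenvalues the eigenvalue order is
used unconditionally, because axis-continuity matching is meaningless when
consecutive frames are decorrelated (the synthetic generator applies an
independent random rotation per frame). Signs of the eigenvectors are
irrelevant since absolute components are reported.

**SASA.** Shrake–Rupley point sampling: each atom's sphere is inflated by the
probe radius (default 0.14 nm), covered with n deterministic golden-spiral
points (default 960), and the fraction of points not buried inside any
neighbour's inflated sphere, times the sphere area, is accumulated over the
selection. Neighbour search uses a KD-tree. Per-atom radii default to the
Bondi van der Waals set (element-keyed, configurable); an unknown element is
a hard error naming the element. The estimator converges to <0.5% between
960 and 4000 points on the fixtures; the isolated-sphere analytic value
4π(R+r_probe)² is reproduced to the quadrature tolerance of the point set.

## Hydration and double layer

**Surface-minimum-distance RDF.** Each solvent/ion atom is binned by its
minimum center-to-center distance to any protein atom under the orthorhombic
minimum-image convention (triclinic boxes are rejected); counts are divided
by the bin width and averaged over frames. No solvent-excluded surface is
constructed: "distance to the surface" means minimum atom distance. The
defining property of this unnormalised profile is that its integral to r is
the mean number of species atoms within r of the surface; the integral is
implemented as the exact cumulative step-function integral (full bins plus
the fractional final bin), so the identity holds to machine precision rather
than to trapezoid error. Default bin width is 0.002 nm for water/ion work
(first hydration peak at ~0.3 nm), coarser bins are fine for ion statistics.
Water is counted per atom; an oxygen-only (per-molecule) mode is a flag.

**Rescaled RDF.** For cross-system comparison a straight line a + br is
fitted over a window (default 1–2 nm, ≥5 bins required) and the profile is
divided by the line. If the fitted line crosses zero anywhere in the profile
support the operation fails rather than dividing by ~0.

**Net charge and screening length.** Qnet(r) = Q_protein + n₊(r) − n₋(r),
with n± the exact cumulative ion counts, reported at bin right edges; for a
neutral box Qnet at the half-box is zero as an integer identity. The decay is
fitted with A₀·exp(−r/ζ) over 0.25–1.0 nm by nonlinear least squares in
linear space (log-linear regression is available for strictly positive data
but cannot handle the zero crossings seen for weakly charged proteins). The
RMS residual and the (A₀, ζ) covariance are always reported so deviations
from exponential decay are quantifiable.

**Poisson–Boltzmann Debye length.** For a monovalent 1:1 electrolyte,
ζ = sqrt(ε_r ε₀ k_B T / (2 e² N_A · 10³C)) with C in mol/L. For ε_r = 78,
C = 0.15 mol/L, T = 300 K this gives 0.79 nm. (The inverse-square form
sometimes printed for this expression is dimensionally inconsistent; the
standard form above is implemented and reproduces the 0.79 nm check.)

**Survival probability.** Occupancy hᵢ(t) = 1 when atom i is within the
cutoff (default 0.35 nm) of the surface. The intermittent definition
P(t) = ⟨h(t₀)h(t₀+t)⟩/⟨h(t₀)⟩ is the default; the continuous definition
requires uninterrupted residence and is never larger. Both average over all
time origins and require uniform frame spacing. Both are provided and
labelled because published estimators differ in exactly this choice.

## Umbrella sampling, WHAM and B22

**WHAM.** Windows restrain the inter-protein center-of-mass distance with
harmonic biases (reference protocol: 51 windows, centers 3.0–8.0 nm in
0.1 nm steps, k = 1000 kJ/mol/nm²). The estimator histograms each window on a
common grid (default 200 bins over the sampled range) and iterates the
self-consistent equations for the bin probabilities and window free energies
in log space (log-sum-exp stabilised) until max|Δ(RT ln fᵢ)| < 10⁻⁸ kJ/mol
(max 10⁵ iterations; non-convergence is a hard error reporting the residual).
Adjacent windows must share at least one occupied bin, otherwise the error
names the gap. A window with zero spring constant is legal and reduces WHAM
to Boltzmann inversion of its histogram.

*Zero reference.* ΔG is shifted to zero at the bin nearest the largest
window center (configurable via `reference_r`), and the profile is trimmed
there. The bin at the largest *sampled* r is the extreme tail of the last
window — it holds O(1) counts and carries O(RT) noise, which would offset
the entire profile by a constant that does not shrink with sample size. The
largest window center sits on the plateau and is the best-sampled point of
the last window.

*Uncertainty.* Optional Bayesian bootstrap (Dirichlet weights over samples
within windows, default 50 replicas in `b22_report`, warm-started from the
converged free energies), giving a per-bin standard deviation with the
reference bin fixed at zero. A half-vs-full sample comparison is the
convergence diagnostic used in the tests.

**B22.** B22 = −(2πN_A/Mw²)∫₀^∞ (g(r) − 1) r² dr with
g(r) = exp(−ΔG(r)/RT), the low-concentration, spherical approximation. The
grid integral is trapezoidal (a Simpson difference is reported as the
quadrature-error estimate; the closed-form oracles are matched to ≲0.1% at
the default grids). Below the sampled range the default core rule is a hard
core (g = 0, contributing −r_min³/3; the proteins overlap there), and the
core contribution is reported separately so its influence is auditable.
Beyond the sampled range the default tail rule is g = 1 (zero contribution),
which requires the PMF to be zero-referenced at its largest r — violating
profiles are rejected with instructions rather than silently shifted. Units:
r enters the integral in cm, so B22 emerges in mol·mL/g² for Mw in g/mol.
Sign convention: attractive wells give B22 < 0, pure repulsion B22 > 0, and
pointwise-deepening an attractive PMF never increases B22.

## Scattering estimators

**Guinier fit.** In the Guinier regime I(q) = I(0)exp(−q²Rg²/3), so ln I is
linear in q² with slope −Rg²/3. The fit range is determined
self-consistently: start from the lowest decile of q, fit, recompute
q_max = 1.3/Rg, refit until stable (≤20 iterations, ≥5 points always
required; weighted by 1/σ² of ln I when intensity errors are present). The
criterion is the standard dimensionless q·Rg ≤ 1.3 (the dimensional form
occasionally printed is a typographical inconsistency). A single boundary
point dithering in and out of the limit between iterations is treated as
converged on the intersection set, with the q_max·Rg constraint re-enforced
by trimming; genuine oscillations of more than one point are an error
reporting both candidate set sizes. A non-decaying curve (slope ≥ 0) is an
error: there is no Guinier regime to fit.

**SLS Debye plot.** KC/Rθ regressed on concentration (interface unit mg/mL,
converted to g/mL internally): intercept = 1/Mw, slope = 2·B22, with
regression standard errors. A non-positive intercept is unphysical and is
rejected as a calibration problem. dn/dC is interpreted as 0.185 mL/g and
λ = 633 nm for the optional Rayleigh optical-constant helper; supplying
KC/Rθ directly is the primary path.

## Synthetic-data generators

The generators are statistical stand-ins for molecular-dynamics trajectories
and instruments: no force field, water, or integrator. All are
bitwise-reproducible under a fixed seed. Their defaults encode the study
conditions: 300 K, 150 mM 1:1 salt (148 ion pairs, 12 nm box, protein charge
+11e for the Fab-like case), crystal semi-axes (3.9, 2.875, 2.275) nm, and
the 51-window umbrella protocol above.

**Ellipsoid protein.** Six marker beads sit at the axis tips; the remaining
beads are octant-symmetric 8-fold orbits on the ellipsoid surface, which
makes the gyration tensor exactly diagonal in the body frame so the
principal axes coincide exactly with the geometric axes (hence
`n_beads = 6 + 8k`). Frames apply an isotropic breathing scale 1 + A·u
(u uniform in [−1, 1], A < 0.5), a uniform random rotation and a random
translation. Real proteins flex anisotropically and their principal axes
fluctuate; passing tests on this generator demonstrates the estimators'
geometric correctness, not robustness to conformational change.

**Ion cloud.** A central "protein" particle of charge Q with n bulk
cation/anion pairs uniform in the half-box sphere and |Q| excess counterions
whose radii follow a truncated exponential with the target screening length
ζ (inverse-CDF sampling), so the ensemble-mean net charge decays as
Q·exp(−r/ζ) and every frame is exactly neutral. The box must exceed 6ζ so
the truncation correction is negligible in the 0.25–1.0 nm fit window. Real
double layers have structured first shells and ion–ion correlations; the
generator only reproduces the mean-field exponential decay it is asked to.

**Umbrella windows.** Each window is Metropolis-sampled from
exp(−[ΔG(x) + k/2(x−xᵢ)²]/RT) with a Gaussian proposal of width
sqrt(RT/k), 1000 burn-in steps and 10× thinning (all windows advance in
parallel). An acceptance rate below 0.05 in any window aborts with an error.
In the stiff-spring limit the per-window sample variance approaches RT/k
(equipartition), which the tests check at 10%. Analytic PMF forms: flat,
Gaussian well (depth ≥ 0, minimum −depth), and Gaussian well behind a hard
wall at the lower range edge. Outside `r_range` the smooth forms continue
analytically; only the hard wall truncates, so edge windows are not
artificially clipped.

**Scattering.** SANS curves carry multiplicative Gaussian noise
(count-statistics character); draws that would make an intensity negative
are redrawn. SLS series carry additive noise with standard deviation
expressed as a fraction of the intercept 1/Mw (instrument character). The
q grid spans 0.1/Rg to 3/Rg by default so the Guinier limit lies strictly
inside it.

## Problem sizes used in the shipped checks

The acceptance script and test suite run the umbrella pipeline at 51 windows
× 5×10⁴ samples (WHAM recovery and end-to-end B22), the ion cloud at 1500
frames, and the Guinier noise calibration over 200 seeds; unit tests use
scaled-down versions of the same fixtures with tolerances widened in
proportion to the expected statistical error at those sizes. The WHAM depth
estimate at the full size lands within ±1 kJ/mol of the generating
14 kJ/mol well with a maximum deviation below 0.5 kJ/mol over the well
region, and the end-to-end B22 agrees with the analytic-PMF route to a few
percent (the B22 error is dominated by exp(−ΔG_min/RT), i.e. it amplifies
the well-depth error by 1/RT ≈ 0.4 per kJ/mol).

## Known limitations

- Orthorhombic boxes only; triclinic minimum image is rejected.
- B22 uses the spherical, low-concentration approximation; no orientational
  averaging over anisotropic protein shapes.
- The surface RDF uses atom-center distances, not a solvent-excluded
  surface.
- The Guinier and Debye-plot estimators assume the respective linear regimes
  hold over the fitted ranges; no form-factor modelling beyond Guinier.
- The synthetic generators define the ground truth the pipeline is validated
  against; agreement there does not certify accuracy on real MD or
  instrument data with systematic effects the generators omit (background
  subtraction, window equilibration, correlated noise).
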