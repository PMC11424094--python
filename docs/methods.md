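# Methods

## Continuum model

The bleached population in a spherical condensate of fixed radius R
obeys radial diffusion with piecewise-constant coefficients D_den (r < R)
and D_dil (r > R).  The interface enters as a flux condition: the net
outward flux equals κ[c(R−) − (c_den/c_dil) c(R+)], the linearized form of
exchange rates that satisfy detailed balance at the equilibrium partition
ratio c_den/c_dil.  κ (µm/s) is the interface conductance; κ = ∞ pins
the concentration jump to its equilibrium ratio.

**Discretization.**  Conservative finite volumes on a radial grid: cells
are spherical shells, R lies exactly on a cell face, the grid is uniform
inside the droplet (default 60 cells; fewer than 30 is rejected) and
geometrically stretched outside (ratio 1.05).  The flux between the two
cells straddling R uses a series-resistance form,

    Φ = A(R) · (c_in − g·c_out) / (dL/D_den + 1/κ + g·dR/D_dil),   g = c_den/c_dil,

which reduces exactly to the equilibrium-partition condition at κ = ∞
and keeps the scheme conservative, so mass conservation is a testable
invariant (closed domains are checked to 1e-6 relative drift and the run
aborts if violated — this doubles as the grid self-consistency check).
The semi-discrete system is linear and stiff (D_dil ≫ D_den plus the
interface term); it is integrated with SciPy's BDF using the assembled
sparse operator as the exact Jacobian, rtol 1e-8.

**Outer boundary.**  Two domains: a closed sphere of given outer radius
(reflecting wall; used for finite-pool FRAP), and an "infinite" proxy —
an absorbing far-field boundary at 10·max(R, sqrt(D_dil t_max)), which
stands in for the r → ∞ condition.  The high-resolution solver also
serves as the numerical stand-in for the exact Laplace-transform solution
when testing the closed-form recovery time; the integral form of that
exact solution is deliberately not re-derived here.

**Recovery-time extraction.**  Three extractors are exposed:

* `fit_single_exponential` (default): least squares of 1 − exp(−t/τ) on
  the whole curve resampled to a uniform time grid.  Uniform-time
  sampling weights the slow part of the recovery the way a fit to an
  experimental trace does and tracks the dominant relaxation.
* the same function with an `f_window`, restricting the fit to a band of
  f values — useful to isolate the early or late response, but biased by
  the fast dense-phase transient when used on strongly multi-exponential
  curves;
* `RecoveryCurve.t_at_1me()`, the 1 − 1/e crossing time.

The validity statement "closed form within 10% of the solved model for
D_dil > 20 D_den" holds with the default extractor over concentration
ratios c_den/c_dil from ~100 upward — the regime of the systems this
model is applied to (ratios 111, 154 and 1190).  At ratios below ~30 the
closed form overestimates the fitted time by 15–25% even at the stated
diffusivity contrast, because the dilute-supply term is no longer
separated from the dense-phase spectrum; the acceptance sweep therefore
uses the physical ratios, and users working at low partition ratios
should fit the solver output directly.

**Finite-pool fits.**  In a closed box f(t) plateaus at A < 1; the form
f(t) = A[1 − exp(−t/(Aτ))] is fit with bounded least squares (A within
(0, 1.5]).  A agrees with the mass-balance prediction
N_dilute/(N_dilute + N_droplet) to within the fit's ~2% bias.

**Parameter inversion.**  κ is recovered from a solved curve via
κ = (R/3)/(τ_fit − τ_den − τ_dil).  This is accurate (<5%) when the
interface term carries at least ~2/3 of the total time; at
τ_int ≈ τ_diffusive and D_dil = 20 D_den, the closed-form bias leaks ~6%
into κ.  Error bars on inferred κ should account for this when the
interface is not clearly dominant.

## Interface-conductance theory

* Mean-field: κ⁻¹ = ∫ c_den/(c_eq(x) D(x)) dx across the interface
  window (trapezoid quadrature on the supplied profile).  For a
  dilute-like window of width δ this is κ0 = c_dil D_dil/(δ c_den).
* Sticker availability: κ = 4π r0 δ D_dil n² c_dil/(2 + s + s⁻¹) ·
  (f^A_dil f^B_den + f^B_dil f^A_den), with the stoichiometry factor
  parsed as the denominator (2 + s + s⁻¹) — the unique parsing under
  which κ/κ0 equals the availability parameter u exactly, which the test
  suite asserts to 1e-12.  Units: r0, δ in nm, concentrations in nm⁻³,
  D in µm²/s, κ in µm/s; 1 nm⁻³ = 1.661 M.
* Slab inversion: κ = (c_dil/c_den)·sqrt(D_dil/τ)·tan(d/sqrt(τ D_dil))
  maps a measured labeled-population decay time τ to κ; it is the exact
  inverse of the slowest eigenmode of 1D diffusion toward a surface that
  absorbs at rate κ c_den/c_dil (verified against a 1D finite-volume
  solver to 0.03%).  τ at or below the pure-diffusion limit (2d/π)²/D_dil
  raises a diffusion-limited error: no finite κ can reproduce it.
  The inversion presumes the decay is in its quasi-steady (slowest-mode)
  regime, i.e. observation times well past d²/D_dil.
* Crossover radius: R_x = (1/(3κ)) / (1/(π² D_den) + c_den/(3 c_dil D_dil));
  below R_x recovery is interface-limited (uniform recovery), above it
  diffusion-limited (recovery front).

## Sticker-spacer simulator

Polymers are chains of A/B stickers with three pair potentials: a
finitely extensible bond −½KR0²ln(1 − (r/R0)²) between chain neighbours
(implicit spacer), a cosine attraction well −½U0(1 + cos πr/r0) between
opposite types, and a WCA repulsion between same types that enforces
one-to-one binding.  Defaults K = 0.15 kBT/nm², R0 = 10 nm, U0 = 14 kBT,
r0 = 1 nm, ε = 1 kBT, σ = 2 nm, rc = 1.12σ.  All pairs feel the
type-appropriate non-bonded potential, bonded neighbours included.  The
thermal mean bond length under bond + same-type repulsion is 3.95 nm by
radial quadrature (r² e^(−U) weighting), matching the nominal 3.9 nm
chain geometry.

**Integration.**  BAOAB Langevin splitting with unit sticker mass,
friction γ per sticker and kBT = 1; the reduced time unit is γ nm²/kBT at
the defaults and D_free = kBT/γ.  γ = 0, T = 0 reduces to velocity
Verlet (energy drift < 1e-4 over 10⁴ steps is a test invariant).  The
free-particle MSD carries the underdamped correction
6(kT/γ)[t − (1 − e^(−γt))/γ]; diffusion fits must use lags ≫ 1/γ.
Default dt = 0.005 reduced time; instabilities (bond over-extension,
non-finite coordinates) abort with advice to reduce dt.  Non-bonded
forces use a linked-cell pass (particle-centric, minimum image) when the
box is at least three cells across, else an O(N²) loop; the two kernels
agree to 1e-12 in the tests.  No unit map to physical time is imposed:
the literature values this model family is compared against never pin
γ or dt, so simulation outputs are reported in reduced units and only
unit-free ratios are compared quantitatively.

**Scale.**  Production-quality studies of this model use ~1000 polymers
in a 500×50×50 nm box; the package supports that scale but its test
suite runs reduced systems (~60–130 polymers in proportionally smaller
boxes at the same densities) so the full suite stays within minutes.
What the reduced-scale tests show: the dense phase is stable and single-
clustered, one-to-one binding holds, exchange statistics have the right
direction and rough magnitude.  What they do not show: converged
coexistence concentrations, interface widths, or absolute conductances
at the published scale.

**Exchange at reduced binding strength.**  The isolated A-B pair bond
lifetime grows roughly exponentially with U0 (Kramers escape from a
14 kBT well takes ~e^14 reduced time units), so at the default binding
strength no entry event fires within any desk-scale run, and the
survival protocol's lasting-bond criterion (10× the pair lifetime)
cannot be exercised.  Exchange-rate tests therefore run at U0 = 6–7 kBT,
where the dense phase is still stable but entries occur within ~10⁵
steps; bond-lifetime monotonicity is tested at U0 = 4–8 kBT.  Defaults
are unchanged.

## Phase analysis

Clustering follows the contact rule: stickers are connected when they
share a chain or lie within r0 = 1 nm (periodic minimum image, KD-tree);
polymers inherit sticker connectivity; the largest cluster is the dense
phase.  Density profiles recenter each snapshot on the largest cluster's
periodic (circular-mean) centre of mass and histogram polymer centres of
mass along the slab axis or radially.  c_den/c_dil come from plateau
averages; a symmetric double-tanh fit supplies the interface width δ,
the slab half-width, and hence the dilute half-width d — with a minimum
plateau margin of 3 bins to guard against degenerate fits on sharp
synthetic profiles.  δ has no operational definition in the source
literature; the tanh 10–90-style width used here is a package choice and
is configurable.  Diffusion coefficients come from time-averaged
centre-of-mass MSD fit through the origin (MSD = 6Dt over a stated lag
window).  "Bound" stickers are those with an opposite-type sticker
within r0 — a distance criterion, chosen because the attraction range is
the natural energy cutoff.

## Exchange protocols

Survival labeling: polymers outside the largest cluster at t = 0 are
labeled; a labeled polymer is permanently unlabeled when it has held an
A-B bond to a dense-phase polymer — dense at bond formation — for more
than `entry_multiple` (default 10) isolated-pair lifetimes continuously.
Continuity is judged across consecutive frames, so the recording
interval must be ≤ pair_lifetime/5 (enforced).  S(t) is fit with a
decaying exponential; the decay time feeds the slab inversion.  The flux
method divides the entry rate per interface area by c_den; when entries
come from survival bookkeeping, the rate uses exposure correction
(n_entries / ∫N_labeled dt, scaled to the dilute pool).  In-silico FRAP
flags all largest-cluster members at each bleach origin and averages the
unbleached fraction over origins; the droplet radius follows from the
closed-form mass balance 4πR³c_den/3 + (V_box − 4πR³/3)c_dil = N_total.
Bounce events are maximal contact intervals between a polymer and the
dense cluster; an interval without a lasting bond is a bounce.

Open bookkeeping choice: for a polymer whose bond partner later leaves
the cluster, the partner's phase is evaluated at bond formation.

## Synthetic fixtures

Slab and droplet configurations place chain random walks centred on
uniformly sampled centre-of-mass targets, so the target concentrations
are met exactly up to count rounding; single-sticker docking connects
dense chains into one cluster without disturbing the density (the
clustering rule is type-agnostic).  Brownian trajectories have exact D
by construction; recovery-curve fixtures evaluate the finite-pool form;
scripted exchange trajectories realize hand-specified entry schedules for
bookkeeping oracles.  Fixtures are deterministic given a seed.  They
emulate geometry and bookkeeping, not thermodynamics: fixture
configurations are not equilibrium states, so passing fixture tests
validates the measurement code, not the force field.

## Known limitations

* Fixed droplet radius; no partial/off-centre bleach, no moving
  interface, no coarsening, single component, no hydrodynamics.
* The closed-form recovery time degrades below c_den/c_dil ≈ 30 even at
  D_dil = 20 D_den (see above).
* Absolute κ from reduced-scale simulations is not converged; only
  unit-free trends are asserted.
* The tangent slab inversion applied to short trajectories that
  have not reached the quasi-steady decay regime will raise or mislead;
  the package enforces the diffusion-limit precondition but cannot detect
  transients automatically.
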