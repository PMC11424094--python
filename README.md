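# condex

Material exchange between biomolecular condensates and the surrounding
dilute phase: continuum FRAP theory with an interface-conductance
boundary condition, closed-form interface-resistance theory, and a
coarse-grained sticker-spacer Langevin simulator with the measurement
protocols that connect the two.

## Who this is for

Condensates formed by liquid-liquid phase separation constantly exchange
material with the dilute phase, and FRAP (fluorescence recovery after
photobleaching) is the standard probe of that exchange.  Recovery can be
limited by three serial processes: mixing inside the droplet, supply of
molecules from the dilute phase, and passage through the interface
itself.  `condex` is for biophysicists who want to (i) decompose a
measured recovery time into those contributions and infer the interface
conductance κ, (ii) predict when interface resistance dominates (small
droplets recover uniformly; large ones show a diffusion front), and
(iii) study the microscopic origin of interface resistance — the
"bouncing" of molecules whose stickers are already saturated — with
sticker-spacer polymer simulations.

## The model

The bleached population c(r, t) obeys two-phase radial diffusion

    dc/dt = D_den ∇²c   (r < R),      dc/dt = D_dil ∇²c   (r > R),

joined at the droplet surface by flux balance with an interface
conductance κ:

    -D_den ∂c/∂r |_(R-) = -D_dil ∂c/∂r |_(R+) = κ [ c(R-) - (c_den/c_dil) c(R+) ].

The unbleached fraction f(t) inside the droplet recovers on

    τ = R²/(π² D_den) + c_den R²/(3 c_dil D_dil) + R/(3κ),

valid when dilute diffusion is much faster than dense diffusion (within
10% of the full solution for D_dil > 20 D_den in the physical regime).
In a closed system with a finite dilute pool, f(t) ≈ A[1 − exp(−t/(Aτ))]
with plateau A < 1.

Microscopically, polymers of A and B stickers bound by one-to-one A-B
bonds phase separate; a polymer incident from the dilute phase can only
join the dense phase if a pair of *unbound* stickers meets at the
surface.  The resulting conductance,

    κ = 4π r0 δ D_dil n² c_dil / (2 + s + s⁻¹) · (f^A_dil f^B_den + f^B_dil f^A_den),

can sit far below the mean-field value κ0 = c_dil D_dil/(δ c_den); the
suppression κ/κ0 equals a dimensionless sticker-availability parameter u.

## Worked example

The LAF-1 droplet (R = 1 µm, D_den = 0.0017 µm²/s, D_dil = 94 µm²/s,
c_den/c_dil = 1190) recovered from full-droplet photobleaching in 4570 s:

```python
import math
from condex import TwoPhaseParams, recovery_timescale, crossover_radius

p = TwoPhaseParams(R=1.0, D_den=0.0017, D_dil=94.0,
                   c_den=1190.0, c_dil=1.0, kappa=math.inf)
ts = recovery_timescale(p)
print(f"tau_dil = {ts.tau_dil:.2f} s, tau_den = {ts.tau_den:.1f} s, "
      f"tau(no interface resistance) = {ts.tau_total:.1f} s")
kappa = (p.R / 3) / (4570 - ts.tau_dil - ts.tau_den)
print(f"kappa = {kappa:.3g} um/s")
print(f"crossover radius = {crossover_radius(p.with_(kappa=kappa)):.1f} um")
```

prints

```
tau_dil = 4.22 s, tau_den = 59.6 s, tau(no interface resistance) = 63.8 s
kappa = 7.4e-05 um/s
crossover radius = 70.6 um
```

Diffusion alone predicts recovery in about a minute; the measured 76
minutes therefore imply an interface conductance of 7.4×10⁻⁵ µm/s —
recovery is interface-limited for any LAF-1 droplet smaller than ~71 µm.

The same machinery solves the full PDE.  For the simulated A6B6 droplet
system (R = 37 nm in a (286 nm)³ box, c_den = 8.1 mM, c_dil = 0.073 mM,
D_den = 0.013 µm²/s, D_dil = 17 µm²/s, κ = 0.20 µm/s):

```python
from condex import solve_frap_radial, unbleached_fraction, fit_finite_recovery
p = TwoPhaseParams(R=0.037, D_den=0.013, D_dil=17.0,
                   c_den=8.1, c_dil=0.073, kappa=0.20)
field = solve_frap_radial(p, outer_radius=0.1774, domain="finite", t_max=1.0)
A, tau = fit_finite_recovery(unbleached_fraction(field))
print(f"A = {A:.3f}, tau = {tau:.4f} s")
```

prints `A = 0.509, tau = 0.0700 s`: the droplet recovers to only half of
the prebleach level (the closed box holds a finite unbleached pool) on a
70 ms timescale.

A CLI wraps the main entry points: `condex frap`, `condex kappa
{crossover,meanfield,sticker,slab-invert}`, `condex sim`, `condex
analyze`, `condex kappa-sim`, `condex frap-sim`, `condex fixture`.

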