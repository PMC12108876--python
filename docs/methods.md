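# Methods

## Model and assumptions

The scoliotic curve is idealised as a two-dimensional, initially bent
Euler–Bernoulli beam-column in the coronal plane. The midline deviation
between the inferior and superior end vertebrae is the beam's initial
lateral displacement y₀(x); treatment loads superimpose a correction
displacement y₁(x), and the observable is the total y = y₀ + y₁. The
governing equation, in the tension (traction) convention, is

    EI y₁'''' − P_eff y₁'' = −Q + P_eff y₀'' ,  P_eff = P cos α,

on x ∈ [−h, +h], h = L/2. Tension makes the homogeneous solutions
hyperbolic (rate k = √(P_eff/EI)), so increasing traction always damps
the deviation monotonically — there is no buckling branch in this
regime. The model is quasi-static and linear: no viscoelasticity, no
axial rotation or sagittal coupling, no shear deformation term, and the
lateral load acts directly on the spine (force transmission through the
rib cage is not modelled). Q is a uniform intensity; a spatially varying
Q(x) is supported by the numeric solver only.

Boundary conditions. The default is pinned, zero-moment ends:
y₁(±h) = 0 and y₁''(±h) = 0. An alternative mode interprets the end
restraints as rotational springs (end moment proportional to end slope,
EI y₁'' = k_s y₁' at −h and −EI y₁'' = k_i y₁' at +h, with
k_i = 3EI/L_i derived from the length L_i of spine below the curve).
The spring stiffnesses k_s, k_i are stored on `BeamParameters` either
way, but under the default conditions they do not enter the solution;
the spring mode exists for sensitivity studies and is off by default,
because curvature-proportional end conditions collapse to zero end
moment for any non-negative stiffness and that zero-moment form is the
one consistent with the closed-form solution implemented here.

## Initial profile fit

y₀ is a degree-3 polynomial fitted by unweighted ordinary least squares
to the midline points after transforming them to the midpoint-origin
frame in metres (x = (X − X_mid)/1000, y = Y/1000; inferior end at −h).
A cubic is the lowest degree able to represent a single-apex curve with
asymmetric ends, and it is what makes the closed form exact (y₀'''' = 0).
Degree is configurable; degrees above 3 route to the numeric solver.
For the bundled reference patient the fit gives

    y₀(x) = −33.86561 x³ − 3.55545 x² + 0.31890 x + 0.03345   (RMSE 1.2 mm),

with endpoint residuals below 1.5 mm — the fitted curve does not pass
exactly through the zero end deviations, which is expected of a free
(unconstrained) least-squares fit.

## Closed-form solution and numeric oracle

With a cubic y₀, the particular solution is −y₀ + Q x²/(2 P_eff), and
the total displacement reduces to

    y(x) = c₀ + c₁ x + c_cosh cosh(kx) + c_sinh sinh(kx) + Q x²/(2 P_eff),

with the four constants fixed by a 4×4 linear system from the boundary
conditions. The hyperbolic basis (rather than raw exponentials) keeps
the system well scaled; an overflow guard rejects k·h > 350, far beyond
any physiological load. P_eff = 0 is a degenerate case (pure bending)
answered by the numeric solver.

The independent check is a second-order central finite-difference
discretisation of the same fourth-order boundary-value problem, with the
end-moment (or spring) conditions imposed by one-sided second-order
stencils, solved as a sparse banded system. Default 2001 nodes: on this
grid the two routes agree to better than 10⁻⁶ m across the tested load
range, while truncation error still dominates the (n⁴-growing) round-off
amplification of the biharmonic-type operator; convergence checks use
coarser grids (251 → 501 nodes shows the expected ≈4× error reduction)
because much finer grids hit that round-off floor.

## Load planning

The required total axial load is the smallest P in a bracket (default
1–10⁶ N) for which y(x*; P, Q) equals the target displacement (default
0) at the assessment station x* (default 0.095 m, near the superior end
— where the zero crossing used for the reference reproduction occurs;
the apex, x = 0.035 m for the reference patient, is equally supported).
A coarse geometric scan locates the first sign change and Brent's method
refines it to 0.5 N — sub-newton precision carries no physical meaning.
Per-session loads are body-weight fractions with g = 10 m/s²: this
rounding is deliberate, since the reference protocol's 40% of 65 kg is
exactly 260 N only at g = 10. Session counts are the plain ceiling of
total over per-session load; no mechanical model of how per-session
forces accumulate is implied. Pulling at angle α from the spine axis
inflates the total load by 1/cos α for the same axial component.

## Moment analysis

At the apex of a curve with Cobb angle θ and end-vertebra chord d, the
axial load's bending moment is M_P = P (d/2) sin(θ/2) and the lateral
three-point load's is M_Q = (Q/2)(d/2) cos(θ/2) (each end vertebra
reacts half of Q; symmetric support assumed). They are equal at
θ* = 2 arctan(Q/(2P)), independent of d. The default comparison uses
equal load magnitudes, giving θ* = 2 arctan(1/2) ≈ 53.13°; the clinical
literature quotes this threshold as ≈53.3°, a figure-reading-level
difference. `cobb_from_profile` estimates θ from the fitted profile as
the angle between the end tangents — a convenience for synthetic
studies, not a substitute for radiographic Cobb measurement.

## Synthetic data

The generator emulates the structure of a digitized midline: axial
stations at a fixed interval (7 mm default), zero deviation at both end
vertebrae, a single interior apex of programmed magnitude and location,
and seeded i.i.d. Gaussian noise on Y only (axial stations are
instrument-fixed). Two shape families bracket plausible single curves: a
cubic root-factor product (exactly representable by the fit, so recovery
is exact without noise) and an apex-warped half-sine (non-polynomial
control). The generator does not attempt anatomical realism — no double
curves, no vertebra-level structure, no correlated digitisation error —
so passing recovery tests demonstrates the pipeline's numerics, not its
robustness to real radiographic artefacts.

## Numerical choices and defaults

| Parameter | Default | Why |
| --- | --- | --- |
| EI | 15.1 N·m² | reference patient's bending stiffness (cadaveric lumbar data) |
| L, Li | 0.196 m, 0.042 m | reference patient's curve and sub-curve lengths |
| axial / lateral fraction | 0.40 / 0.25 of body weight | recommended per-session maxima |
| g | 10 m/s² | protocol rounding; 9.81 would give 255.06 N, not 260 N |
| station x* | 0.095 m | reproduction default; configurable |
| root bracket / tolerance | (1, 10⁶) N / 0.5 N | covers the physical regime; sub-newton precision meaningless |
| FD nodes | 2001 (odd, ≥201) | truncation ≪ 10⁻⁶ m without hitting round-off |
| overflow guard | k·h ≤ 350 | cosh overflow margin in double precision |
| max-deviation tie-break | first attaining point | deterministic reporting |

## Limitations

Two-dimensional, linear, quasi-static; stiffness taken from sagittal
lumbar measurements and applied to a coronal thoracolumbar problem; the
enormous required totals (tens of kN) are cumulative bookkeeping
quantities of the protocol, not forces ever applied at once; single-curve
(single-apex) geometry only. Results for patients other than the bundled
reference require their own digitized midline and constants.
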