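# Methods

## Model and assumptions

stenoflow evaluates steady, laminar, fully developed, incompressible
axisymmetric flow of a Casson fluid through a rigid tube of dimensionless
reference radius R₀ = 1 whose wall radius H(z) deviates from R₀ only inside
cosine-shaped abnormal segments (stenoses and dilatations).  All quantities
are dimensionless: radii scale with R₀, axial lengths with the tube length,
viscosity μ = 1.

The closed form rests on the **mild-lesion (locally Poiseuille)
approximation**: at every axial station the flow is treated as fully
developed pipe flow at the local radius H(z), valid when lesion heights are
small against both the lesion length and the vessel radius.  The package
*reports* the ratios |δᵢ|/Lᵢ and |δᵢ|/R₀ (`validate_mild_stenosis`,
default advisory threshold 0.3, strict mode available) rather than
enforcing them, because the anchor parameter set used by the source
figures (δ up to 0.15–0.2 with L = 0.2) itself violates a literal reading
of the smallness condition.

The Casson constitutive law relates shear stress and shear rate through
√τ = √τ₀ + √(μ(−du/dr)) above the yield stress τ₀; below it the fluid
moves as a rigid plug.  The plug radius r₀ is the free rheology parameter
(as in the swept figures); the converter r₀ = 2τ₀/|P| from the plug force
balance is provided but never applied implicitly, and no axially varying
r₀(z) coupling is attempted.

## Drive and the two sign conventions

The net axial forcing is D = M + f + P with magnetization constant M,
gravity term f = F sin φ, and pressure gradient P.  The flux law is
Q = g(H, r₀)·D with conductance

g(H, r₀) = H³r₀/6 + H⁴/8 − r₀⁴/168 − (2/7)√r₀ H^{7/2},

positive for r₀ < H and zero at r₀ = H (fully plugged, treated as a valid
degenerate state for velocity/flux but an error for the inversion).

Two inversions of the flux law are shipped:

- **paper** (default): P = −Q/g + (M + f), τ_w = (Q/2g)(√H−√r₀)² + (M + f).
  These are the printed forms of the source study, and they are the forms
  whose parameter trends match that study's figures.  Note they are *not*
  the algebraic inverse of Q = g·D; the package reproduces them as printed.
- **derived**: P = Q/g − (M + f), the self-consistent inversion; τ_w is
  then exactly −μ du/dr at the wall with no additive body-force term.

With M = f = 0 the two modes are sign-opposites and all normalized ratios
coincide.  Two consequences of the paper convention worth knowing:

1. **Impedance pole.**  The uniform-tube pressure gradient
   −Q/g(1, r₀) + (M + f) crosses zero at r₀ ≈ 0.118 (caption forcing) or
   M ≈ 3.12, where λ̄ = λ/λₙ has a pole and the curve families invert.
   Impedance sweeps therefore use r₀ ∈ [0.15, 0.4] and M ∈ [0, 3]; all
   other responses use the full default grids (below).  Derived mode has
   no pole.
2. **Retrograde throat drive.**  At the caption defaults the paper-mode
   drive D = 2(M+f) − Q/g is negative at the stenosis throat (H = 0.9), so
   the local velocity is negative there.  Trend directions are unaffected,
   but the radial no-slip profile check is evaluated at the widest
   unobstructed station (H = R₀, forward drive), matching the generic
   statement that velocity is highest at the center and zero at the wall.

## Axial assembly

Δp integrates P(z) by composite Simpson on panels aligned with the segment
boundaries (H is smooth inside panels but has derivative kinks at αᵢ, βᵢ),
with ≈2001 nodes by default distributed proportionally to panel length
(even counts per panel).  Node doubling changes Δp by ≪ 1e−8 relative at
the defaults.  λₙ and τ_wn use H ≡ 1 **over the same domain length** as the
lesioned run, so the normalizations λ̄ = λ/λₙ and τ̄_w = τ_w/τ_wn are exact
ratios (both equal 1 identically for zero-height lesions, in both modes).

The domain is [0, max(1, β_last)] by default — the caption-default two-lesion
layout ends at β₂ = 1.2 and is never truncated mid-bump — and an explicit
`domain_length` (e.g. the literal unit interval) is honoured as given.

τ̄_w is reported at a single station, by default the **throat** (first
segment's midpoint).  In sweeps, the station resolves to the midpoint of
the lesion whose height is being swept: wall shear and velocity at the
stenosis midpoint are locally independent of the dilatation height, so a
dilatation-height sweep evaluated there would be flat.

## Sweep and figure defaults

The source prints no sweep grids or axis values, so grids are the package's
choice: 21-point uniform grids over δ ∈ [0, 0.2], M ∈ [0, 4], φ ∈ [0, π/2],
r₀ ∈ [0.01, 0.4] (impedance exceptions above), bracketing every caption
value; family curves at δ ∈ {0.05, 0.10, 0.15}; fixed values at the caption
anchors (r₀ = 0.2, M = 2.0, F = 0.3, φ = π/6, Q = 0.1, the non-swept lesion
height 0.1).  Velocity responses report both the centerline value and the
value at r = 0.2 (the radial position the captions print), since the
figures do not state which radius is plotted.  The figure suite regenerates
the 24 swept figures (fig02–fig25) as deterministic CSVs plus plots; two of
the source captions print M = 0.2, r = 2.0 — transposed relative to every
sibling caption, and unrunnable literally because a plug radius of 2.0
exceeds the lumen — so those figures use the transposed values and the
emitted `metadata.json` records the substitution.

## Trend expectations

The shipped monotonicity fixture encodes the directions stated by the
source's abstract and figure narrative: λ̄ and τ̄_w increase with stenosis
height and decrease with dilatation height; velocity decreases with
stenosis height, increases with dilatation height, with M, and with φ; the
radial profile decreases to zero at the wall.  The source's concluding
summary states the *opposite* direction for λ̄ and τ̄_w versus stenosis
height; the abstract/figure-level direction is the one encoded, and this
conflict is deliberately not reconciled silently.  Directions are tested as
sign conditions on successive finite differences per family curve (strict,
except the radial profile where the plug core is exactly flat; a 1e−12
allowance absorbs last-ulp rounding at the plug boundary).

## Verification strategy

Every closed form is guarded by an independent brute-force oracle
(`stenoflow.oracles`, also behind `stenoflow verify`):

- flux: adaptive quadrature of 2∫u r dr against g·D, tolerance 1e−8
  relative on a 48-point (H, r₀, D) grid (H ∈ {0.7, 0.85, 1.0, 1.1},
  r₀ ∈ {0, 0.1, 0.2, 0.3}, D ∈ {0.5, 1, 2} — stenosed, normal and dilated
  stations at caption scale);
- wall shear: Richardson-extrapolated one-sided finite difference of the
  velocity at r = H, tolerance 1e−6 relative;
- constitutive law: residual of √τ − √τ₀ − √(−du/dr) with τ = D r/2,
  tolerance 1e−8 absolute;
- limit suite: Newtonian collapse (parabola, g = H⁴/8, τ_w = 4Q/H³
  simultaneously), fully plugged degenerate state, exact no-slip, and the
  lesion-free normalization identities, at 1e−12.

The tolerances separate transcription-level errors (order-one effects)
from quadrature/finite-difference noise.  Oracles call only the velocity
closed form, never the conductance or shear closed forms they check;
injecting a corrupted conductance coefficient makes the flux check fail
(exercised as a mutation test).

## Determinism and problem sizes

The entire pipeline is closed-form plus fixed quadrature: repeated runs are
bit-identical (CSVs are written with explicit float formatting), and there
is no randomness anywhere in the model.  Default problem sizes — 2001
quadrature nodes, 21-point sweep grids, 3-value families, 51-point radial
profiles — were chosen so a full figure suite plus oracle run completes in
seconds while quadrature error stays near machine precision.

## Known limitations

- The mild-lesion closed form ignores flow separation, recirculation and
  entrance effects that a real post-stenotic region exhibits; trends, not
  pointwise fields, are the meaningful output at caption-size lesions.
- The paper-mode conventions are reproduced as printed, including their
  pole and retrograde-drive artifacts documented above.
- M is a given dimensionless constant; no dimensional magnetization
  physics is modelled.  Steady flow only; rigid walls; axisymmetric
  non-overlapping lesions on a uniform baseline radius.
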