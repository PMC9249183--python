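# stenoflow

Closed-form hemodynamics of a steady, incompressible **Casson (yield-stress)
fluid** — the standard low-shear-rate blood model — flowing through an
inclined axisymmetric vessel whose wall carries **cosine-shaped stenoses**
(lumen narrowings) and **post-stenotic dilatations** (aneurysm-like
widenings), under a constant body-force field (a magnetization constant *M*
and the axial gravity component *F* sin *φ* of the inclination).

It is aimed at biofluid-mechanics researchers and students who want the
classical mild-stenosis closed forms — flow impedance, wall shear stress and
velocity profiles, and how they respond to lesion height, plug-core radius,
magnetization and inclination — as tested, scriptable code rather than a
one-off computer-algebra notebook.

## Model

Wall geometry, with segment *i* of signed height δᵢ (positive = stenosis,
negative = dilatation), length *Lᵢ* and upstream gap *dᵢ*, occupying
[αᵢ, βᵢ]:

    H(z) = R0 − (δᵢ/2) [1 + cos(2π (z − αᵢ − Lᵢ/2) / Lᵢ)]   for αᵢ ≤ z ≤ βᵢ
    H(z) = R0                                                 elsewhere

At each station the Casson solution has an unyielded **plug core** of radius
r₀ moving rigidly, surrounded by a sheared annulus.  With net axial drive
D = M + f + P (f = F sin φ, P = −∂p/∂z sign convention folded in, μ = 1):

    u(r) = (D/2) [ (H² − r²)/2 − (4/3)√r₀ (H^{3/2} − r^{3/2}) + r₀ (H − r) ],  r₀ ≤ r ≤ H
    Q    = g(H, r₀) · D,     g = H³r₀/6 + H⁴/8 − r₀⁴/168 − (2/7)√r₀ H^{7/2}

(the Buckingham–Reiner-type flux law).  Inverting for the pressure gradient
and integrating along the tube gives the pressure drop Δp, impedance
λ = Δp/Q, and wall shear stress τ_w = (Q/2g)(√H − √r₀)², each normalized by
its uniform-tube (H ≡ 1) value to λ̄ and τ̄_w.  Two sign conventions for the
inversion are shipped (`mode="paper"`, the default, and `mode="derived"`);
see `docs/methods.md`.

## Worked example

```python
import stenoflow as sf

cfg = sf.caption_defaults()          # two lesions, r0=0.2, M=2, F=0.3, phi=pi/6, Q=0.1
sol = sf.solve(cfg.flux, cfg.geometry, cfg.plug_radius, cfg.forces, cfg.mode)
print(f"lambda_bar = {sol.normalized_impedance:.4f}")
print(f"tau_bar_w  = {sol.normalized_wss:.4f}")
print(f"delta_p    = {sol.pressure_drop:.4f}")
```

prints

```
lambda_bar = 1.0587
tau_bar_w  = 1.0758
delta_p    = -1.4273
```

λ̄ > 1: the 10%-height stenosis raises flow resistance about 5.9% above the
uniform-tube value (the 10% dilatation partly offsets it).  τ̄_w > 1: wall
shear at the stenosis throat is about 7.6% above its uniform-tube value.
Δp < 0 reflects the printed sign convention at the default forcing.

The same numbers from the shell, plus sweeps and figure regeneration:

```bash
stenoflow hemodynamics --out summary.json
stenoflow sweep --param delta1 --family delta2 --out sweep.csv
stenoflow figures --out-dir figures/       # 24 CSV/PNG pairs + trend report
stenoflow verify --out report.json         # brute-force oracle suite
```

A config file (YAML or JSON) overrides any default; the schema with the
caption-default values is:

```yaml
geometry:
  segments:
    - {kind: stenosis,   height: 0.10, length: 0.2, gap: 0.2}
    - {kind: dilatation, height: 0.10, length: 0.2, gap: 0.6}
  domain_length: auto
casson: {plug_radius: 0.2}
forces: {M: 2.0, F: 0.3, phi: 0.5235987755982988}
flux: 0.1
mode: paper
```

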