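# fieldpot

Field-dependent machine-learned interatomic potentials: one model yields
the potential energy of an atomistic system in a uniform external electric
field and — as exact derivatives of that single energy — the atomic forces,
the dipole moment and the polarizability tensor. The package targets
method development and simulation studies of field-driven phenomena:
in-field vibrational spectroscopy (IR and Raman from time-correlation
functions), field-dependent dynamics, and periodic systems where the
dipole itself is multivalued and only forces are trustworthy training
targets.

## The model

Atomic environments are encoded as embedded atom densities: for atom *i*,
angular channel (l<sub>x</sub>, l<sub>y</sub>, l<sub>z</sub>) with
l = l<sub>x</sub>+l<sub>y</sub>+l<sub>z</sub> ≤ L, and contracted radial
function *n*,

```
ρᵢⁿ = Σ_l Σ_{lx+ly+lz=l}  l!/(lx!·ly!·lz!) ·
      [ Σ_m dₘⁿ ( Σ_{j≠i} c_j φᵐ_{lxlylz}(r_ij) + c_ε φ_{lxlylz}(ε) ) ]²
```

where `φᵐ_{lxlylz}(r) = x^lx y^ly z^lz exp(−α_m (r−r_m)²) f_c(r)` is a
Cartesian Gaussian-type orbital with a squared-cosine cutoff `f_c`, and the
applied field enters as a *pseudo-orbital* — the bare monomial
`ε_x^lx ε_y^ly ε_z^lz` with its own coefficient c<sub>ε</sub>, added inside
the square like one more neighbor. The descriptor therefore depends on
distances, bond angles, the field strength |ε| and the angles between ε and
each bond: invariant when molecule and field rotate together, sensitive
when the field rotates alone. Orbital coefficients c_j (and c<sub>ε</sub>)
can be refined by message passing: each iteration re-predicts them from the
atom's current descriptor. Per-element feed-forward networks map
descriptors to atomic energies, E = Σᵢ Eᵢ.

Response properties are derivatives of that one scalar:

```
F = −∂E/∂r        μ = −∂E/∂ε        α = −∂²E/∂ε∂ε
```

evaluated by automatic differentiation (numpy/autograd), so they are exact
for the model and mutually consistent. Training minimizes
λ_V ΔE² + λ_F‖ΔF‖² + λ_μ‖Δμ‖² + λ_α‖Δα‖² with per-property weights that
decay linearly as the plateau learning-rate schedule progresses. Because
forces are single-valued even when the periodic dipole is not, force-only
training (λ_F alone) learns the full field-dependent surface; the dipole
is then recovered from −∂E/∂ε up to a field-dependent constant.

Units: Å, eV, V Å⁻¹, e·Å (dipole; 1 e·Å = 4.803204 D), e·Å² V⁻¹
(polarizability), fs, amu.

## A worked example

`examples/04_force_only_dipoles.py` trains on *forces only* in a periodic
box of dipolar diatomics whose stored dipole labels are corrupted by
polarization-quantum jumps, then reads the dipole back out of the energy's
field gradient:

```
training force RMSE: 17.12 meV/Å (80 periodic configurations, forces only)
dipole vs continuous truth along a 60-frame trajectory:
  min Pearson r over components: 0.99984
  offset-removed residual: 0.72% of the dynamic range
greedy branch correction of the wrapped labels: max error 8.88e-16 e·Å (up to one global quantum)
```

The model never sees a dipole label, yet its −∂E/∂ε tracks the continuous
dipole; the greedy branch-correction utility independently repairs the
wrapped labels to machine precision. The other examples walk through the
descriptors and their symmetry (01), responses from one energy function
(02), single-configuration training with full field-curve extrapolation
(03), and MD-based IR/Raman spectra (05).

A thin CLI wraps the same library calls:

```
fieldpot synth --kind molecule -n 100 --out data.xyz
fieldpot --config run.yaml train --data data.xyz --out model.ckpt
fieldpot predict --model model.ckpt --data data.xyz --out pred.xyz
fieldpot md / spectra / check-derivatives ...
```

Data files use an extended-XYZ dialect (`Lattice`, `pbc`, `field`,
`energy`, `dipole`, row-major `polarizability` in the comment line; per-atom
`species x y z [fx fy fz]`).

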