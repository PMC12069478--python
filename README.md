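# hypertab

Invariant-based hyperelastic constitutive modeling driven by plain-text
parameter tables, for soft-tissue and soft-matter mechanics.

Finite-element analysis of soft materials — brain, skin, arteries, heart
valves, myocardium — hinges on the constitutive model: the map from the
deformation gradient **F** to the Cauchy stress **σ**. Implementing a new
model normally means deriving and coding the stress and the fourth-order
tangent by hand, which is error-prone and restricts model innovation to
specialists. `hypertab` removes that step: *one* evaluation engine covers a
very large family of anisotropic, (quasi-)incompressible hyperelastic models,
and an individual model is nothing but a small table of numbers.

## The model family

Deformation is measured through 15 invariants of the isochoric/volumetric
split `F = J^(1/3) I · F̄`: the isotropic pair `Ī₁ = tr b̄`,
`Ī₂ = ½(Ī₁² − b̄:b̄)`, the volumetric `I₃ = J²`, and — for up to three fiber
families with reference unit directions `n⁰_α` — the fiber invariants
`Ī₄(αβ) = C̄ : n⁰_α ⊗ n⁰_β` and `Ī₅(αβ) = C̄² : n⁰_α ⊗ n⁰_β` with β ≥ α,
numbered 1–15 by `NINV = 4 + 2(α−1) + β(β−1)` for family 4 (one more for
family 5). The free energy is a sum of decoupled terms, one per table row,

    ψ = Σₖ w₂ₖ · f₂( f₁( f₀( Ī_iₖ − Ī_i₀ ; w₀ₖ ) ) ; w₁ₖ ),

where each deviation from the reference value (3, 3, 1, or ζ_αβ = n⁰_α·n⁰_β)
passes through three nested activations: identity / Macauley bracket ⟨∘⟩ /
absolute value, then an integer power, then identity / `exp(∘)−1` /
`−ln(1−∘)`. Stress and tangent follow exactly:

    σ = (1/J) ∂ψ/∂F · Fᵗ = Σᵢ (∂ψ/∂Īᵢ) Gᵢ,      ℂ = ∂σ/∂ε,

with closed-form per-invariant direction tensors `Gᵢ` and an analytically
assembled consistent tangent (spatial-consistent or Jaumann convention).
Each row is polyconvex by construction for admissible selectors and
non-negative weights, and the ζ-corrected inputs guarantee a stress-free
reference configuration a priori.

A material is a text file:

```
*PARAMETER TABLE, TYPE="UNIVERSAL_TAB"
** kfinv, kf0, kf1, kf2, w0, w1, w2
1, 1, 1, 1, 1.0, 1.0, 0.5      ** C10 (I1bar - 3)
3, 1, 2, 1, 1.0, 1.0, 2.0      ** (1/D1)(I3 - 1)^2
```

An optional `MIXED_INV` block defines mixed invariants (ids 101, 102, …) as
linear combinations of the base deviations — this is how fiber-dispersion
(kappa-weighted `Ī₁`/`Ī₄`) models are expressed.

The built-in catalog ships the classical models (neo-Hooke, Mooney-Rivlin,
Yeoh, polynomial, Holzapfel, Kaliske, Holzapfel dispersion) and published
best-fit soft-tissue models for gray/white brain matter, porcine skin, aortic
media/adventitia, tricuspid valve leaflets, and human myocardium, each with
its fitted parameters and default fiber frame.

Beyond evaluation, the package provides homogeneous-deformation drivers
(uniaxial / equibiaxial / biaxial-ratio / simple and triaxial shear /
volumetric, with traction-free lateral faces solved by Newton iteration on
the engine's tangent) and weight calibration against stress–stretch data,
including L1-sparsified fitting — the desk-scale analogue of constitutive
model discovery from libraries of 2¹⁶–2³² candidate term combinations.

## Worked example

Dump a cataloged myocardium model and pull a uniaxial stress curve:

```python
import hypertab as ht

print(ht.serialize(ht.catalog("heart_discovered")))
curve = ht.run_protocol(
    ht.catalog("neo_hooke", C10=1.0),          # incompressible: no slot-3 row
    ht.LoadingProtocol(mode="uniaxial", start=1.0, end=2.0, steps=6),
)
print(curve.data[["control", "F22", "s11", "psi"]].to_string(index=False))
```

```
*PARAMETER TABLE, TYPE="UNIVERSAL_TAB"
2, 1, 2, 1, 1.0, 1.0, 2.581
4, 2, 2, 2, 1.0, 21.151, 0.08098907853056593
14, 2, 2, 2, 1.0, 4.371, 0.31503088538091967
6, 1, 2, 2, 1.0, 0.508, 0.48622047244094485

 control      F22      s11      psi
     1.0 1.000000 0.000000 0.000000
     1.2 0.912871 1.213333 0.106667
     1.4 0.845154 2.491429 0.388571
     1.6 0.790569 3.870000 0.810000
     1.8 0.745356 5.368889 1.351111
     2.0 0.707107 7.000000 2.000000
```

The driver solved the lateral stretch (`F22 = λ^(-1/2)`, here the analytic
incompressible solution) and eliminated the pressure through the
traction-free faces; the axial stress matches the classical closed form
`σ₁₁ = 2 C₁₀ (λ² − 1/λ)` — 7.0 kPa at λ = 2 — and `psi` is the stored energy
`C₁₀(Ī₁ − 3)`.

The same operations are available from a shell:

```sh
hypertab catalog --name neo_hooke --out nh.tab
hypertab eval --table nh.tab --protocol uniaxial --range 1.0:2.0:11 --out curve.csv
hypertab verify --table nh.tab --fd-check --objectivity
```

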