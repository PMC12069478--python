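# Methods

## Constitutive framework

The engine evaluates hyperelastic free energies that are sums of decoupled,
single-invariant terms. Kinematics uses the multiplicative volumetric /
isochoric split `F = J^(1/3) I · F̄`, `J = det F > 0`, with isochoric
Cauchy–Green tensors `b̄ = F̄ F̄ᵗ` and `C̄ = F̄ᵗ F̄`. Fifteen invariant slots are
supported: `Ī₁ = tr C̄`, `Ī₂ = ½(Ī₁² − C̄:C̄)`, `I₃ = det C = J²`, and for up
to three unit fiber directions the stretch and square-stretch measures
`Ī₄(αβ) = C̄ : n⁰_α ⊗ n⁰_β`, `Ī₅(αβ) = C̄² : n⁰_α ⊗ n⁰_β`, β ≥ α. The
coupling entries (α ≠ β) are pseudo-invariants: they flip sign with a fiber
direction flip, and the engine stores them with the sign of the declared
vectors — no absolute value is applied at the kinematic level, leaving the
sign handling to each term's zeroth-layer activation. Slot numbers follow
`4 + 2(α−1) + β(β−1)` (family 4) and one more for family 5, a bijection onto
4–15; with fewer than three fiber families the numbering is unchanged and
the unavailable slots are flagged, so a table row touching one is rejected
at validation rather than silently zeroed.

Every term acts on the deviation of its invariant from the reference value
(3, 3, 1, or `ζ_αβ = n⁰_α · n⁰_β`), which makes the energy — and, together
with the derivative conventions below, the stress — vanish identically at
`F = I`.

### Activation chain

Per table row, `ψ_k = w₂ f₂(f₁(f₀(w₀·dev)))` with

| layer | selector 1 | selector 2 | selector 3 |
|-------|------------|------------|------------|
| f₀    | identity   | Macauley ⟨∘⟩ | absolute value |
| f₁    | power m = 1 | m = 2 | … any integer m ≥ 1 |
| f₂    | `w₁·(∘)`   | `exp(w₁·∘) − 1` | `−ln(1 − w₁·∘)` |

First and second derivatives are propagated analytically; `f₀'' ≡ 0` for all
three branches. Two conventions at the `f₀` kink (`dev = 0`) matter:

* the **first** derivative of ⟨∘⟩ and |∘| at exactly 0 is taken as 0 (the
  printed forms `|x|/x` are undefined there). This keeps the reference state
  exactly stress-free for every admissible row, including hypothetical
  linear Macauley fiber terms.
* the **squared slope** of `f₀` entering the second-derivative chain is taken
  as the active-side limit `w₀²` at 0. The curvature of a gated term is
  discontinuous at the kink; choosing the tension-side limit initializes
  Newton solvers with the physical stiffness — e.g. a fiber row
  (⟨∘⟩, m = 2, exp) with weights (1, k₂, k₁/2k₂) reports curvature k₁ at zero
  fiber-stretch deviation, the exact second derivative of
  `(k₁/2k₂)(exp(k₂ x²) − 1)`, instead of the compression-side 0.

The logarithm branch is only defined for `w₁·f₁ < 1`. Evaluation raises a
recoverable domain error carrying the offending value rather than clamping;
drivers treat it as a step-size cut. `w₀` is implemented as input scaling,
`f₀(w₀·dev)`; every cataloged table uses `w₀ = 1`, so this choice does not
affect any shipped model.

Mixed invariants (ids ≥ 101) are linear combinations
`Σⱼ cⱼ · devⱼ` of the base deviations — enough to express
dispersion-type `κ(Ī₁−3) + (1−3κ)(Ī₄−1)` inputs. Because they are linear,
the chain rule is exact: first derivatives redistribute onto base slots with
the coefficients `cⱼ`, and the second derivative generates cross terms
`cⱼ cⱼ' ψ_k''` between base slots, kept in a sparse map consumed by the
tangent assembly.

### Stress

All invariants are functions of `C = FᵗF`; the engine carries exact first
and second derivatives `∂Ī/∂C`, `∂²Ī/∂C∂C` in closed form (products of
`I3^(−p)` prefactors, `C⁻¹`, and constant fiber dyads). The Cauchy stress is
the push-forward

σ = Σᵢ (∂ψ/∂Īᵢ) Gᵢ, Gᵢ = (2/J) F (∂Īᵢ/∂C) Fᵗ,

which equals `(1/J) ∂ψ/∂F · Fᵗ` exactly. A frequently printed shortcut omits
the deviatoric projector on the isochoric dyad terms; this engine
deliberately implements the exact chain rule through the `J^(−1/3)` split, so
every isochoric `Gᵢ` is traceless automatically (the isochoric invariants are
homogeneous of degree zero in a volumetric rescaling, hence `∂Ī/∂C : C = 0`).
Only the exact form satisfies the finite-difference contract
σ = (1/J)∂ψ/∂F·Fᵗ that the test suite enforces at ~10⁻⁹ relative error.
For the same reason the symmetrized `Ī₅` dyad is
`n̄_α ⊗ b̄n̄_β + b̄n̄_α ⊗ n̄_β + n̄_β ⊗ b̄n̄_α + b̄n̄_β ⊗ n̄_α` — the exact
derivative — rather than the occasionally mis-printed variant with a
repeated β index.

### Tangent

The material elasticity tensor is assembled as

ℂ = 4 [ Σᵢ ψᵢ'' ∂Īᵢ/∂C ⊗ ∂Īᵢ/∂C + Σᵢ<ⱼ xᵢⱼ sym(∂Īᵢ/∂C ⊗ ∂Īⱼ/∂C) + Σᵢ ψᵢ' ∂²Īᵢ/∂C∂C ],

with `xᵢⱼ` the sparse mixed-invariant cross terms, then pushed forward to
the spatial configuration and completed with geometric stress terms. Two
conventions are shipped:

* **spatial-consistent** (default): the exact directional derivative of the
  Cauchy stress under a symmetric velocity-gradient perturbation,
  `C₄ : δε = d/dh σ((I + h δε) F)`. This is what the drivers' Newton loops
  consume, and it is verified against directional finite differences for
  every catalog model. Note that the pure Cauchy derivative contains a
  `− σ ⊗ I` volume term, so its 6×6 form is exactly major-symmetric only at
  stress-free states.
* **jaumann**: the co-rotational rate form used by Abaqus-style host codes —
  push-forward plus symmetrized `δ ⊗ σ` terms, differing from the
  spatial-consistent tangent by exactly `σ ⊗ I`. It is major-symmetric for
  hyperelastic input at every state; the two conventions coincide for
  isochoric perturbations and at the reference.

The reduced 6×6 matrix uses Voigt ordering (11, 22, 33, 12, 13, 23) with
engineering shear strain.

## Parameter tables

The text dialect has two block types. `UNIVERSAL_TAB` rows carry
`kfinv, kf0, kf1, kf2, w0, w1, w2` (4 integers + 3 floats); `MIXED_INV` rows
carry a row number and 15 coefficients, column j being the coefficient on
base slot j; row r defines mixed id `100 + r`. Keyword matching is
case-insensitive and quotes are optional on input; output is emitted in the
canonical uppercase quoted form with shortest-round-trip floats, so
parse ∘ serialize ∘ parse is the identity. `**` comments and blank lines are
ignored; malformed rows fail with the line number.

Validation flags negative `w₂` — and negative `w₁` outside the logarithm
branch — as polyconvexity warnings rather than errors, because the standard
three-row volumetric table `(I₃−1) + ½(I₃−1)² − ln I₃` legitimately uses
`w₁ = −1` on its logarithmic row. A missing slot-3 row downgrades the model
to incompressible-only and is reported as a warning. Unit tags (kPa / MPa)
are metadata; no conversion is performed, since published soft-tissue tables
mix both.

Where a published energy expression and its printed parameter table disagree
by a constant factor on a linear term, the catalog follows the printed
table (the table is the executable interface; the discrepancy only rescales
one weight). Zero-weight rows of published models are omitted, as the table
format permits.

## Homogeneous-deformation drivers

Models without a volumetric row run exactly incompressible: lateral
kinematics enforce `J = 1` and the indeterminate pressure is eliminated
through the zero-traction condition of the protocol (for simple shear,
through the traction-free out-of-plane face, a documented convention — the
in-plane shear component is pressure-independent either way). Models with
volumetric rows run fully compressible with no constraint. This mirrors how
published soft-tissue tables are written: the brain, skin, artery, valve and
myocardium tables carry no volumetric rows.

Lateral stretches are found by Newton iteration on the lateral Cauchy stress
components, with the Jacobian taken from the spatial-consistent tangent
(`∂σᵤᵤ/∂λᵥ = [C₄ : eᵥ⊗eᵥ]ᵤᵤ / λᵥ`, with the `J = 1` constraint folded into
the perturbation direction for incompressible runs). Residuals are driven
below `10⁻⁹ · max(1, |σ_axial|)`. Continuation warm-starts each step from the
previous solution; a control value at the reference re-initializes from the
undeformed state, which solves the traction condition exactly. On Newton
failure or a log-domain violation the step is halved up to five times, after
which the curve is truncated and the reason recorded. Curves are written as
delimited text with one header line and 17-significant-digit floats, and are
deterministic given identical inputs.

Triaxial shear planes may be named by the fiber-frame letters f, s, n
(f = e₁, s = e₂, n = e₃), mirroring myocardial testing conventions: mode
"fs" is `F = I + γ e₁ ⊗ e₂`.

## Synthetic experiments and calibration

`simulate_dataset` runs the drivers and records, per point, the realized
deformation gradient and the protocol's stress channels (axial for
uniaxial, both in-plane normals for biaxial, the in-plane shear for shear),
with seeded additive or multiplicative Gaussian noise on the stress. It
emulates homogeneous, perfectly aligned, noise-in-stress-only experiments.
It does **not** emulate stretch measurement error, specimen-to-specimen
variability, viscoelastic or preconditioning effects, or boundary-effect
inhomogeneity — so passing recovery tests demonstrate identifiability and
optimizer correctness under the stated noise model, not robustness to every
artifact of real tissue testing.

Fitting evaluates candidate models at the *stored* deformation gradients,
eliminating the pressure through the experiment's declared traction-free
channel. With the kinematics frozen per point, predictions are exactly
linear in the outer weights `w₂` and nonlinear only in the inner weights
`w₁` of exponential/logarithmic rows. The optimizer exploits the split:

* the penalized linear subproblem (least squares + `α‖w₂‖₁`, optionally
  `w₂ ≥ 0`) is solved exactly by cyclic coordinate descent with soft
  thresholding at `α/2`;
* free `w₁` are fitted by bounded trust-region least squares (scipy TRF);
  for smooth problems (`α = 0`) a final joint trust-region solve over
  (w₁, w₂) follows a linear warm start, while for `α > 0` the two half-steps
  alternate — both are descent steps, so the logged penalized objective is
  non-increasing.

Templates with ≥ 2 free nonlinear weights restart from 5 seeded lognormal
perturbations; the best objective wins, ties broken by smaller weight norm.
Goodness of fit is the coefficient of determination per experiment channel,
aggregated as the unweighted mean over defined channels (channels with zero
stress variance are reported as undefined); published fitting studies do not
pin down an averaging rule, so the simplest one is used and declared.

One caveat on the sparsity path: the number of active terms along increasing
`α` is non-increasing for well-conditioned designs (and provably so for
orthogonal ones), but on strongly correlated term libraries the lasso can
transiently activate a compensating term as the dominant one shrinks. The
monotone-path test therefore uses a noiseless single-generator design where
the idealized behavior holds; the estimator itself is exact either way.

## Numerical choices

* Finite-difference oracles (tests and `verify`): central differences with
  `h = 10⁻⁶ · max(1, ‖F‖)`, balancing truncation against round-off in double
  precision.
* Tolerances: `det F̄ = 1` to 10⁻¹⁰ after the split; fiber unit norm to
  10⁻¹² (inputs off by more than 10⁻⁶ are renormalized with a warning);
  lateral traction residual 10⁻⁹ relative to the axial stress; stress-free
  reference check at 10⁻¹² scaled by the largest row weight so kPa and MPa
  models are judged alike.
* Coordinate convention: fixed right-handed Cartesian frame; no Voigt
  reduction anywhere inside the kinematics; the 6×6 tangent ordering is
  (11, 22, 33, 12, 13, 23) with engineering shear.
* Problem sizes: verification suites sample 20–50 seeded random states per
  catalog model at perturbation amplitude 0.05–0.08 about the reference
  (well inside every log-branch domain); recovery studies use ~200 stress
  observations per dataset (uniaxial λ ≤ 1.5 plus equibiaxial λ ≤ 1.3) with
  additive noise of 0.02 stress units and 20 seeds, sizes chosen so the full
  suite runs in well under a minute per study on one CPU.

## Limitations

* Hyperelastic, history-independent response only: no viscoelasticity, rate
  effects, growth, damage, or inelastic splits.
* Material-point and homogeneous-specimen scale only: no finite-element
  discretization, no anatomical geometries, no contact or dynamics.
* Incompressible simple shear reports normal stresses only up to the stated
  pressure convention; experiments that constrain a different face should
  re-eliminate the pressure from the returned deviatoric stress.
* The catalog reproduces published table structures and best-fit weights;
  it does not redo the original fits to proprietary experimental data, and
  the shipped parameters are only as good as their sources.
* Calibration assumes the stored deformation gradients are the true
  kinematics (stress-only noise); with kinematic noise the estimator is no
  longer exactly linear in `w₂`.
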