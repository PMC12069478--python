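"""Free energy, Cauchy stress and tangent stiffness for a material model.

Stress assembly follows the invariant separation

    sigma = sum_i (dpsi/dI_i) G_i,   G_i = (2/J) F (dI_i/dC) F^t,

which is the exact push-forward of ``sigma = (1/J) (dpsi/dF) F^t`` through the
volumetric/isochoric split; the isochoric ``G_i`` are traceless by
construction.

The tangent is built from the material elasticity tensor

    CC = 4 [ sum_i psi_i'' dI_i (x) dI_i  +  cross terms  +  sum_i psi_i' d2I_i ]

pushed forward to the spatial configuration, plus geometric stress terms. Two
conventions are shipped:

``spatial-consistent``
    The exact directional derivative of the Cauchy stress under a symmetric
    velocity-gradient perturbation, ``dsigma = C4 : d(eps)`` for
    ``F -> (I + d(eps)) F``. This is what the drivers' Newton loops use. Note
    the pure Cauchy derivative carries a ``- sigma (x) I`` volume term, so at
    a stressed state its 6x6 form is not exactly major-symmetric.

``jaumann``
    The co-rotational (Abaqus-style) rate form: push-forward plus the
    symmetrized ``delta (x) sigma`` terms. Major-symmetric for hyperelastic
    input at every state; differs from spatial-consistent exactly by
    ``sigma (x) I`` (they coincide for isochoric perturbations and at
    stress-free states).

The reduced 6x6 matrix uses Voigt ordering (11, 22, 33, 12, 13, 23) with
engineering shear strain, i.e. ``dsigma_voigt = C66 . [e11,e22,e33,g12,g13,g23]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .kinematics import (
    FiberFrame,
    compute_invariants,
    decompose,
    invariant_cderivs,
    invariant_gradients,
)
from .network import EnergyDerivatives, accumulate
from .table import MaterialModel, validate

__all__ = [
    "VOIGT_PAIRS",
    "StressResult",
    "TangentResult",
    "energy_derivatives",
    "free_energy",
    "cauchy_stress",
    "tangent",
    "to_voigt",
    "reference_check",
]

VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


@dataclass
class StressResult:
    psi: float
    sigma: np.ndarray
    deviatoric_only: bool = False


@dataclass
class TangentResult:
    C4: np.ndarray  # 6x6 reduced form
    convention: str
    full: np.ndarray | None = None  # 3x3x3x3 tensor


def _check_model(model: MaterialModel) -> None:
    rep = validate(model)
    if not rep.ok:
        raise ConfigurationError("; ".join(rep.errors))


def energy_derivatives(model: MaterialModel, F: np.ndarray) -> tuple:
    """Decompose ``F`` and accumulate per-invariant energy derivatives."""
    state = decompose(F)
    inv = compute_invariants(state, model.fibers)
    acc = accumulate(model.rows, inv, model.mixed)
    return state, inv, acc


def free_energy(model: MaterialModel, F: np.ndarray) -> float:
    """Free energy per unit reference volume, zero at ``F = I``."""
    _check_model(model)
    return energy_derivatives(model, F)[2].psi


def cauchy_stress(model: MaterialModel, F: np.ndarray) -> StressResult:
    """Cauchy stress ``sigma = sum_i psi_i' G_i``; symmetric, zero at ``F = I``.

    For models without a volumetric row the returned stress is the deviatoric
    part only (the pressure is indeterminate); ``deviatoric_only`` is set and
    drivers supply the pressure from traction conditions.
    """
    _check_model(model)
    state, _, acc = energy_derivatives(model, F)
    sigma = _assemble_stress(model, state, acc)
    return StressResult(psi=acc.psi, sigma=sigma, deviatoric_only=model.is_incompressible)


def _assemble_stress(
    model: MaterialModel, state, acc: EnergyDerivatives
) -> np.ndarray:
    slots = acc.active_slots()
    G = invariant_gradients(state, model.fibers, slots)
    sigma = np.zeros((3, 3))
    for slot in slots:
        d = acc.dpsi[slot]
        if d != 0.0:
            sigma += d * G[slot]
    return 0.5 * (sigma + sigma.T)


def tangent(
    model: MaterialModel, F: np.ndarray, convention: str = "spatial-consistent"
) -> TangentResult:
    """Fourth-order tangent stiffness in reduced 6x6 Voigt form."""
    if convention not in ("spatial-consistent", "jaumann"):
        raise ValueError(f"unknown tangent convention {convention!r}")
    _check_model(model)
    state, _, acc = energy_derivatives(model, F)
    sigma = _assemble_stress(model, state, acc)

    slots = acc.active_slots()
    cder = invariant_cderivs(state, model.fibers, slots)

    CC = np.zeros((3, 3, 3, 3))
    for slot in slots:
        _, dI, d2I = cder[slot]
        if acc.d2psi[slot] != 0.0:
            CC += acc.d2psi[slot] * np.einsum("ij,kl->ijkl", dI, dI)
        if acc.dpsi[slot] != 0.0:
            CC += acc.dpsi[slot] * d2I
    for (i, j), x in acc.cross.items():
        dIi, dIj = cder[i][1], cder[j][1]
        CC += x * (
            np.einsum("ij,kl->ijkl", dIi, dIj) + np.einsum("ij,kl->ijkl", dIj, dIi)
        )
    CC *= 4.0

    Fm, J = state.F, state.J
    c_spatial = np.einsum("iI,jJ,kK,lL,IJKL->ijkl", Fm, Fm, Fm, Fm, CC) / J

    eye = np.eye(3)
    geom = 0.5 * (
        np.einsum("ik,jl->ijkl", eye, sigma)
        + np.einsum("il,jk->ijkl", eye, sigma)
        + np.einsum("ik,jl->ijkl", sigma, eye)
        + np.einsum("il,jk->ijkl", sigma, eye)
    )
    C4 = c_spatial + geom
    if convention == "spatial-consistent":
        C4 = C4 - np.einsum("ij,kl->ijkl", sigma, eye)
    return TangentResult(C4=to_voigt(C4), convention=convention, full=C4)


def to_voigt(T: np.ndarray) -> np.ndarray:
    """Reduce a minor-symmetric 3x3x3x3 tensor to 6x6 (engineering shear)."""
    M = np.empty((6, 6))
    for a, (i, j) in enumerate(VOIGT_PAIRS):
        for b, (k, l) in enumerate(VOIGT_PAIRS):
            M[a, b] = T[i, j, k, l]
    return M


@dataclass
class ReferenceCheckReport:
    psi: float
    sigma_norm: float
    passed: bool


def reference_check(
    model: MaterialModel,
    fibers: FiberFrame | None = None,
    tol: float = 1e-12,
) -> ReferenceCheckReport:
    """Verify the stress-free reference: psi and sigma vanish at ``F = I``.

    The tolerance scales with the largest row weight so models in MPa and kPa
    are judged alike.
    """
    if fibers is not None:
        model = model.with_fibers(fibers)
    res = cauchy_stress(model, np.eye(3))
    scale = max(1.0, max((abs(r.w2) for r in model.rows), default=1.0))
    norm = float(np.linalg.norm(res.sigma))
    passed = abs(res.psi) <= tol * scale and norm <= tol * scale
    return ReferenceCheckReport(psi=res.psi, sigma_norm=norm, passed=passed)
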