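"""Deformation kinematics and the 15-invariant bookkeeping.

The deformation gradient ``F`` is split multiplicatively into a volumetric
part ``J^(1/3) I`` and an isochoric part ``Fbar = J^(-1/3) F``. Shape change
is measured through the isochoric Cauchy-Green tensors ``bbar = Fbar Fbar^t``
and ``Cbar = Fbar^t Fbar``; volume change through ``I3 = J^2``. Up to three
unit fiber directions ``n_alpha^0`` extend the isotropic invariants ``Ibar_1``
and ``Ibar_2`` with fiber stretch invariants ``Ibar_4(ab) = Cbar : n_a x n_b``
and ``Ibar_5(ab) = Cbar^2 : n_a x n_b`` (``b >= a``), including the coupling
pseudo-invariants with ``a != b`` whose sign follows the stored fiber vectors.

Slot numbering
--------------
Invariants are addressed by an integer slot::

    Ibar_1 -> 1, Ibar_2 -> 2, I_3 -> 3
    Ibar_4(ab) -> 4 + 2(a-1) + b(b-1)
    Ibar_5(ab) -> 5 + 2(a-1) + b(b-1)

which maps the twelve (family, a, b) combinations bijectively onto 4..15.
Mixed invariants (linear combinations of the slot deviations) live on ids
>= 101 and are defined by the material table.

Every invariant is reported together with its reference value (3, 3, 1 or
``zeta_ab = n_a^0 . n_b^0``) so that the deviation vanishes identically at
``F = I``.

This module also provides the exact first and second derivatives of each
invariant with respect to ``C = F^t F``, from which the stress engine builds
the Cauchy stress and the consistent tangent. Because the isochoric
invariants are homogeneous of degree zero in a volumetric rescaling of ``C``,
their push-forward stress-direction tensors are automatically traceless
(deviatoric); no separate projection step is applied or needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InvalidDeformationError

__all__ = [
    "N_SLOTS",
    "FiberFrame",
    "DeformationState",
    "InvariantVector",
    "MixedInvariantDef",
    "decompose",
    "invariant_index",
    "slot_components",
    "slots_available",
    "compute_invariants",
    "invariant_gradients",
    "invariant_cderivs",
    "evaluate_mixed",
]

N_SLOTS = 15

_EYE = np.eye(3)

#: symmetric fourth-order identity, II[i,j,k,l] = (d_ik d_jl + d_il d_jk)/2
_II_SYM = 0.5 * (
    np.einsum("ik,jl->ijkl", _EYE, _EYE) + np.einsum("il,jk->ijkl", _EYE, _EYE)
)


def invariant_index(family: int, alpha: int, beta: int) -> int:
    """Slot number of the fiber invariant ``Ibar_family(alpha beta)``.

    ``family`` is 4 (stretch, ``Cbar``) or 5 (``Cbar^2``); ``beta >= alpha``.
    """
    if family not in (4, 5):
        raise ConfigurationError(f"invariant family must be 4 or 5, got {family}")
    if not (1 <= alpha <= 3 and 1 <= beta <= 3):
        raise ConfigurationError(f"fiber indices must lie in 1..3, got ({alpha},{beta})")
    if beta < alpha:
        raise ConfigurationError(
            f"fiber indices must satisfy beta >= alpha, got ({alpha},{beta})"
        )
    return family + 2 * (alpha - 1) + beta * (beta - 1)


_SLOT_COMPONENTS = {
    invariant_index(fam, a, b): (fam, a, b)
    for fam in (4, 5)
    for a in (1, 2, 3)
    for b in range(a, 4)
}


def slot_components(slot: int) -> tuple[int, int, int]:
    """Inverse of :func:`invariant_index` for slots 4..15."""
    try:
        return _SLOT_COMPONENTS[slot]
    except KeyError:
        raise ConfigurationError(f"slot {slot} is not a fiber-invariant slot") from None


def slots_available(n_dir: int) -> frozenset[int]:
    """Set of invariant slots resolvable with ``n_dir`` fiber families."""
    slots = {1, 2, 3}
    for slot, (_, _a, b) in _SLOT_COMPONENTS.items():
        if b <= n_dir:
            slots.add(slot)
    return frozenset(slots)


@dataclass(frozen=True)
class FiberFrame:
    """Reference fiber directions and their mutual dot products.

    ``directions`` has shape ``(n_dir, 3)`` with ``n_dir`` in 0..3; each row is
    a unit vector. ``zeta[a, b] = n_a^0 . n_b^0`` supplies the reference values
    of the fiber invariants.
    """

    directions: np.ndarray

    UNIT_TOL = 1e-12

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        if d.shape[0] > 3:
            raise ConfigurationError("at most three fiber families are supported")
        if d.size:
            norms = np.linalg.norm(d, axis=1)
            if np.any(norms <= 0.0) or not np.all(np.isfinite(d)):
                raise ConfigurationError("fiber directions must be finite nonzero vectors")
            if np.any(np.abs(norms - 1.0) > 1e-6):
                warnings.warn(
                    "fiber directions renormalized (off unit length by more than 1e-6)",
                    stacklevel=3,
                )
            if np.any(np.abs(norms - 1.0) > self.UNIT_TOL):
                d = d / norms[:, None]
        object.__setattr__(self, "directions", d)

    @classmethod
    def from_vectors(cls, *vectors) -> "FiberFrame":
        if not vectors:
            return cls(np.zeros((0, 3)))
        return cls(np.asarray(vectors, dtype=float))

    @property
    def n_dir(self) -> int:
        return self.directions.shape[0]

    @property
    def zeta(self) -> np.ndarray:
        return self.directions @ self.directions.T

    def available_slots(self) -> frozenset[int]:
        return slots_available(self.n_dir)


@dataclass(frozen=True)
class DeformationState:
    """A deformation gradient with its volumetric/isochoric split."""

    F: np.ndarray
    J: float
    Fbar: np.ndarray
    bbar: np.ndarray
    Cbar: np.ndarray

    DETBAR_TOL = 1e-10

    def pushed_fibers(self, fibers: FiberFrame) -> np.ndarray:
        """Isochoric fiber vectors in the current configuration, Fbar . n^0."""
        return fibers.directions @ self.Fbar.T


def decompose(F: np.ndarray, *, detbar_tol: float = DeformationState.DETBAR_TOL) -> DeformationState:
    """Split ``F`` into volume and shape parts and form the strain tensors."""
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise InvalidDeformationError(f"F must be 3x3, got shape {F.shape}")
    if not np.all(np.isfinite(F)):
        raise InvalidDeformationError("F contains non-finite entries")
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvalidDeformationError(f"det(F) = {J} must be positive")
    Fbar = J ** (-1.0 / 3.0) * F
    state = DeformationState(F=F, J=J, Fbar=Fbar, bbar=Fbar @ Fbar.T, Cbar=Fbar.T @ Fbar)
    if abs(np.linalg.det(Fbar) - 1.0) > detbar_tol:
        raise InvalidDeformationError("isochoric part lost unit determinant")
    return state


@dataclass
class InvariantVector:
    """Values, reference values and deviations of the 15 invariant slots.

    Arrays are indexed by slot number (entry 0 is unused). Slots whose fiber
    family is absent are flagged unavailable and hold NaN. ``mixed`` maps a
    mixed-invariant id (>= 101) to its value.
    """

    values: np.ndarray
    ref: np.ndarray
    available: np.ndarray
    mixed: dict[int, float] = field(default_factory=dict)

    @property
    def dev(self) -> np.ndarray:
        return self.values - self.ref

    def require(self, slot: int) -> float:
        """Deviation on ``slot``; raises if the slot is unavailable."""
        if not (1 <= slot <= N_SLOTS) or not self.available[slot]:
            raise ConfigurationError(
                f"invariant slot {slot} is not available for this fiber frame"
            )
        return float(self.dev[slot])


def compute_invariants(state: DeformationState, fibers: FiberFrame) -> InvariantVector:
    """Evaluate all resolvable invariant slots for a deformation state."""
    values = np.full(N_SLOTS + 1, np.nan)
    ref = np.full(N_SLOTS + 1, np.nan)
    available = np.zeros(N_SLOTS + 1, dtype=bool)

    Cbar = state.Cbar
    I1b = float(np.trace(Cbar))
    values[1] = I1b
    values[2] = 0.5 * (I1b**2 - float(np.tensordot(Cbar, Cbar)))
    values[3] = state.J**2
    ref[1] = ref[2] = 3.0
    ref[3] = 1.0
    available[1:4] = True

    if fibers.n_dir:
        zeta = fibers.zeta
        Cbar2 = Cbar @ Cbar
        n0 = fibers.directions
        for slot, (fam, a, b) in _SLOT_COMPONENTS.items():
            if b > fibers.n_dir:
                continue
            na, nb = n0[a - 1], n0[b - 1]
            T = Cbar if fam == 4 else Cbar2
            values[slot] = float(na @ T @ nb)
            ref[slot] = float(zeta[a - 1, b - 1])
            available[slot] = True

    return InvariantVector(values=values, ref=ref, available=available)


# ---------------------------------------------------------------------------
# derivatives with respect to C = F^t F
# ---------------------------------------------------------------------------


def _scale_derivs(I3: float, Ci: np.ndarray, p: float):
    """Derivatives of s = I3^(-p) with respect to C (I3 = det C here)."""
    s = I3 ** (-p)
    ds = -p * s * Ci
    CiCi = 0.5 * (
        np.einsum("ik,jl->ijkl", Ci, Ci) + np.einsum("il,jk->ijkl", Ci, Ci)
    )
    d2s = p * p * s * np.einsum("ij,kl->ijkl", Ci, Ci) + p * s * CiCi
    return s, ds, d2s


def invariant_cderivs(
    state: DeformationState, fibers: FiberFrame, slots=None
) -> dict[int, tuple[float, np.ndarray, np.ndarray]]:
    """Exact first and second derivatives of the invariants w.r.t. ``C``.

    Returns ``{slot: (value, dI/dC, d2I/dC2)}`` with ``dI/dC`` a symmetric
    3x3 tensor and ``d2I/dC2`` a minor-symmetric 3x3x3x3 tensor. ``slots``
    restricts the computation; by default every available slot is returned.
    """
    C = state.F.T @ state.F
    I3 = float(np.linalg.det(C))
    Ci = np.linalg.inv(C)
    if slots is None:
        slots = sorted(fibers.available_slots())

    CiCi = 0.5 * (
        np.einsum("ik,jl->ijkl", Ci, Ci) + np.einsum("il,jk->ijkl", Ci, Ci)
    )
    out: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
    n0 = fibers.directions

    for slot in slots:
        if slot == 3:
            dI = I3 * Ci
            d2I = I3 * np.einsum("ij,kl->ijkl", Ci, Ci) - I3 * CiCi
            out[slot] = (I3, dI, d2I)
            continue
        if slot == 1:
            A = float(np.trace(C))
            dA = _EYE.copy()
            d2A = np.zeros((3, 3, 3, 3))
            p = 1.0 / 3.0
        elif slot == 2:
            trC = float(np.trace(C))
            A = 0.5 * (trC**2 - float(np.tensordot(C, C)))
            dA = trC * _EYE - C
            d2A = np.einsum("ij,kl->ijkl", _EYE, _EYE) - _II_SYM
            p = 2.0 / 3.0
        else:
            fam, a, b = slot_components(slot)
            if b > fibers.n_dir:
                raise ConfigurationError(
                    f"slot {slot} needs fiber family {b}, frame has {fibers.n_dir}"
                )
            N = 0.5 * (
                np.outer(n0[a - 1], n0[b - 1]) + np.outer(n0[b - 1], n0[a - 1])
            )
            if fam == 4:
                A = float(np.tensordot(C, N))
                dA = N
                d2A = np.zeros((3, 3, 3, 3))
                p = 1.0 / 3.0
            else:
                A = float(np.tensordot(C @ C, N))
                dA = C @ N + N @ C
                d2A = 0.5 * (
                    np.einsum("ik,jl->ijkl", _EYE, N)
                    + np.einsum("il,jk->ijkl", _EYE, N)
                    + np.einsum("ik,jl->ijkl", N, _EYE)
                    + np.einsum("il,jk->ijkl", N, _EYE)
                )
                p = 2.0 / 3.0

        s, ds, d2s = _scale_derivs(I3, Ci, p)
        val = s * A
        dI = s * dA + A * ds
        d2I = (
            s * d2A
            + np.einsum("ij,kl->ijkl", ds, dA)
            + np.einsum("ij,kl->ijkl", dA, ds)
            + A * d2s
        )
        out[slot] = (val, dI, d2I)
    return out


def invariant_gradients(
    state: DeformationState, fibers: FiberFrame, slots=None
) -> dict[int, np.ndarray]:
    """Spatial stress-direction tensors ``G_i = (2/J) F (dI_i/dC) F^t``.

    These satisfy ``sigma = sum_i (dpsi/dI_i) G_i`` which equals the exact
    ``(1/J) (dpsi/dF) F^t``. Isochoric slots come out traceless.
    """
    cderivs = invariant_cderivs(state, fibers, slots)
    F, J = state.F, state.J
    return {slot: (2.0 / J) * (F @ dI @ F.T) for slot, (_, dI, _) in cderivs.items()}


@dataclass(frozen=True)
class MixedInvariantDef:
    """A mixed invariant: a linear combination of base slot deviations.

    ``coeff`` is a length-15 vector aligned to the slot numbering; the value
    of the mixed invariant is ``sum_j coeff[j] * dev[j]``, which vanishes at
    the reference configuration by construction. ``id`` is ``100 + row``.
    """

    id: int
    coeff: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coeff, dtype=float).reshape(-1)
        if c.shape[0] != N_SLOTS:
            raise ConfigurationError(
                f"mixed invariant needs {N_SLOTS} coefficients, got {c.shape[0]}"
            )
        if not np.any(c != 0.0):
            raise ConfigurationError("mixed invariant has all-zero coefficients")
        object.__setattr__(self, "coeff", c)
        object.__setattr__(self, "id", int(self.id))

    def base_slots(self) -> list[int]:
        """Slots with a nonzero coefficient (1-based)."""
        return [j + 1 for j in range(N_SLOTS) if self.coeff[j] != 0.0]


def evaluate_mixed(
    inv: InvariantVector, defs: list[MixedInvariantDef]
) -> dict[int, tuple[float, dict[int, float]]]:
    """Evaluate mixed invariants and return chain-rule coefficient maps.

    Returns ``{id: (value, {base_slot: coefficient})}`` and also stores the
    values on ``inv.mixed``. A nonzero coefficient on an unavailable base slot
    is a configuration error.
    """
    out: dict[int, tuple[float, dict[int, float]]] = {}
    for mdef in defs:
        value = 0.0
        coeffs: dict[int, float] = {}
        for slot in mdef.base_slots():
            c = float(mdef.coeff[slot - 1])
            value += c * inv.require(slot)
            coeffs[slot] = c
        inv.mixed[mdef.id] = value
        out[mdef.id] = (value, coeffs)
    return out
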