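"""Nested activation functions and per-neuron energy accumulation.

Each additive energy term (one table row, one "neuron") evaluates

    psi_k = w2 * f2( f1( f0(dev; w0) ); w1 )

on the deviation ``dev`` of one invariant from its reference value, with

    f0: identity (x), Macauley bracket <x>, or absolute value |x|
        (applied to the w0-scaled input),
    f1: integer power x^m, m >= 1,
    f2: scaled identity w1*x, exponential exp(w1*x)-1,
        or negative logarithm -ln(1 - w1*x).

The engine needs psi, dpsi/dI and d2psi/dI2 per invariant slot; all three are
propagated through the chain analytically. Because each neuron touches a
single invariant, cross second derivatives between different base slots only
arise through mixed invariants (linear combinations of base deviations); those
are stored in a sparse cross-term map consumed by the tangent assembly.

Conventions at the kink x = 0: the first derivative of both the Macauley
bracket and the absolute value is defined as 0, which keeps the reference
configuration exactly stress-free for any admissible row. For the *second*
derivative chain, the squared slope of f0 at x = 0 is taken as the active-side
limit w0^2 (for the Macauley bracket this is the tension-side limit; for the
absolute value the two one-sided limits agree). This initializes Newton
solvers at the reference state with the physical tension-side stiffness, e.g.
a fiber row (Macauley, quadratic, exponential) with weights (1, k2, k1/2k2)
contributes curvature k1 at zero stretch deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DomainError, SelectorError
from .kinematics import N_SLOTS, InvariantVector, evaluate_mixed

__all__ = [
    "F0_IDENTITY",
    "F0_MACAULEY",
    "F0_ABS",
    "F2_IDENTITY",
    "F2_EXP",
    "F2_LOG",
    "ActivationSpec",
    "EnergyDerivatives",
    "eval_f0",
    "eval_f1",
    "eval_f2",
    "neuron_contribution",
    "accumulate",
]

F0_IDENTITY, F0_MACAULEY, F0_ABS = 1, 2, 3
F2_IDENTITY, F2_EXP, F2_LOG = 1, 2, 3


@dataclass(frozen=True)
class ActivationSpec:
    """Selectors and weights of one constitutive neuron.

    ``w0`` and ``w1`` are dimensionless shape weights; ``w2`` carries the
    stress unit of the model (kPa or MPa by convention of the table).
    """

    kf0: int
    kf1: int
    kf2: int
    w0: float = 1.0
    w1: float = 1.0
    w2: float = 1.0

    def __post_init__(self):
        if self.kf0 not in (F0_IDENTITY, F0_MACAULEY, F0_ABS):
            raise SelectorError(f"unknown zeroth-layer selector kf0={self.kf0}")
        if int(self.kf1) < 1:
            raise SelectorError(f"power kf1 must be >= 1, got {self.kf1}")
        if self.kf2 not in (F2_IDENTITY, F2_EXP, F2_LOG):
            raise SelectorError(f"unknown second-layer selector kf2={self.kf2}")


def eval_f0(x: float, kf0: int, w0: float = 1.0) -> tuple[float, float, float]:
    """Zeroth layer: value, first and second derivative w.r.t. ``x``.

    The second derivative vanishes identically for all three branches; the
    first derivative of the kinked branches at exactly 0 is taken as 0.
    """
    z = w0 * x
    if kf0 == F0_IDENTITY:
        return z, w0, 0.0
    if kf0 == F0_MACAULEY:
        return (z, w0, 0.0) if z > 0.0 else (0.0, 0.0, 0.0)
    if kf0 == F0_ABS:
        return abs(z), w0 * float(np.sign(z)), 0.0
    raise SelectorError(f"unknown zeroth-layer selector kf0={kf0}")


def eval_f1(x: float, m: int) -> tuple[float, float, float]:
    """First layer: integer power ``x^m`` with first and second derivative."""
    m = int(m)
    if m < 1:
        raise SelectorError(f"power must be >= 1, got {m}")
    if m == 1:
        return x, 1.0, 0.0
    if m == 2:
        return x * x, 2.0 * x, 2.0
    return x**m, m * x ** (m - 1), (m * m - m) * x ** (m - 2)


def eval_f2(x: float, kf2: int, w1: float = 1.0) -> tuple[float, float, float]:
    """Second layer: identity, exponential or negative logarithm of ``w1*x``."""
    if kf2 == F2_IDENTITY:
        return w1 * x, w1, 0.0
    if kf2 == F2_EXP:
        e = np.exp(w1 * x)
        return e - 1.0, w1 * e, w1 * w1 * e
    if kf2 == F2_LOG:
        arg = 1.0 - w1 * x
        if arg <= 0.0:
            raise DomainError(
                f"logarithm branch needs w1*x < 1, got w1*x = {w1 * x}", value=w1 * x
            )
        return -np.log(arg), w1 / arg, (w1 / arg) ** 2
    raise SelectorError(f"unknown second-layer selector kf2={kf2}")


def neuron_contribution(spec: ActivationSpec, dev: float) -> tuple[float, float, float]:
    """Energy, first and second derivative of one neuron at deviation ``dev``.

    Returns ``(psi_k, dpsi_k, d2psi_k)`` where the derivatives are with
    respect to the invariant itself (equivalently its deviation).
    """
    y0, d0, _ = eval_f0(dev, spec.kf0, spec.w0)
    y1, d1, dd1 = eval_f1(y0, spec.kf1)
    y2, d2, dd2 = eval_f2(y1, spec.kf2, spec.w1)

    psi = spec.w2 * y2
    dpsi = spec.w2 * d2 * d1 * d0
    # active-side slope limit for the curvature chain at the f0 kink
    d0sq = d0 * d0
    if dev == 0.0 and spec.kf0 in (F0_MACAULEY, F0_ABS):
        d0sq = spec.w0 * spec.w0
    d2psi = spec.w2 * (dd2 * d1 * d1 + d2 * dd1) * d0sq
    return psi, dpsi, d2psi


@dataclass
class EnergyDerivatives:
    """Free energy and its per-slot derivatives, accumulated over all rows.

    ``dpsi`` and ``d2psi`` are indexed by invariant slot (entry 0 unused);
    ``cross`` holds the sparse off-diagonal second derivatives
    ``d2psi/dI_i dI_j`` (i < j) generated by mixed-invariant rows.
    """

    psi: float = 0.0
    dpsi: np.ndarray = field(default_factory=lambda: np.zeros(N_SLOTS + 1))
    d2psi: np.ndarray = field(default_factory=lambda: np.zeros(N_SLOTS + 1))
    cross: dict[tuple[int, int], float] = field(default_factory=dict)

    def active_slots(self) -> list[int]:
        """Slots carrying a nonzero first or second derivative."""
        slots = set(np.nonzero(self.dpsi)[0]) | set(np.nonzero(self.d2psi)[0])
        for i, j in self.cross:
            slots.update((i, j))
        return sorted(int(s) for s in slots if s >= 1)


def accumulate(rows, inv: InvariantVector, mixed_defs=()) -> EnergyDerivatives:
    """Sum neuron contributions of all table rows at an invariant state.

    ``rows`` is an iterable with attributes ``kfinv, kf0, kf1, kf2, w0, w1,
    w2`` (parameter-table rows). Rows on mixed slots (kfinv >= 101) are
    redistributed onto the base slots via the chain rule; since mixed
    invariants are linear in the base deviations this is exact, and the
    second-order cross terms go into ``EnergyDerivatives.cross``.
    """
    mixed = evaluate_mixed(inv, list(mixed_defs)) if mixed_defs else {}
    acc = EnergyDerivatives()
    for idx, row in enumerate(rows):
        spec = ActivationSpec(row.kf0, row.kf1, row.kf2, row.w0, row.w1, row.w2)
        slot = int(row.kfinv)
        try:
            if slot >= 101:
                if slot not in mixed:
                    raise ConfigurationError(
                        f"row {idx + 1} references undefined mixed invariant {slot}"
                    )
                value, coeffs = mixed[slot]
                psi, dpsi, d2psi = neuron_contribution(spec, value)
                acc.psi += psi
                items = sorted(coeffs.items())
                for j, cj in items:
                    acc.dpsi[j] += cj * dpsi
                    acc.d2psi[j] += cj * cj * d2psi
                for a in range(len(items)):
                    for b in range(a + 1, len(items)):
                        (ji, ci), (jj, cj) = items[a], items[b]
                        key = (ji, jj)
                        acc.cross[key] = acc.cross.get(key, 0.0) + ci * cj * d2psi
            else:
                dev = inv.require(slot)
                psi, dpsi, d2psi = neuron_contribution(spec, dev)
                acc.psi += psi
                acc.dpsi[slot] += dpsi
                acc.d2psi[slot] += d2psi
        except DomainError as err:
            raise DomainError(
                f"row {idx + 1} (slot {slot}): {err}", value=err.value
            ) from err
    return acc
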