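"""Homogeneous-deformation protocols: the experiments models are fit to.

Supported modes (all with homogeneous deformation gradients):

``uniaxial``
    stretch ``lam`` along one axis, lateral faces traction-free.
``equibiaxial``
    equal stretch on two axes, third face traction-free.
``biaxial_ratio``
    ``lam_2 - 1 = ratio * (lam_1 - 1)``, third face traction-free.
``simple_shear``
    ``F = I + gamma e_a (x) e_b``; the plane is named either by axis digits
    ("12", "31", ...) or by the fiber-frame letters f, s, n ("fs" means
    displacement along f = e1 varying with s = e2). This covers the six
    triaxial shear modes used for myocardium.
``volumetric``
    ``F = lam I`` (compressible models only).

Models without a volumetric table row run exactly incompressible: the lateral
kinematics enforce ``J = 1`` and the indeterminate pressure is eliminated
through the zero-traction condition (for simple shear, through a traction-free
out-of-plane face). Models with volumetric rows run fully compressible, with
lateral stretches found by Newton iteration on the lateral Cauchy stress using
the engine's spatial-consistent tangent. Continuation warm-starts each step
from the previous solution; on a Newton failure or an activation domain error
the step is halved up to five times, after which the curve is truncated with a
logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError, HypertabError, SolverError
from .engine import cauchy_stress, energy_derivatives, tangent, _assemble_stress
from .table import MaterialModel

__all__ = ["LoadingProtocol", "CurveTable", "make_deformation", "solve_lateral", "run_protocol"]

log = logging.getLogger(__name__)

_LETTER_AXES = {"f": 1, "s": 2, "n": 3}

LATERAL_TOL = 1e-9
MAX_NEWTON = 60
MAX_HALVINGS = 5


def _shear_plane(plane: str) -> tuple[int, int]:
    p = plane.strip().lower()
    if len(p) == 2 and p[0] in "123" and p[1] in "123":
        a, b = int(p[0]), int(p[1])
    elif len(p) == 2 and p[0] in _LETTER_AXES and p[1] in _LETTER_AXES:
        a, b = _LETTER_AXES[p[0]], _LETTER_AXES[p[1]]
    else:
        raise ConfigurationError(f"unrecognized shear plane {plane!r}")
    if a == b:
        raise ConfigurationError(f"shear plane needs two distinct axes, got {plane!r}")
    return a, b


@dataclass(frozen=True)
class LoadingProtocol:
    """A stretch- or shear-controlled homogeneous loading path."""

    mode: str
    start: float = 1.0
    end: float = 1.5
    steps: int = 11
    axis: int = 1
    ratio: float = 1.0  # biaxial_ratio only
    plane: str = "12"  # simple_shear only
    lateral: str = "solve"  # "solve" | "prescribed"

    MODES = ("uniaxial", "equibiaxial", "biaxial_ratio", "simple_shear", "volumetric")

    def __post_init__(self):
        if self.mode not in self.MODES:
            raise ConfigurationError(
                f"unknown protocol mode {self.mode!r}; choose from {self.MODES}"
            )
        if self.steps < 1:
            raise ConfigurationError("steps must be >= 1")
        if self.axis not in (1, 2, 3):
            raise ConfigurationError("axis must be 1, 2 or 3")
        if self.mode != "simple_shear" and (self.start <= 0 or self.end <= 0):
            raise ConfigurationError("stretch control values must be positive")
        if self.mode == "simple_shear":
            _shear_plane(self.plane)

    @property
    def reference_control(self) -> float:
        return 0.0 if self.mode == "simple_shear" else 1.0

    def control_values(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.steps)

    def control_label(self) -> str:
        return "gamma" if self.mode == "simple_shear" else "stretch"


def _axes(protocol: LoadingProtocol) -> tuple[int, int, int]:
    """(loading axis, first lateral, second lateral), 0-based."""
    a = protocol.axis - 1
    others = [i for i in range(3) if i != a]
    return a, others[0], others[1]


def make_deformation(
    protocol: LoadingProtocol, control: float, lateral_values=()
) -> np.ndarray:
    """Deformation gradient for a control value and explicit lateral stretches.

    ``lateral_values`` are the stretches on the traction-free axes in the
    order returned by the solver (uniaxial: two values, or one value when the
    volume constraint fixes the second; equibiaxial / biaxial_ratio: one).
    """
    if protocol.mode == "simple_shear":
        a, b = _shear_plane(protocol.plane)
        F = np.eye(3)
        F[a - 1, b - 1] = control
        return F
    if control <= 0:
        raise ConfigurationError("stretch control values must be positive")
    if protocol.mode == "volumetric":
        return control * np.eye(3)

    a, b, c = _axes(protocol)
    lam = np.ones(3)
    lam[a] = control
    if protocol.mode == "uniaxial":
        if len(lateral_values) == 2:
            lam[b], lam[c] = lateral_values
        elif len(lateral_values) == 1:  # J = 1 closes the third stretch
            lam[b] = lateral_values[0]
            lam[c] = 1.0 / (control * lam[b])
        else:
            raise ConfigurationError("uniaxial needs one or two lateral stretches")
    elif protocol.mode in ("equibiaxial", "biaxial_ratio"):
        lam[b] = control if protocol.mode == "equibiaxial" else 1.0 + protocol.ratio * (
            control - 1.0
        )
        if len(lateral_values) == 1:
            lam[c] = lateral_values[0]
        elif not lateral_values:
            lam[c] = 1.0 / (lam[a] * lam[b])  # exact incompressibility
        else:
            raise ConfigurationError("biaxial modes take at most one lateral stretch")
    return np.diag(lam)


def _deviatoric_stress(model: MaterialModel, F: np.ndarray) -> np.ndarray:
    state, _, acc = energy_derivatives(model, F)
    return _assemble_stress(model, state, acc)


def _tangent_full(model: MaterialModel, F: np.ndarray) -> np.ndarray:
    return tangent(model, F, "spatial-consistent").full


def solve_lateral(
    model: MaterialModel,
    protocol: LoadingProtocol,
    control: float,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Find the deformation gradient satisfying the lateral traction condition.

    Returns ``(F, x)`` where ``x`` holds the solved lateral stretches (empty
    for fully prescribed kinematics). Newton residuals are driven below
    ``1e-9 * max(1, |sigma_axial|)``.
    """
    a, b, c = _axes(protocol)
    incomp = model.is_incompressible
    if control == 1.0 and protocol.mode != "simple_shear":
        # the undeformed state solves every traction condition exactly
        x0 = None

    if protocol.mode == "simple_shear":
        return make_deformation(protocol, control), np.zeros(0)
    if protocol.mode == "volumetric":
        if incomp:
            raise ConfigurationError(
                "volumetric protocol needs a model with a slot-3 row"
            )
        return make_deformation(protocol, control), np.zeros(0)

    if incomp:
        if protocol.mode in ("equibiaxial", "biaxial_ratio"):
            return make_deformation(protocol, control), np.zeros(0)
        # uniaxial: one unknown, J = 1 closes the third stretch
        x = np.array([control ** (-0.5) if x0 is None or not len(x0) else x0[0]])

        def residual(xv):
            F = make_deformation(protocol, control, [xv[0]])
            sig = _deviatoric_stress(model, F)
            return F, sig, np.array([sig[b, b] - sig[c, c]])

        def jacobian(F, xv):
            C4 = _tangent_full(model, F)
            lam_b = xv[0]
            lam_c = F[c, c]
            L = np.zeros((3, 3))
            L[b, b] = 1.0 / lam_b
            L[c, c] = -1.0 / lam_b  # d lam_c / d lam_b = -lam_c / lam_b
            dS = np.einsum("ijkl,kl->ij", C4, L)
            return np.array([[dS[b, b] - dS[c, c]]])

    else:
        if protocol.mode == "uniaxial":
            unknown_axes = [b, c]
        else:
            unknown_axes = [c]
        x = np.array(
            x0 if x0 is not None and len(x0) == len(unknown_axes) else [1.0] * len(unknown_axes)
        , dtype=float)

        def residual(xv):
            F = make_deformation(protocol, control, list(xv))
            sig = _deviatoric_stress(model, F)
            return F, sig, np.array([sig[u, u] for u in unknown_axes])

        def jacobian(F, xv):
            C4 = _tangent_full(model, F)
            Jm = np.empty((len(unknown_axes), len(unknown_axes)))
            for jcol, v in enumerate(unknown_axes):
                L = np.zeros((3, 3))
                L[v, v] = 1.0 / F[v, v]
                dS = np.einsum("ijkl,kl->ij", C4, L)
                for irow, u in enumerate(unknown_axes):
                    Jm[irow, jcol] = dS[u, u]
            return Jm

    F, sig, r = residual(x)
    scale = max(1.0, abs(sig[a, a]))
    last = np.linalg.norm(r)
    for _ in range(MAX_NEWTON):
        if np.linalg.norm(r, ord=np.inf) <= LATERAL_TOL * scale:
            return F, x
        Jm = jacobian(F, x)
        try:
            dx = np.linalg.solve(Jm, -r)
        except np.linalg.LinAlgError as err:
            raise SolverError(f"singular lateral Jacobian: {err}", residual=last) from err
        step = 1.0
        for _ in range(MAX_HALVINGS + 1):
            try:
                Fn, sign, rn = residual(x + step * dx)
            except (DomainError, HypertabError):
                step *= 0.5
                continue
            if np.linalg.norm(rn) <= last or step < 1.0 / 2**MAX_HALVINGS:
                break
            step *= 0.5
        else:
            raise SolverError("lateral Newton step halving exhausted", residual=last)
        x = x + step * dx
        F, sig, r = Fn, sign, rn
        scale = max(1.0, abs(sig[a, a]))
        last = np.linalg.norm(r)
    raise SolverError("lateral Newton did not converge", residual=float(last))


@dataclass
class CurveTable:
    """Per-step records of a protocol run plus provenance metadata."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    truncated_reason: str | None = None

    def write(self, path) -> None:
        """Delimited text with one header line and 17-significant-digit floats."""
        self.data.to_csv(path, index=False, float_format="%.17g")


_COLUMNS = (
    ["control"]
    + [f"F{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
    + ["s11", "s22", "s33", "s12", "s13", "s23", "psi"]
)


def _full_stress(model: MaterialModel, protocol: LoadingProtocol, F: np.ndarray):
    """Total Cauchy stress with the pressure eliminated for incompressible runs."""
    res = cauchy_stress(model, F)
    sigma = res.sigma
    if res.deviatoric_only:
        if protocol.mode == "simple_shear":
            a, bax = _shear_plane(protocol.plane)
            free = ({0, 1, 2} - {a - 1, bax - 1}).pop()
        elif protocol.mode in ("equibiaxial", "biaxial_ratio", "uniaxial"):
            free = _axes(protocol)[2]
        else:  # pragma: no cover - volumetric rejected earlier
            free = 2
        sigma = sigma - sigma[free, free] * np.eye(3)
    return sigma, res.psi


def run_protocol(model: MaterialModel, protocol: LoadingProtocol) -> CurveTable:
    """Run a loading protocol, solving lateral conditions with continuation."""
    records: list[list[float]] = []
    reason = None
    x_prev: np.ndarray | None = None
    for control in protocol.control_values():
        try:
            F, x_prev = solve_lateral(model, protocol, control, x_prev)
            sigma, psi = _full_stress(model, protocol, F)
        except (DomainError, SolverError) as err:
            reason = f"truncated at {protocol.control_label()}={control:g}: {err}"
            log.warning(reason)
            break
        records.append(
            [control, *F.reshape(-1),
             sigma[0, 0], sigma[1, 1], sigma[2, 2],
             sigma[0, 1], sigma[0, 2], sigma[1, 2], psi]
        )
    df = pd.DataFrame(records, columns=_COLUMNS)
    meta = {
        "model": model.name or "unnamed",
        "protocol": protocol.mode,
        "units": model.units,
        "convention": "spatial-consistent",
    }
    return CurveTable(data=df, metadata=meta, truncated_reason=reason)
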