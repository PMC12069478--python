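"""Weight calibration against stress-stretch data, and synthetic experiments.

This is the desk-scale counterpart of constitutive model discovery: a
template table with free weights is fit to (possibly noisy) stress-stretch
curves, optionally with an L1 penalty on the outer weights ``w2`` that prunes
terms from the library.

Fitting model
-------------
Each data point stores the full deformation gradient realized in the
experiment together with the measured stress channels. Predictions evaluate
the candidate model at that stored ``F``; for incompressible experiments the
indeterminate pressure is eliminated through the declared traction-free
channel (predicted normal stresses are reported relative to it). With the
kinematics frozen per point, the predicted stress is exactly *linear* in the
outer weights ``w2`` and nonlinear only in the inner weights ``w1`` of
exponential/logarithmic rows. The solver exploits this split:

* ``w2``: the penalized linear subproblem (least squares + L1, optionally
  w2 >= 0) is solved exactly by cyclic coordinate descent with soft
  thresholding;
* ``w1``: bounded trust-region nonlinear least squares (scipy) with ``w2``
  held fixed;

alternated until the penalized objective stalls. Both half-steps are descent
steps, so the iteration log is non-increasing. Templates with two or more
free nonlinear weights are restarted from several seeded initial guesses and
the best objective wins (ties broken by smaller weight norm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConfigurationError, DomainError
from .engine import energy_derivatives, _assemble_stress
from .kinematics import compute_invariants, decompose, invariant_gradients
from .network import ActivationSpec, neuron_contribution
from .drivers import LoadingProtocol, run_protocol, _axes, _shear_plane
from .table import MaterialModel

__all__ = [
    "Experiment",
    "ExperimentSet",
    "FitResult",
    "simulate_dataset",
    "fit_weights",
    "r_squared",
    "count_submodels",
]


@dataclass
class Experiment:
    """One protocol's worth of measured stress channels.

    ``F`` has shape (n, 3, 3); ``stress`` (n, n_channels) holds the measured
    Cauchy stress on ``channels`` (0-based index pairs). ``pressure_channel``
    names the traction-free normal channel used to eliminate the pressure for
    incompressible materials (None for compressible experiments).
    """

    protocol: LoadingProtocol
    control: np.ndarray
    F: np.ndarray
    stress: np.ndarray
    channels: list[tuple[int, int]]
    pressure_channel: tuple[int, int] | None = None
    weight: float = 1.0

    def __post_init__(self):
        d = np.diff(self.control)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ConfigurationError("control values must be strictly monotone")


@dataclass
class ExperimentSet:
    experiments: list[Experiment]
    noise_model: str = "none"
    noise_sd: float = 0.0
    seed: int | None = None

    def n_points(self) -> int:
        return sum(e.stress.size for e in self.experiments)


def _protocol_channels(model: MaterialModel, protocol: LoadingProtocol):
    """Measured channels and pressure-elimination channel for a protocol."""
    if protocol.mode == "simple_shear":
        a, b = _shear_plane(protocol.plane)
        channels = [(a - 1, b - 1)]
        free = ({0, 1, 2} - {a - 1, b - 1}).pop()
    elif protocol.mode == "uniaxial":
        a, _, c = _axes(protocol)
        channels, free = [(a, a)], c
    elif protocol.mode in ("equibiaxial", "biaxial_ratio"):
        a, b, c = _axes(protocol)
        channels, free = [(a, a), (b, b)], c
    else:  # volumetric
        channels, free = [(0, 0)], 2
    pressure = (free, free) if model.is_incompressible else None
    return channels, pressure


def simulate_dataset(
    model: MaterialModel,
    protocols,
    noise_sd: float = 0.0,
    seed: int | None = None,
    noise_model: str = "additive",
) -> ExperimentSet:
    """Generate synthetic experiments by running the drivers on ``model``.

    With ``noise_sd = 0`` the stresses equal the driver curves exactly.
    Gaussian noise is applied to the stress channels, either ``additive``
    (in stress units) or ``multiplicative`` (relative); the generator is
    seeded so datasets are reproducible.
    """
    if noise_model not in ("additive", "multiplicative"):
        raise ConfigurationError(f"unknown noise model {noise_model!r}")
    rng = np.random.default_rng(seed)
    experiments = []
    for protocol in protocols:
        curve = run_protocol(model, protocol)
        if curve.truncated_reason:
            raise ConfigurationError(
                f"generator model cannot run the protocol: {curve.truncated_reason}"
            )
        df = curve.data
        F = df[[f"F{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]].to_numpy().reshape(
            -1, 3, 3
        )
        channels, pressure = _protocol_channels(model, protocol)
        cols = {(0, 0): "s11", (1, 1): "s22", (2, 2): "s33",
                (0, 1): "s12", (0, 2): "s13", (1, 2): "s23"}
        stress = df[[cols[ch] for ch in channels]].to_numpy()
        if noise_sd > 0:
            if noise_model == "additive":
                stress = stress + rng.normal(0.0, noise_sd, stress.shape)
            else:
                stress = stress * (1.0 + rng.normal(0.0, noise_sd, stress.shape))
        experiments.append(
            Experiment(
                protocol=protocol,
                control=df["control"].to_numpy(),
                F=F,
                stress=stress,
                channels=channels,
                pressure_channel=pressure,
            )
        )
    return ExperimentSet(
        experiments=experiments,
        noise_model=noise_model if noise_sd > 0 else "none",
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# prediction machinery
# ---------------------------------------------------------------------------


class _Design:
    """Frozen per-point kinematics for fast weight-only re-evaluation."""

    def __init__(self, template: MaterialModel, data: ExperimentSet):
        self.template = template
        self.devs: list[dict[int, float]] = []  # per point: slot -> deviation
        self.gchan: list[dict[int, np.ndarray]] = []  # slot -> channel G values
        self.y: list[float] = []
        self.w: list[float] = []
        self.point_channels: list[int] = []  # observation -> experiment index
        slots_needed = set()
        mixed_map = {m.id: m for m in template.mixed}
        for r in template.rows:
            if r.kfinv >= 101:
                slots_needed.update(mixed_map[r.kfinv].base_slots())
            else:
                slots_needed.add(r.kfinv)
        slots_needed = sorted(slots_needed)

        for ei, exp in enumerate(data.experiments):
            sw = np.sqrt(exp.weight)
            for t in range(exp.F.shape[0]):
                state = decompose(exp.F[t])
                inv = compute_invariants(state, template.fibers)
                G = invariant_gradients(state, template.fibers, slots_needed)
                dev = {s: inv.require(s) for s in slots_needed}
                gch = {}
                for s in slots_needed:
                    vals = np.empty(len(exp.channels))
                    for q, (i, j) in enumerate(exp.channels):
                        g = G[s][i, j]
                        if i == j and exp.pressure_channel is not None:
                            pi, pj = exp.pressure_channel
                            g -= G[s][pi, pj]
                        vals[q] = g
                    gch[s] = vals
                # mixed invariants are linear: fold their slots in directly
                for mid, mdef in mixed_map.items():
                    dev[mid] = sum(
                        mdef.coeff[s - 1] * dev[s] for s in mdef.base_slots()
                    )
                    gch[mid] = sum(
                        mdef.coeff[s - 1] * gch[s] for s in mdef.base_slots()
                    )
                self.devs.append(dev)
                self.gchan.append(gch)
                for q in range(len(exp.channels)):
                    self.y.append(exp.stress[t, q] * sw)
                    self.w.append(sw)
                    self.point_channels.append(len(self.devs) - 1)
        self.y = np.asarray(self.y)
        self.w = np.asarray(self.w)
        self._chan_of_obs = []
        k = 0
        for exp in data.experiments:
            for t in range(exp.F.shape[0]):
                for q in range(len(exp.channels)):
                    self._chan_of_obs.append(q)
                k += 1
        self._chan_of_obs = np.asarray(self._chan_of_obs)

    def row_column(self, row, w1: float) -> np.ndarray:
        """Weighted unit-stress column of one table row (w2 = 1)."""
        spec = ActivationSpec(row.kf0, row.kf1, row.kf2, row.w0, w1, 1.0)
        col = np.empty(self.y.shape[0])
        for o in range(self.y.shape[0]):
            p = self.point_channels[o]
            dev = self.devs[p][row.kfinv]
            try:
                _, dpsi, _ = neuron_contribution(spec, dev)
            except DomainError:
                dpsi = np.nan
            col[o] = dpsi * self.gchan[p][row.kfinv][self._chan_of_obs[o]]
        return col * self.w

    def matrix(self, rows, w1s) -> np.ndarray:
        return np.column_stack([self.row_column(r, w1) for r, w1 in zip(rows, w1s)])


def _soft(x: float, thr: float) -> float:
    return np.sign(x) * max(abs(x) - thr, 0.0)


def _lasso_cd(A, y, l1, nonneg, w0=None, max_pass=5000, tol=1e-13):
    """Exact coordinate descent for ||A w - y||^2 + l1 ||w||_1 (w >= 0 opt.)."""
    n, p = A.shape
    w = np.zeros(p) if w0 is None else np.array(w0, dtype=float)
    norms = np.einsum("ij,ij->j", A, A)
    r = y - A @ w
    for _ in range(max_pass):
        delta = 0.0
        for k in range(p):
            if norms[k] == 0.0:
                continue
            rho = A[:, k] @ r + norms[k] * w[k]
            if nonneg:
                wk = max(0.0, (rho - l1 / 2.0) / norms[k])
            else:
                wk = _soft(rho, l1 / 2.0) / norms[k]
            if wk != w[k]:
                r = r + A[:, k] * (w[k] - wk)
                delta = max(delta, abs(wk - w[k]))
                w[k] = wk
        if delta <= tol * (1.0 + np.max(np.abs(w), initial=0.0)):
            break
    return w


@dataclass
class FitResult:
    """Fitted model with goodness of fit and the optimizer trace."""

    model: MaterialModel
    r2: list[float] = field(default_factory=list)
    r2_mean: float = np.nan
    objective: float = np.nan
    iteration_log: list[float] = field(default_factory=list)
    converged: bool = True


def fit_weights(
    template: MaterialModel,
    data: ExperimentSet,
    l1_alpha: float = 0.0,
    nonneg: bool = True,
    max_outer: int = 40,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit free table weights to an experiment set.

    Rows flagged ``free_w2`` / ``free_w1`` are fitted; if no row carries a
    flag, every ``w2`` is treated as free (the common "fit the outer layer"
    case). The objective is the weighted residual sum of squares plus
    ``l1_alpha * sum |w2|`` over the free outer weights, with ``w2 >= 0``
    (and free ``w1 >= 0``) enforced when ``nonneg``.
    """
    rows = template.rows
    if not rows:
        raise ConfigurationError("template has no rows")
    if not data.experiments:
        raise ConfigurationError("experiment set is empty")
    free_w2 = [r.free_w2 for r in rows]
    if not any(free_w2) :
        free_w2 = [True] * len(rows)
    free_w1 = [r.free_w1 for r in rows]
    if not (any(free_w2) or any(free_w1)):
        raise ConfigurationError("template has no free weights")

    design = _Design(template, data)
    y = design.y
    idx_w2 = [i for i, f in enumerate(free_w2) if f]
    idx_w1 = [i for i, f in enumerate(free_w1) if f]

    def objective_and_state(w1_all, w2_all):
        A = design.matrix(rows, w1_all)
        resid = A @ w2_all - y
        resid = np.nan_to_num(resid, nan=1e6)
        return float(resid @ resid + l1_alpha * np.sum(np.abs(w2_all[idx_w2])))

    def solve_linear(w1_all, w2_all):
        A = design.matrix(rows, w1_all)
        A = np.nan_to_num(A, nan=0.0)
        fixed = A[:, [i for i in range(len(rows)) if i not in idx_w2]]
        w_fixed = np.array([w2_all[i] for i in range(len(rows)) if i not in idx_w2])
        target = y - (fixed @ w_fixed if w_fixed.size else 0.0)
        Afree = A[:, idx_w2]
        if l1_alpha == 0.0 and not nonneg:
            sol, *_ = np.linalg.lstsq(Afree, target, rcond=None)
        else:
            sol = _lasso_cd(Afree, target, l1_alpha, nonneg,
                            w0=[w2_all[i] for i in idx_w2])
        out = np.array(w2_all, dtype=float)
        out[idx_w2] = sol
        return out

    def solve_joint(w1_all, w2_all):
        """Smooth joint trust-region fit of free (w1, w2); ignores the penalty."""
        x0 = np.concatenate([w1_all[idx_w1], w2_all[idx_w2]])
        lb = 0.0 if nonneg else -np.inf
        n1 = len(idx_w1)

        def unpack(x):
            w1 = np.array(w1_all, dtype=float)
            w2 = np.array(w2_all, dtype=float)
            w1[idx_w1] = x[:n1]
            w2[idx_w2] = x[n1:]
            return w1, w2

        def resid(x):
            w1, w2 = unpack(x)
            r = design.matrix(rows, w1) @ w2 - y
            return np.nan_to_num(r, nan=1e6)

        sol = least_squares(resid, np.clip(x0, lb, np.inf) if nonneg else x0,
                            bounds=(lb, np.inf), method="trf", xtol=1e-14,
                            ftol=1e-14, gtol=1e-14)
        return unpack(sol.x)

    def solve_w1_only(w1_all, w2_all):
        if not idx_w1:
            return w1_all
        x0 = np.array(w1_all[idx_w1], dtype=float)
        lb = 0.0 if nonneg else -np.inf

        def resid(x):
            w1 = np.array(w1_all, dtype=float)
            w1[idx_w1] = x
            r = design.matrix(rows, w1) @ w2_all - y
            return np.nan_to_num(r, nan=1e6)

        sol = least_squares(resid, np.clip(x0, lb, np.inf) if nonneg else x0,
                            bounds=(lb, np.inf), method="trf", xtol=1e-12)
        out = np.array(w1_all, dtype=float)
        out[idx_w1] = sol.x
        return out

    rng = np.random.default_rng(seed)
    starts = n_starts if len(idx_w1) >= 2 else 1
    best = None
    for s in range(starts):
        w1_all = np.array([r.w1 for r in rows], dtype=float)
        w2_all = np.array([r.w2 for r in rows], dtype=float)
        if s > 0:
            w1_all[idx_w1] = np.abs(w1_all[idx_w1]) * rng.lognormal(0.0, 1.0, len(idx_w1))
        logbook = [objective_and_state(w1_all, w2_all)]
        converged = False
        if l1_alpha == 0.0:
            # pure smooth problem: one joint trust-region solve (after a linear
            # warm start so w2 begins at its exact conditional optimum)
            w2_all = solve_linear(w1_all, w2_all)
            logbook.append(objective_and_state(w1_all, w2_all))
            if idx_w1:
                w1_all, w2_all = solve_joint(w1_all, w2_all)
                logbook.append(objective_and_state(w1_all, w2_all))
            converged = True
        else:
            # penalized: exact L1 coordinate passes on w2 alternated with
            # w1-only smooth steps (both are descent steps on the objective)
            obj = logbook[0]
            for _ in range(max_outer):
                w2_all = solve_linear(w1_all, w2_all)
                w1_all = solve_w1_only(w1_all, w2_all)
                new_obj = objective_and_state(w1_all, w2_all)
                logbook.append(new_obj)
                if obj - new_obj <= 1e-12 * max(1.0, obj):
                    converged = True
                    break
                obj = new_obj
        obj = logbook[-1]
        norm = float(np.linalg.norm(w2_all) + np.linalg.norm(w1_all))
        cand = (obj, norm, w1_all.copy(), w2_all.copy(), logbook, converged)
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand

    obj, _, w1_all, w2_all, logbook, converged = best
    fitted = template.with_weights(w1=list(w1_all), w2=list(w2_all))
    r2_list, r2_mean = r_squared(fitted, data)
    return FitResult(
        model=fitted,
        r2=r2_list,
        r2_mean=r2_mean,
        objective=obj,
        iteration_log=logbook,
        converged=converged,
    )


def predict_channels(model: MaterialModel, exp: Experiment) -> np.ndarray:
    """Model stress on an experiment's channels at its stored deformations."""
    out = np.empty_like(exp.stress)
    for t in range(exp.F.shape[0]):
        state, _, acc = energy_derivatives(model, exp.F[t])
        sigma = _assemble_stress(model, state, acc)
        for q, (i, j) in enumerate(exp.channels):
            v = sigma[i, j]
            if i == j and exp.pressure_channel is not None:
                pi, pj = exp.pressure_channel
                v -= sigma[pi, pj]
            out[t, q] = v
    return out


def r_squared(model: MaterialModel, data: ExperimentSet):
    """Coefficient of determination per experiment channel and their mean.

    Channels with zero stress variance are undefined and reported as NaN;
    the mean is taken over the defined channels (unweighted).
    """
    values = []
    for exp in data.experiments:
        pred = predict_channels(model, exp)
        for q in range(len(exp.channels)):
            y = exp.stress[:, q]
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            if ss_tot == 0.0:
                values.append(np.nan)
                continue
            ss_res = float(np.sum((y - pred[:, q]) ** 2))
            values.append(1.0 - ss_res / ss_tot)
    defined = [v for v in values if not np.isnan(v)]
    mean = float(np.mean(defined)) if defined else np.nan
    return values, mean


def count_submodels(n_terms: int) -> int:
    """Size of the discovery library spanned by ``n_terms`` on/off terms."""
    if n_terms < 0:
        raise ConfigurationError("n_terms must be non-negative")
    return 2 ** int(n_terms)
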