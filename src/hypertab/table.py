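"""Parameter-table dialect (parse / validate / serialize) and model catalog.

A material is specified as keyword blocks of plain text::

    *PARAMETER TABLE, TYPE="UNIVERSAL_TAB"
    kfinv, kf0, kf1, kf2, w0, w1, w2
    ...
    *PARAMETER TABLE, TYPE="MIXED_INV"
    row, c1, c2, ..., c15

Each UNIVERSAL_TAB row is one additive energy term: an invariant slot (or a
mixed-invariant id >= 101), three activation selectors, and three weights.
Each MIXED_INV row defines mixed invariant ``100 + row`` as a linear
combination of the 15 base invariant deviations, with column j carrying the
coefficient on base slot j.

Keyword matching is case-insensitive and quotes around TYPE are optional on
input; output is emitted in the exact uppercase quoted form above. Comment
lines starting with ``**`` and blank lines are ignored. Floats are written
with shortest round-trip precision (17 significant digits where needed).

The catalog ships the classical models (neo-Hooke, Mooney-Rivlin, Yeoh,
polynomial, Holzapfel, Kaliske, Holzapfel fiber dispersion) and the published
best-fit soft-tissue models for brain, skin, artery, heart valve, and
myocardium, each with its fitted parameters as defaults and a sensible
default fiber frame. Unit tags (kPa / MPa) are metadata only; no conversion
is performed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import CatalogError, ConfigurationError, ParseError
from .kinematics import (
    N_SLOTS,
    FiberFrame,
    MixedInvariantDef,
    slot_components,
    slots_available,
)
from .network import F2_LOG, ActivationSpec

__all__ = [
    "ParameterRow",
    "MaterialModel",
    "ValidationReport",
    "parse",
    "serialize",
    "validate",
    "catalog",
    "catalog_names",
    "catalog_models",
    "CATALOG_VARIANTS",
]


@dataclass(frozen=True)
class ParameterRow:
    """One seven-column table row; ``free_*`` flags mark calibration unknowns."""

    kfinv: int
    kf0: int
    kf1: int
    kf2: int
    w0: float = 1.0
    w1: float = 1.0
    w2: float = 1.0
    free_w1: bool = False
    free_w2: bool = False

    def __post_init__(self):
        # selector validation happens eagerly so bad rows fail at build time
        ActivationSpec(self.kf0, self.kf1, self.kf2, self.w0, self.w1, self.w2)
        if not math.isfinite(self.w2):
            raise ConfigurationError("row weight w2 must be finite")
        if not (1 <= self.kfinv <= N_SLOTS or self.kfinv >= 101):
            raise ConfigurationError(f"invariant slot {self.kfinv} out of range")

    @property
    def spec(self) -> ActivationSpec:
        return ActivationSpec(self.kf0, self.kf1, self.kf2, self.w0, self.w1, self.w2)


@dataclass
class MaterialModel:
    """Ordered parameter rows, mixed-invariant definitions and a fiber frame."""

    rows: list[ParameterRow] = field(default_factory=list)
    mixed: list[MixedInvariantDef] = field(default_factory=list)
    fibers: FiberFrame = field(default_factory=lambda: FiberFrame.from_vectors())
    units: str = "kPa"
    name: str | None = None

    @property
    def has_volumetric(self) -> bool:
        """True if any row acts on the volumetric slot 3 (directly or mixed)."""
        mixed_on_3 = {m.id for m in self.mixed if m.coeff[2] != 0.0}
        return any(r.kfinv == 3 or r.kfinv in mixed_on_3 for r in self.rows)

    @property
    def is_incompressible(self) -> bool:
        return not self.has_volumetric

    def mixed_def(self, mid: int) -> MixedInvariantDef:
        for m in self.mixed:
            if m.id == mid:
                return m
        raise ConfigurationError(f"mixed invariant {mid} is not defined")

    def with_fibers(self, fibers: FiberFrame) -> "MaterialModel":
        return replace(self, fibers=fibers)

    def with_weights(self, w1=None, w2=None) -> "MaterialModel":
        """Copy with per-row weights replaced (None entries keep the old value)."""
        rows = []
        for i, r in enumerate(self.rows):
            nw1 = r.w1 if w1 is None or w1[i] is None else float(w1[i])
            nw2 = r.w2 if w2 is None or w2[i] is None else float(w2[i])
            rows.append(replace(r, w1=nw1, w2=nw2))
        return replace(self, rows=rows)


# ---------------------------------------------------------------------------
# parse / serialize
# ---------------------------------------------------------------------------

_KEYWORD_RE = re.compile(
    r"^\*\s*parameter\s+table\s*,\s*type\s*=\s*\"?(?P<type>[A-Za-z_]+)\"?\s*$",
    re.IGNORECASE,
)


def _parse_number(tok: str, lineno: int) -> float:
    try:
        return float(tok)
    except ValueError:
        raise ParseError(f"non-numeric field {tok!r}", line=lineno) from None


def _parse_int(tok: str, lineno: int) -> int:
    val = _parse_number(tok, lineno)
    if val != int(val):
        raise ParseError(f"expected an integer, got {tok!r}", line=lineno)
    return int(val)


def parse(text: str) -> MaterialModel:
    """Parse keyword blocks into a model fragment (rows and mixed defs).

    Fiber directions are not part of the dialect; attach them afterwards with
    :meth:`MaterialModel.with_fibers`.
    """
    rows: list[ParameterRow] = []
    mixed: list[MixedInvariantDef] = []
    block: str | None = None
    seen_block = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            m = _KEYWORD_RE.match(line)
            if not m:
                raise ParseError(f"unrecognized keyword line {line!r}", line=lineno)
            block = m.group("type").upper()
            if block not in ("UNIVERSAL_TAB", "MIXED_INV"):
                raise ParseError(f"unknown TYPE {block!r}", line=lineno)
            seen_block = True
            continue
        if block is None:
            raise ParseError("data row before any *PARAMETER TABLE keyword", line=lineno)
        toks = [t.strip() for t in line.rstrip(",").split(",")]
        if block == "UNIVERSAL_TAB":
            if len(toks) != 7:
                raise ParseError(
                    f"UNIVERSAL_TAB row needs 7 fields, got {len(toks)}", line=lineno
                )
            try:
                rows.append(
                    ParameterRow(
                        kfinv=_parse_int(toks[0], lineno),
                        kf0=_parse_int(toks[1], lineno),
                        kf1=_parse_int(toks[2], lineno),
                        kf2=_parse_int(toks[3], lineno),
                        w0=_parse_number(toks[4], lineno),
                        w1=_parse_number(toks[5], lineno),
                        w2=_parse_number(toks[6], lineno),
                    )
                )
            except ConfigurationError as err:
                raise ParseError(str(err), line=lineno) from err
        else:
            if len(toks) != 16:
                raise ParseError(
                    f"MIXED_INV row needs 16 fields, got {len(toks)}", line=lineno
                )
            row_id = _parse_int(toks[0], lineno)
            coeff = [_parse_number(t, lineno) for t in toks[1:]]
            try:
                mixed.append(MixedInvariantDef(id=100 + row_id, coeff=np.array(coeff)))
            except ConfigurationError as err:
                raise ParseError(str(err), line=lineno) from err

    if not seen_block:
        raise ParseError("no *PARAMETER TABLE block found")
    return MaterialModel(rows=rows, mixed=mixed)


def _fmt(x: float) -> str:
    return repr(float(x))


def serialize(model: MaterialModel) -> str:
    """Emit the model in the exact keyword dialect; re-parses to equality."""
    lines: list[str] = []
    if model.mixed:
        lines.append('*PARAMETER TABLE, TYPE="MIXED_INV"')
        for m in model.mixed:
            coeffs = ", ".join(_fmt(c) for c in m.coeff)
            lines.append(f"{m.id - 100}, {coeffs}")
    lines.append('*PARAMETER TABLE, TYPE="UNIVERSAL_TAB"')
    for r in model.rows:
        lines.append(
            f"{r.kfinv}, {r.kf0}, {r.kf1}, {r.kf2}, "
            f"{_fmt(r.w0)}, {_fmt(r.w1)}, {_fmt(r.w2)}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate(model: MaterialModel, fibers: FiberFrame | None = None) -> ValidationReport:
    """Static checks of a model against a fiber frame.

    Unavailable invariant slots are hard errors; suspicious weights (negative
    w2, negative w1 outside the logarithmic volumetric convention) are
    warnings because they void the term-wise polyconvexity guarantee.
    """
    fibers = fibers if fibers is not None else model.fibers
    avail = slots_available(fibers.n_dir)
    rep = ValidationReport()
    mixed_ids = {m.id for m in model.mixed}

    for m in model.mixed:
        for slot in m.base_slots():
            if slot not in avail:
                fam, a, b = slot_components(slot)
                rep.errors.append(
                    f"mixed invariant {m.id} uses slot {slot} "
                    f"(family {b} fibers required, {fibers.n_dir} declared)"
                )

    for i, r in enumerate(model.rows, start=1):
        if r.kfinv >= 101:
            if r.kfinv not in mixed_ids:
                rep.errors.append(f"row {i}: mixed invariant {r.kfinv} is undefined")
        elif r.kfinv not in avail:
            _, _, b = slot_components(r.kfinv)
            rep.errors.append(
                f"row {i}: slot {r.kfinv} needs fiber family {b}, "
                f"only {fibers.n_dir} declared"
            )
        if r.w2 < 0:
            rep.warnings.append(f"row {i}: negative w2 voids polyconvexity")
        if r.w1 < 0 and r.kf2 != F2_LOG:
            rep.warnings.append(f"row {i}: negative w1 voids polyconvexity")
        if r.kf2 == F2_LOG:
            rep.notes.append(
                f"row {i}: logarithm branch, admissible only while w1*f1 < 1"
            )

    if not model.has_volumetric:
        rep.warnings.append(
            "no volumetric (slot 3) row: incompressible-only model, "
            "stress determinate only up to a pressure"
        )
    return rep


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


def _vol_ogden_style(D: float) -> list[ParameterRow]:
    """Three-row volumetric set equal to (1/D)[(I3^2-1)/2 - ln I3]."""
    return [
        ParameterRow(3, 1, 1, 1, 1.0, 1.0, 1.0 / D),
        ParameterRow(3, 1, 2, 1, 1.0, 0.5, 1.0 / D),
        ParameterRow(3, 1, 1, 3, 1.0, -1.0, 1.0 / D),
    ]


def _two_fiber_frame(angle_deg: float) -> FiberFrame:
    a = math.radians(angle_deg)
    return FiberFrame.from_vectors(
        [math.cos(a), math.sin(a), 0.0], [math.cos(a), -math.sin(a), 0.0]
    )


def _dispersion_mixed(kappa: float) -> list[MixedInvariantDef]:
    c1 = np.zeros(N_SLOTS)
    c1[0] = kappa
    c1[3] = 1.0 - 3.0 * kappa  # slot 4 = I4(11)
    c2 = np.zeros(N_SLOTS)
    c2[0] = kappa
    c2[7] = 1.0 - 3.0 * kappa  # slot 8 = I4(22)
    return [MixedInvariantDef(101, c1), MixedInvariantDef(102, c2)]


def _neo_hooke(C10=1.0, D1=None, units="kPa"):
    rows = [ParameterRow(1, 1, 1, 1, 1.0, 1.0, C10)]
    if D1 is not None:
        rows.append(ParameterRow(3, 1, 2, 1, 1.0, 1.0, 1.0 / D1))
    return MaterialModel(rows=rows, units=units, name="neo_hooke")


def _mooney_rivlin(C10=1.0, C01=0.5, D1=None, units="kPa"):
    rows = [
        ParameterRow(1, 1, 1, 1, 1.0, 1.0, C10),
        ParameterRow(2, 1, 1, 1, 1.0, 1.0, C01),
    ]
    if D1 is not None:
        rows.append(ParameterRow(3, 1, 2, 1, 1.0, 1.0, 1.0 / D1))
    return MaterialModel(rows=rows, units=units, name="mooney_rivlin")


def _yeoh(C10=1.0, C20=0.3, C30=0.1, D1=1.0, D2=1.0, D3=1.0, units="kPa"):
    rows = [
        ParameterRow(1, 1, 1, 1, 1.0, 1.0, C10),
        ParameterRow(1, 1, 2, 1, 1.0, 1.0, C20),
        ParameterRow(1, 1, 3, 1, 1.0, 1.0, C30),
        ParameterRow(3, 1, 2, 1, 1.0, 1.0, 1.0 / D1),
        ParameterRow(3, 1, 4, 1, 1.0, 1.0, 1.0 / D2),
        ParameterRow(3, 1, 6, 1, 1.0, 1.0, 1.0 / D3),
    ]
    return MaterialModel(rows=rows, units=units, name="yeoh")


def _polynomial(N=2, C=None, D=None, units="kPa"):
    N = int(N)
    C = list(C) if C is not None else [1.0 / (i + 1) for i in range(N)]
    D = list(D) if D is not None else [1.0] * N
    if len(C) != N or len(D) != N:
        raise CatalogError(f"polynomial needs {N} C and {N} D coefficients")
    rows = [ParameterRow(1, 1, i + 1, 1, 1.0, 1.0, C[i]) for i in range(N)]
    rows += [ParameterRow(3, 1, 2 * (i + 1), 1, 1.0, 1.0, 1.0 / D[i]) for i in range(N)]
    return MaterialModel(rows=rows, units=units, name="polynomial")


def _holzapfel(C10=1.0, k1=1.0, k2=1.0, D=1.0, angle_deg=45.0, units="kPa"):
    rows = [
        ParameterRow(1, 1, 1, 1, 1.0, 1.0, C10),
        ParameterRow(4, 2, 2, 2, 1.0, k2, k1 / (2.0 * k2)),
        ParameterRow(8, 2, 2, 2, 1.0, k2, k1 / (2.0 * k2)),
        *_vol_ogden_style(D),
    ]
    return MaterialModel(
        rows=rows, fibers=_two_fiber_frame(angle_deg), units=units, name="holzapfel"
    )


def _kaliske(a=(1.0, 0.2, 0.1), b=(0.5, 0.1, 0.05), c=None, d=None, e=None, f=None,
             D=1.0, angle_deg=30.0, units="kPa"):
    c = list(c) if c is not None else [0.3, 0.15, 0.08, 0.04, 0.02]
    d = list(d) if d is not None else [0.2, 0.1, 0.05, 0.025, 0.0125]
    e = list(e) if e is not None else [0.25, 0.12, 0.06, 0.03, 0.015]
    f = list(f) if f is not None else [0.15, 0.08, 0.04, 0.02, 0.01]
    rows = [ParameterRow(1, 1, i + 1, 1, 1.0, 1.0, ai) for i, ai in enumerate(a)]
    rows += [ParameterRow(2, 1, j + 1, 1, 1.0, 1.0, bj) for j, bj in enumerate(b)]
    for slot, coeffs in ((4, c), (5, d), (8, e), (9, f)):
        rows += [
            ParameterRow(slot, 1, k + 2, 1, 1.0, 1.0, ck) for k, ck in enumerate(coeffs)
        ]
    rows += _vol_ogden_style(D)
    return MaterialModel(
        rows=rows, fibers=_two_fiber_frame(angle_deg), units=units, name="kaliske"
    )


def _holzapfel_dispersion(C10=1.0, k1=1.0, k2=1.0, kappa=0.074, D=1.0,
                          angle_deg=45.0, units="kPa"):
    rows = [
        ParameterRow(1, 1, 1, 1, 1.0, 1.0, C10),
        ParameterRow(101, 2, 2, 2, 1.0, k2, k1 / (2.0 * k2)),
        ParameterRow(102, 2, 2, 2, 1.0, k2, k1 / (2.0 * k2)),
        *_vol_ogden_style(D),
    ]
    return MaterialModel(
        rows=rows,
        mixed=_dispersion_mixed(kappa),
        fibers=_two_fiber_frame(angle_deg),
        units=units,
        name="holzapfel_dispersion",
    )


_BRAIN_MR = {"gray": (0.0021, 1.8817), "white": (0.0168, 0.9697)}
_BRAIN_BK = {"gray": 1.9043, "white": 0.9556}
# six-term brain model weights: mu1, (a1, b1), (alpha1, beta1), mu2, (a2, b2),
# (alpha2, beta2); zero-weight terms are dropped from the table
_BRAIN_SIX = {
    "gray": dict(mu1=0.0, a1=0.0, b1=1.0, alpha1=1.2520, beta1=0.9875,
                 mu2=3.8007, a2=6.2285, b2=1.6495, alpha2=4.6743, beta2=1.6663),
    "white": dict(mu1=0.2215, a1=0.2350, b1=0.2398, alpha1=0.0, beta1=1.0,
                  mu2=0.0, a2=6.3703, b2=1.8893, alpha2=4.5065, beta2=1.1789),
}


def _brain_mooney_rivlin(variant="gray", units="kPa"):
    mu1, mu2 = _BRAIN_MR[variant]
    rows = [
        ParameterRow(1, 1, 1, 1, 1.0, 1.0, mu1 / 2.0),
        ParameterRow(2, 1, 1, 1, 1.0, 1.0, mu2 / 2.0),
    ]
    return MaterialModel(rows=rows, units=units, name=f"brain_mooney_rivlin:{variant}")


def _brain_blatz_ko(variant="gray", units="kPa"):
    mu = _BRAIN_BK[variant]
    rows = [ParameterRow(2, 1, 1, 1, 1.0, 1.0, mu / 2.0)]
    return MaterialModel(rows=rows, units=units, name=f"brain_blatz_ko:{variant}")


def _brain_six_term(variant="gray", units="kPa"):
    p = _BRAIN_SIX[variant]
    candidates = [
        ParameterRow(2, 1, 1, 1, 1.0, 1.0, p["mu1"]),
        ParameterRow(2, 1, 1, 2, 1.0, p["b1"], p["a1"] / (2.0 * p["b1"])),
        ParameterRow(2, 1, 1, 3, 1.0, p["beta1"], p["alpha1"] / (2.0 * p["beta1"])),
        ParameterRow(2, 1, 2, 1, 1.0, 1.0, p["mu2"]),
        ParameterRow(2, 1, 2, 2, 1.0, p["b2"], p["a2"] / (2.0 * p["b2"])),
        ParameterRow(2, 1, 2, 3, 1.0, p["beta2"], p["alpha2"] / (2.0 * p["beta2"])),
    ]
    rows = [r for r in candidates if r.w2 != 0.0]
    return MaterialModel(rows=rows, units=units, name=f"brain_six_term:{variant}")


def _skin_holzapfel(mu=0.2492, a4=0.1054, b4=10.7914, units="MPa"):
    rows = [
        ParameterRow(1, 1, 1, 1, 1.0, 1.0, mu),
        ParameterRow(4, 2, 2, 2, 1.0, b4, a4 / (2.0 * b4)),
    ]
    fibers = FiberFrame.from_vectors([1.0, 0.0, 0.0])
    return MaterialModel(rows=rows, fibers=fibers, units=units, name="skin_holzapfel")


def _skin_discovered(a1=1.3291, b1=0.8207, a4=0.2656, b4=0.3921, units="MPa"):
    rows = [
        ParameterRow(1, 1, 2, 2, 1.0, b1, a1 / (2.0 * b1)),
        ParameterRow(4, 2, 2, 2, 1.0, b4, a4 / (2.0 * b4)),
    ]
    fibers = FiberFrame.from_vectors([1.0, 0.0, 0.0])
    return MaterialModel(rows=rows, fibers=fibers, units=units, name="skin_discovered")


_ARTERY_DISC = {
    "media": dict(mu1=33.45, a=3.74, b=6.66, mu5=2.17, angle=7.00),
    "adventitia": dict(mu1=8.30, a=1.42, b=6.34, mu5=0.49, angle=66.78),
}
_ARTERY_DISP = {
    "media": dict(mu=48.68, a=6.67, b=23.17, kappa=0.074, angle=7.00),
    "adventitia": dict(mu=13.22, a=0.93, b=12.06, kappa=0.091, angle=66.78),
}


def _artery_discovered(variant="media", units="kPa"):
    p = _ARTERY_DISC[variant]
    rows = [
        ParameterRow(1, 1, 1, 1, 1.0, 1.0, p["mu1"] / 2.0),
        ParameterRow(1, 1, 1, 2, 1.0, p["b"], p["a"] / (2.0 * p["b"])),
        ParameterRow(5, 2, 2, 1, 1.0, 1.0, p["mu5"] / 2.0),
        ParameterRow(9, 2, 2, 1, 1.0, 1.0, p["mu5"] / 2.0),
    ]
    return MaterialModel(
        rows=rows,
        fibers=_two_fiber_frame(p["angle"]),
        units=units,
        name=f"artery_discovered:{variant}",
    )


def _artery_holzapfel_dispersion(variant="media", units="kPa"):
    p = _ARTERY_DISP[variant]
    rows = [
        ParameterRow(1, 1, 1, 1, 1.0, 1.0, p["mu"] / 2.0),
        ParameterRow(101, 2, 2, 2, 1.0, p["b"], p["a"] / (2.0 * p["b"])),
        ParameterRow(102, 2, 2, 2, 1.0, p["b"], p["a"] / (2.0 * p["b"])),
    ]
    return MaterialModel(
        rows=rows,
        mixed=_dispersion_mixed(p["kappa"]),
        fibers=_two_fiber_frame(p["angle"]),
        units=units,
        name=f"artery_holzapfel_dispersion:{variant}",
    )


_VALVE = {
    "anterior": (1.0, 0.124, 4.57),
    "posterior": (1.0, 0.188, 14.86),
    "septal": (1.0, 0.191, 17.75),
}


def _valve_fung(variant="anterior", units="kPa"):
    c0, c1, c2 = _VALVE[variant]
    rows = [
        ParameterRow(1, 1, 1, 1, 1.0, 1.0, c0 / 2.0),
        ParameterRow(1, 1, 2, 2, 1.0, c2, c1 / 2.0),
    ]
    return MaterialModel(rows=rows, units=units, name=f"valve_fung:{variant}")


_HEART_FRAME = FiberFrame.from_vectors(
    [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]
)


def _heart_guan(a=0.782, b=7.248, af=4.488, bf=14.571, an=2.513, bn=10.929,
                afs=0.436, bfs=4.959, units="kPa"):
    rows = [
        ParameterRow(1, 1, 1, 2, 1.0, b, a / (2.0 * b)),
        ParameterRow(4, 2, 2, 2, 1.0, bf, af / (2.0 * bf)),
        ParameterRow(14, 2, 2, 2, 1.0, bn, an / (2.0 * bn)),
        ParameterRow(6, 1, 2, 2, 1.0, bfs, afs / (2.0 * bfs)),
    ]
    return MaterialModel(rows=rows, fibers=_HEART_FRAME, units=units, name="heart_guan")


def _heart_holzapfel_ortho(a=0.950, b=5.457, af=3.318, bf=23.701, as_=1.405,
                           bs=20.067, an=2.037, bn=16.976, afs=0.586, bfs=1.081,
                           asn=0.047, bsn=11.842, units="kPa"):
    rows = [
        ParameterRow(1, 1, 1, 2, 1.0, b, a / (2.0 * b)),
        ParameterRow(4, 2, 2, 2, 1.0, bf, af / (2.0 * bf)),
        ParameterRow(8, 2, 2, 2, 1.0, bs, as_ / (2.0 * bs)),
        ParameterRow(14, 2, 2, 2, 1.0, bn, an / (2.0 * bn)),
        ParameterRow(6, 1, 2, 2, 1.0, bfs, afs / (2.0 * bfs)),
        ParameterRow(12, 1, 2, 2, 1.0, bsn, asn / (2.0 * bsn)),
    ]
    return MaterialModel(
        rows=rows, fibers=_HEART_FRAME, units=units, name="heart_holzapfel_ortho"
    )


def _heart_discovered(mu=5.162, af=3.426, bf=21.151, an=2.754, bn=4.371,
                      afs=0.494, bfs=0.508, units="kPa"):
    rows = [
        ParameterRow(2, 1, 2, 1, 1.0, 1.0, mu / 2.0),
        ParameterRow(4, 2, 2, 2, 1.0, bf, af / (2.0 * bf)),
        ParameterRow(14, 2, 2, 2, 1.0, bn, an / (2.0 * bn)),
        ParameterRow(6, 1, 2, 2, 1.0, bfs, afs / (2.0 * bfs)),
    ]
    return MaterialModel(
        rows=rows, fibers=_HEART_FRAME, units=units, name="heart_discovered"
    )


_CATALOG = {
    "neo_hooke": _neo_hooke,
    "mooney_rivlin": _mooney_rivlin,
    "yeoh": _yeoh,
    "polynomial": _polynomial,
    "holzapfel": _holzapfel,
    "kaliske": _kaliske,
    "holzapfel_dispersion": _holzapfel_dispersion,
    "brain_mooney_rivlin": _brain_mooney_rivlin,
    "brain_blatz_ko": _brain_blatz_ko,
    "brain_six_term": _brain_six_term,
    "skin_holzapfel": _skin_holzapfel,
    "skin_discovered": _skin_discovered,
    "artery_discovered": _artery_discovered,
    "artery_holzapfel_dispersion": _artery_holzapfel_dispersion,
    "valve_fung": _valve_fung,
    "heart_guan": _heart_guan,
    "heart_holzapfel_ortho": _heart_holzapfel_ortho,
    "heart_discovered": _heart_discovered,
}

#: (name, variant) pairs covering every shipped parameterization
CATALOG_VARIANTS: tuple[tuple[str, str | None], ...] = (
    ("neo_hooke", None),
    ("mooney_rivlin", None),
    ("yeoh", None),
    ("polynomial", None),
    ("holzapfel", None),
    ("kaliske", None),
    ("holzapfel_dispersion", None),
    ("brain_mooney_rivlin", "gray"),
    ("brain_mooney_rivlin", "white"),
    ("brain_blatz_ko", "gray"),
    ("brain_blatz_ko", "white"),
    ("brain_six_term", "gray"),
    ("brain_six_term", "white"),
    ("skin_holzapfel", None),
    ("skin_discovered", None),
    ("artery_discovered", "media"),
    ("artery_discovered", "adventitia"),
    ("artery_holzapfel_dispersion", "media"),
    ("artery_holzapfel_dispersion", "adventitia"),
    ("valve_fung", "anterior"),
    ("valve_fung", "posterior"),
    ("valve_fung", "septal"),
    ("heart_guan", None),
    ("heart_holzapfel_ortho", None),
    ("heart_discovered", None),
)


def catalog_names() -> list[str]:
    return sorted(_CATALOG)


def catalog(name: str, **params) -> MaterialModel:
    """Build a cataloged model; parameters default to the published best fits."""
    try:
        builder = _CATALOG[name]
    except KeyError:
        raise CatalogError(
            f"unknown model {name!r}; available: {', '.join(catalog_names())}"
        ) from None
    return builder(**params)


def catalog_models():
    """Yield ``(label, model)`` for every shipped parameterization."""
    for name, variant in CATALOG_VARIANTS:
        kwargs = {"variant": variant} if variant else {}
        label = f"{name}:{variant}" if variant else name
        yield label, catalog(name, **kwargs)
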