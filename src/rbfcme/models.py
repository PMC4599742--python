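"""Reaction-network definitions for CME solvers.

A :class:`ReactionNetwork` is a list of reaction channels, each carrying an
integer stoichiometric vector (the jump caused by one firing) and a
propensity function over lattice states.  Propensities are vectorised: they
accept ``d`` integer arrays (one per species) and return an array of
non-negative rates, which lets generator assembly and SSA table
construction work on whole lattices at once.

Built-in systems:

* a bistable genetic toggle switch (two mutually repressing genes),
* its tristable three-species generalisation,
* the osteochondro switch (OCS) of mesenchymal stem-cell fate
  determination (progenitor / osteogenic / chondrogenic regulators),
* the self-regulating gene, a two-component master-equation system in
  which a gene flips between a free ("on") and repressor-bound ("off")
  state; the gene state is encoded as a second lattice axis of extent 2 so
  that the same operator machinery applies,
* simple birth-death chains for oracle tests,
* plain-text (YAML/JSON) configs with arithmetic-only propensity
  expressions.
"""

from __future__ import annotations

import ast
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = [
    "ReactionChannel",
    "ReactionNetwork",
    "ToggleParams",
    "OCSParams",
    "GeneModelParams",
    "build_toggle2d",
    "build_tristable3d",
    "build_ocs",
    "build_self_regulating_gene",
    "build_birth_death",
    "parse_network_config",
    "ConfigError",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when model parameters violate their invariants."""


class ConfigError(ValueError):
    """Raised when a network config file is malformed."""


@dataclass(frozen=True)
class ReactionChannel:
    """One reaction channel: stoichiometric jump plus propensity.

    Parameters
    ----------
    stoichiometry
        Integer change of the state vector caused by one firing.
    propensity
        Vectorised map from ``d`` coordinate arrays to non-negative rates.
    name
        Optional label used in diagnostics.
    """

    stoichiometry: tuple[int, ...]
    propensity: Callable[..., np.ndarray]
    name: str = ""

    def __call__(self, *coords) -> np.ndarray:
        coords = [np.asarray(c) for c in coords]
        if len(coords) != len(self.stoichiometry):
            raise ValueError(
                f"channel {self.name!r} expects {len(self.stoichiometry)} coordinates, "
                f"got {len(coords)}"
            )
        out = np.asarray(self.propensity(*coords), dtype=float)
        return np.broadcast_to(out, np.broadcast_shapes(*(c.shape for c in coords))).copy()


@dataclass(frozen=True)
class ReactionNetwork:
    """A reaction network over ``d`` species.

    ``components`` optionally labels one axis as a discrete (non-copy-number)
    component, e.g. the on/off gene state of the self-regulating gene; the
    axis is then part of the lattice like any species axis.
    """

    d: int
    channels: tuple[ReactionChannel, ...]
    name: str = "custom"
    params: dict = field(default_factory=dict)
    components: tuple[str, ...] | None = None
    component_axis: int | None = None

    def __post_init__(self):
        for ch in self.channels:
            if len(ch.stoichiometry) != self.d:
                raise ValueError(
                    f"channel {ch.name!r} stoichiometry has length "
                    f"{len(ch.stoichiometry)}, expected d={self.d}"
                )
        if (self.components is None) != (self.component_axis is None):
            raise ValueError("components and component_axis must be given together")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def propensities(self, *coords) -> list[np.ndarray]:
        """Evaluate all channel propensities at the given coordinate arrays."""
        return [ch(*coords) for ch in self.channels]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class ToggleParams:
    """Rate constants of the bi-/tri-stable toggle switch.

    Production of each species follows a repressing Hill function
    ``c_prod / (c_half + (sum of competitors)^exponent)``; degradation is
    linear.  For the 2-D switch only ``c1..c6`` and ``beta``/``gamma`` are
    used; the 3-D switch additionally needs ``c7..c9`` and ``zeta``.
    """

    c1: float
    c2: float
    c3: float
    c4: float
    c5: float
    c6: float
    beta: float = 2.0
    gamma: float = 2.0
    c7: float | None = None
    c8: float | None = None
    c9: float | None = None
    zeta: float | None = None

    def __post_init__(self):
        for name in ("c1", "c2", "c3", "c4", "c5", "c6"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("c7", "c8", "c9"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.beta < 1 or self.gamma < 1:
            raise ParameterError("Hill exponents must be >= 1")
        if self.zeta is not None and self.zeta < 1:
            raise ParameterError("Hill exponents must be >= 1")

    @classmethod
    def symmetric_bistable(cls) -> "ToggleParams":
        """The standard bistable parameter set (two modes near (225, 48))."""
        return cls(c1=3e3, c2=1.1e4, c3=1e-3, c4=3e3, c5=1.1e4, c6=1e-3)

    @classmethod
    def symmetric_tristable(cls) -> "ToggleParams":
        """Symmetric tristable set; equivariant under coordinate permutations."""
        return cls(
            c1=3e3, c2=1.1e4, c3=1e-3,
            c4=3e3, c5=1.1e4, c6=1e-3,
            c7=3e3, c8=1.1e4, c9=1e-3,
            beta=2.0, gamma=2.0, zeta=2.0,
        )

    @classmethod
    def scaled_tristable(cls) -> "ToggleParams":
        """A scaled-down tristable set with modes near coordinate ~29.

        Production is reduced tenfold (c_prod = 300) so the modes move from
        ~270 down to ~29 and the system fits a [0, 60]^3 box.  At such low
        copy numbers the relative fluctuation is ~3x larger, which would
        let noise wash the three corner modes into the central state; the
        Hill exponent is therefore steepened to 4, which restores the
        stationary topology of the full-scale system: a trimodal,
        permutation-symmetric distribution whose essential support is
        three-connected over a wide band of thresholds.
        """
        return cls(
            c1=300.0, c2=1.1e4, c3=1e-3,
            c4=300.0, c5=1.1e4, c6=1e-3,
            c7=300.0, c8=1.1e4, c9=1e-3,
            beta=4.0, gamma=4.0, zeta=4.0,
        )


@dataclass(frozen=True)
class OCSParams:
    """Parameters of the osteochondro switch (OCS) cell-differentiation model.

    Species are the osteogenic (x), chondrogenic (y) and progenitor (z)
    transcriptional regulators.  Each production propensity is a Hill-type
    ratio ``(a*s^beta + b) / (m + sum of c*inhibitor^beta terms)``;
    degradation is linear with rates ``k_*``.  ``z_o >= 0`` adds a
    pro-osteogenic stimulus to the numerator of the osteogenic production.
    """

    a_o: float = 0.1
    a_c: float = 0.1
    a_p: float = 0.2
    b_o: float = 1.0
    b_c: float = 1.0
    b_p: float = 0.5
    m_o: float = 1.0
    m_c: float = 1.0
    m_p: float = 10.0
    c_oo: float = 0.1
    c_cc: float = 0.1
    c_pp: float = 0.1
    c_oc: float = 0.1
    c_co: float = 0.1
    c_op: float = 0.5
    c_cp: float = 0.5
    k_o: float = 0.1
    k_c: float = 0.1
    k_p: float = 0.1
    beta: float = 2.0
    z_o: float = 0.0

    def __post_init__(self):
        for name in (
            "a_o", "a_c", "a_p", "b_o", "b_c", "b_p", "m_o", "m_c", "m_p",
            "c_oo", "c_cc", "c_pp", "c_oc", "c_co", "c_op", "c_cp",
            "k_o", "k_c", "k_p", "beta", "z_o",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.m_o <= 0 and self.c_oo == 0 and self.c_oc == 0 and self.c_op == 0:
            raise ParameterError("osteogenic Hill denominator vanishes on the lattice")
        if self.m_c <= 0 and self.c_cc == 0 and self.c_co == 0 and self.c_cp == 0:
            raise ParameterError("chondrogenic Hill denominator vanishes on the lattice")
        if self.m_p <= 0 and self.c_pp == 0:
            raise ParameterError("progenitor Hill denominator vanishes on the lattice")


@dataclass(frozen=True)
class GeneModelParams:
    """Parameters of the self-regulating gene.

    ``g_on``/``g_off`` are protein production rates with free / bound DNA,
    ``k`` the degradation rate, ``f`` the repressor release rate and ``h``
    the binding rate constant.  ``binding_mode`` selects the net binding
    rate h(x): ``"monomer"`` gives h*x, ``"dimer"`` gives (h/2)*x*(x-1).
    """

    g_on: float
    g_off: float
    k: float
    f: float
    h: float
    binding_mode: str = "monomer"

    def __post_init__(self):
        for name in ("g_on", "g_off", "k", "f", "h"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.binding_mode not in ("monomer", "dimer"):
            raise ParameterError(
                f"binding_mode must be 'monomer' or 'dimer', got {self.binding_mode!r}"
            )

    @property
    def X_ad(self) -> float:
        """Adiabatic parameter (g_on + g_off) / (2k)."""
        return (self.g_on + self.g_off) / (2.0 * self.k)

    @property
    def X_eq(self) -> float:
        """Binding equilibrium parameter f / h."""
        return self.f / self.h

    @property
    def omega(self) -> float:
        """Switching-to-degradation rate ratio f / k."""
        return self.f / self.k

    def h_of_x(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.binding_mode == "monomer":
            return self.h * x
        return 0.5 * self.h * x * (x - 1.0)


# ---------------------------------------------------------------------------
# built-in model builders


def build_toggle2d(params: ToggleParams) -> ReactionNetwork:
    """Two mutually repressing genes A (x) and B (y).

    Channels, in order: production of A, degradation of A, production of B,
    degradation of B.  Production of each species is repressed by the other
    through a Hill function.
    """
    p = params

    channels = (
        ReactionChannel((1, 0), lambda x, y: p.c1 / (p.c2 + y ** p.beta), "A+"),
        ReactionChannel((-1, 0), lambda x, y: p.c3 * x, "A-"),
        ReactionChannel((0, 1), lambda x, y: p.c4 / (p.c5 + x ** p.gamma), "B+"),
        ReactionChannel((0, -1), lambda x, y: p.c6 * y, "B-"),
    )
    return ReactionNetwork(2, channels, name="toggle2d", params={"params": p})


def build_tristable3d(params: ToggleParams) -> ReactionNetwork:
    """Three mutually competing species; production of each is repressed by
    the sum of the other two."""
    p = params
    if p.c7 is None or p.c8 is None or p.c9 is None or p.zeta is None:
        raise ParameterError("tristable switch needs c7, c8, c9 and zeta")

    channels = (
        ReactionChannel((1, 0, 0), lambda x, y, z: p.c1 / (p.c2 + (y + z) ** p.beta), "A+"),
        ReactionChannel((-1, 0, 0), lambda x, y, z: p.c3 * x, "A-"),
        ReactionChannel((0, 1, 0), lambda x, y, z: p.c4 / (p.c5 + (x + z) ** p.gamma), "B+"),
        ReactionChannel((0, -1, 0), lambda x, y, z: p.c6 * y, "B-"),
        ReactionChannel((0, 0, 1), lambda x, y, z: p.c7 / (p.c8 + (x + y) ** p.zeta), "C+"),
        ReactionChannel((0, 0, -1), lambda x, y, z: p.c9 * z, "C-"),
    )
    return ReactionNetwork(3, channels, name="tristable3d", params={"params": p})


def build_ocs(params: OCSParams | None = None) -> ReactionNetwork:
    """Osteochondro switch: x osteogenic, y chondrogenic, z progenitor.

    Same birth/death channel structure as the tristable switch, with
    asymmetric Hill-type production propensities.  A positive stimulus
    ``z_o`` is added to the numerator of the osteogenic production.
    """
    p = params if params is not None else OCSParams()
    b = p.beta

    def a1(x, y, z):
        return (p.a_o * x ** b + p.b_o + p.z_o) / (
            p.m_o + p.c_oo * x ** b + p.c_oc * y ** b + p.c_op * z ** b
        )

    def a3(x, y, z):
        return (p.a_c * y ** b + p.b_c) / (
            p.m_c + p.c_cc * y ** b + p.c_co * x ** b + p.c_cp * z ** b
        )

    def a5(x, y, z):
        return (p.a_p * z ** b + p.b_p) / (p.m_p + p.c_pp * z ** b)

    channels = (
        ReactionChannel((1, 0, 0), a1, "O+"),
        ReactionChannel((-1, 0, 0), lambda x, y, z: p.k_o * x, "O-"),
        ReactionChannel((0, 1, 0), a3, "C+"),
        ReactionChannel((0, -1, 0), lambda x, y, z: p.k_c * y, "C-"),
        ReactionChannel((0, 0, 1), a5, "P+"),
        ReactionChannel((0, 0, -1), lambda x, y, z: p.k_p * z, "P-"),
    )
    return ReactionNetwork(3, channels, name="ocs", params={"params": p})


def build_self_regulating_gene(params: GeneModelParams) -> ReactionNetwork:
    """Self-regulating gene as a master-equation system on a doubled lattice.

    State is (x, g) with protein count x on axis 0 and gene state g on
    axis 1 (g=0: DNA free, "on"; g=1: repressor bound, "off").  Channels:

    * production at rate g_on (on) / g_off (off),
    * degradation k*x within a gene state; from the off state, degradation
      below x=1 is excluded since the bound repressor is among the x
      proteins, keeping u_off(x<1) = 0,
    * binding on -> off at rate h(x),
    * release off -> on at rate f,
    * degradation of the bound repressor at x=1, which frees the DNA:
      off(1) -> on(0) at rate k.

    The h/f coupling terms are implemented in the probability-conserving
    orientation (binding moves mass from u_on to u_off, release moves it
    back), matching the verbal model; every column of the assembled
    generator sums to zero.
    """
    p = params

    def prod(x, g):
        return np.where(g == 0, p.g_on, p.g_off) * np.ones_like(np.asarray(x, dtype=float))

    def degrade(x, g):
        x = np.asarray(x, dtype=float)
        # off-state degradation is blocked at x=1 except through the
        # dedicated off(1)->on(0) channel
        allowed = (g == 0) | (x >= 2)
        return p.k * x * allowed

    def bind(x, g):
        return p.h_of_x(x) * (g == 0)

    def release(x, g):
        x = np.asarray(x, dtype=float)
        return p.f * ((g == 1) & (x >= 1))

    def unbind_by_decay(x, g):
        return p.k * ((g == 1) & (np.asarray(x) == 1))

    channels = (
        ReactionChannel((1, 0), prod, "prod"),
        ReactionChannel((-1, 0), degrade, "deg"),
        ReactionChannel((0, 1), bind, "bind"),
        ReactionChannel((0, -1), release, "release"),
        ReactionChannel((-1, -1), unbind_by_decay, "deg-unbind"),
    )
    return ReactionNetwork(
        2,
        channels,
        name="self_regulating_gene",
        params={"params": p},
        components=("on", "off"),
        component_axis=1,
    )


def build_birth_death(lam: float, mu: float) -> ReactionNetwork:
    """1-D birth-death chain: constant birth rate ``lam``, death rate ``mu*x``.

    Its stationary law on [0, N] is a truncated Poisson(lam/mu), which makes
    it the closed-form oracle used throughout the test suite.
    """
    if lam <= 0 or mu <= 0:
        raise ParameterError("birth and death rates must be positive")
    channels = (
        ReactionChannel((1,), lambda x: lam * np.ones_like(np.asarray(x, dtype=float)), "birth"),
        ReactionChannel((-1,), lambda x: mu * np.asarray(x, dtype=float), "death"),
    )
    return ReactionNetwork(1, channels, name="birth_death", params={"lam": lam, "mu": mu})


# ---------------------------------------------------------------------------
# config files

_ALLOWED_FUNCS = {
    "exp": np.exp,
    "log": np.log,
    "sqrt": np.sqrt,
    "abs": np.abs,
    "min": np.minimum,
    "max": np.maximum,
}

_ALLOWED_BINOPS = {
    ast.Add: np.add,
    ast.Sub: np.subtract,
    ast.Mult: np.multiply,
    ast.Div: np.divide,
    ast.Pow: np.power,
    ast.Mod: np.mod,
}


def _compile_expression(expr: str, d: int, params: dict[str, float]) -> Callable[..., np.ndarray]:
    """Compile an arithmetic-only propensity expression over x1..xd.

    Only numbers, parameter names, coordinate names, the operators
    ``+ - * / ** %`` and the functions exp/log/sqrt/abs/min/max are
    admitted; arbitrary code cannot run.
    """
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ConfigError(f"cannot parse propensity expression {expr!r}: {exc}") from exc

    names = {f"x{k + 1}": k for k in range(d)}

    def ev(node, coords):
        if isinstance(node, ast.Expression):
            return ev(node.body, coords)
        if isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float)):
                raise ConfigError(f"non-numeric constant in {expr!r}")
            return float(node.value)
        if isinstance(node, ast.Name):
            if node.id in names:
                return coords[names[node.id]]
            if node.id in params:
                return float(params[node.id])
            raise ConfigError(f"unknown name {node.id!r} in expression {expr!r}")
        if isinstance(node, ast.BinOp):
            op = _ALLOWED_BINOPS.get(type(node.op))
            if op is None:
                raise ConfigError(f"operator not allowed in {expr!r}")
            return op(ev(node.left, coords), ev(node.right, coords))
        if isinstance(node, ast.UnaryOp):
            if isinstance(node.op, ast.USub):
                return -ev(node.operand, coords)
            if isinstance(node.op, ast.UAdd):
                return +ev(node.operand, coords)
            raise ConfigError(f"operator not allowed in {expr!r}")
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_FUNCS:
                raise ConfigError(f"function not allowed in {expr!r}")
            if node.keywords:
                raise ConfigError(f"keyword arguments not allowed in {expr!r}")
            return _ALLOWED_FUNCS[node.func.id](*(ev(a, coords) for a in node.args))
        raise ConfigError(f"syntax not allowed in propensity expression {expr!r}")

    def fn(*coords):
        coords = [np.asarray(c, dtype=float) for c in coords]
        out = ev(tree, coords)
        return np.broadcast_to(
            np.asarray(out, dtype=float), np.broadcast_shapes(*(c.shape for c in coords))
        )

    # fail fast on bad names/operators
    ev(tree, [np.zeros(1)] * d)
    return fn


_BUILTIN_BUILDERS = {
    "toggle2d": (build_toggle2d, ToggleParams),
    "tristable3d": (build_tristable3d, ToggleParams),
    "ocs": (build_ocs, OCSParams),
    "self_regulating_gene": (build_self_regulating_gene, GeneModelParams),
    "birth_death": (None, None),
}


def parse_network_config(path: str | Path) -> ReactionNetwork:
    """Read a reaction network from a YAML or JSON config file.

    Schema: ``model`` names a built-in (toggle2d | tristable3d | ocs |
    self_regulating_gene | birth_death) or ``custom``; ``params`` maps
    parameter names to numbers; for ``custom`` networks, ``d`` gives the
    species count and ``channels`` is a list of ``{shift: [int...],
    propensity: "expression"}`` entries with expressions over ``x1..xd``
    and the parameter names.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".json",):
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    model = data.get("model")
    if model is None:
        raise ConfigError(f"{path}: missing required key 'model'")
    params = data.get("params", {}) or {}
    if not isinstance(params, dict):
        raise ConfigError(f"{path}: 'params' must be a mapping")

    def _coerce(v):
        # YAML 1.1 reads "3.0e3" (no signed exponent) as a string
        if isinstance(v, str):
            try:
                return float(v)
            except ValueError:
                return v
        return v

    params = {k: _coerce(v) for k, v in params.items()}

    if model == "custom":
        d = data.get("d")
        if not isinstance(d, int) or d < 1:
            raise ConfigError(f"{path}: custom model needs an integer 'd' >= 1")
        raw_channels = data.get("channels")
        if not raw_channels:
            raise ConfigError(f"{path}: custom model needs a non-empty 'channels' list")
        channels = []
        for i, entry in enumerate(raw_channels):
            if not isinstance(entry, dict) or "shift" not in entry or "propensity" not in entry:
                raise ConfigError(f"{path}: channel {i} needs 'shift' and 'propensity'")
            shift = entry["shift"]
            if len(shift) != d or not all(isinstance(s, int) for s in shift):
                raise ConfigError(f"{path}: channel {i} shift must be {d} integers")
            fn = _compile_expression(str(entry["propensity"]), d, params)
            channels.append(ReactionChannel(tuple(shift), fn, entry.get("name", f"R{i + 1}")))
        return ReactionNetwork(d, tuple(channels), name="custom", params=dict(params))

    if model == "birth_death":
        try:
            return build_birth_death(float(params["lam"]), float(params["mu"]))
        except KeyError as exc:
            raise ConfigError(f"{path}: birth_death needs params lam and mu") from exc
        except ParameterError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    if model not in _BUILTIN_BUILDERS:
        raise ConfigError(f"{path}: unknown model {model!r}")
    builder, param_cls = _BUILTIN_BUILDERS[model]
    try:
        p = param_cls(**params)
        return builder(p)
    except (TypeError, ParameterError) as exc:
        raise ConfigError(f"{path}: invalid parameters for {model}: {exc}") from exc
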