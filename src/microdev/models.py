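"""Compartmental ODE models of microglial colonization of brain sub-regions.

Three nested model classes describe the density of microglia in each layer of
a brain region over postnatal time (``t`` is postnatal age in days):

* ``logistic`` — a modified logistic model whose equilibrium density is
  inversely proportional to the (growing) sub-region volume, with linear
  apoptosis and linear spreading between neighboring layers.
* ``linear`` — linear proliferation/apoptosis/spreading plus an exponentially
  decaying influx source per layer (migration from outside the region).
* ``two_pop`` — each layer's microglia split into a proliferative population A
  and a quiescent population B. Proliferation and differentiation each have an
  intrinsic (constant) rate and an extrinsic rate modulated by a dimensionless
  environmental factor ``E_i(t) = V_i(t) / v_inf_i`` coupled to the layer's
  volume.

Volumes follow a logistic growth law fitted jointly with the cell model.
Spreading is count-conserving: a flux at rate ``beta`` moves
``beta * M_i * V_i`` cells/day from layer i to layer j (converted back to a
density via ``V_j``). Influx through an ``EXTERNAL`` edge is a density source
``beta_ext * exp(-lam_ext * t)``.

Systems are integrated with SciPy's implicit backward differentiation formula.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .topology import EXTERNAL, RegionTopology

__all__ = [
    "InvalidParameterError",
    "IntegrationError",
    "UnsupportedModelError",
    "VolumeParams",
    "LogisticParams",
    "LinearSourceParams",
    "TwoPopParams",
    "SolverConfig",
    "Trajectory",
    "ObservableSeries",
    "volume_trajectory",
    "environmental_factor",
    "rhs_logistic",
    "rhs_linear_source",
    "rhs_two_population",
    "simulate_model",
    "predict_observables",
    "subpopulation_fractions",
    "switch_time",
    "doubling_time",
]

Edge = tuple[str, str]

EPS_GROWTH = 1e-12  # per-capita growth below this counts as "not growing"


class InvalidParameterError(ValueError):
    """A model parameter violates its domain (sign, ordering, range)."""


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced an inadmissible state."""


class UnsupportedModelError(TypeError):
    """An operation was applied to a trajectory of the wrong model class."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


def _require_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise InvalidParameterError(f"{name} must be non-negative, got {value}")


@dataclass(frozen=True)
class VolumeParams:
    """Logistic volume growth of one layer.

    ``V(t) = v_inf / (1 + (v_inf/v0 - 1) * exp(-g t))`` so that ``V(0) = v0``
    and ``V(t) -> v_inf``. Units: mm^3 for volumes, 1/day for ``g``.
    """

    v0: float
    v_inf: float
    g: float

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.v_inf <= 0:
            raise InvalidParameterError(
                f"volumes must be strictly positive (v0={self.v0}, v_inf={self.v_inf})"
            )
        if self.g < 0:
            raise InvalidParameterError(f"growth rate g must be >= 0, got {self.g}")
        if self.v0 > self.v_inf:
            raise InvalidParameterError(
                f"shrinkage is not modeled: require v0 <= v_inf (got {self.v0} > {self.v_inf})"
            )

    def volume(self, t):
        return volume_trajectory(self, t)


@dataclass(frozen=True)
class LogisticParams:
    """Modified logistic model: growth to a volume-diluted equilibrium density.

    ``dM_i/dt = r M_i (1 - M_i V_i(t)/kappa) - c M_i + spreading``.
    ``kappa`` is a carrying-capacity scale in cells, so the equilibrium
    density is ``kappa / V_i(t)`` (inversely proportional to volume).
    """

    r: float
    kappa: float
    c: float
    m0: Mapping[str, float]
    volume: Mapping[str, VolumeParams]
    beta: Mapping[Edge, float] = field(default_factory=dict)
    lam_ext: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r", "kappa", "c", "lam_ext"):
            _require_nonneg(name, getattr(self, name))
        for layer, v in self.m0.items():
            _require_nonneg(f"m0[{layer}]", v)
        for edge, b in self.beta.items():
            _require_nonneg(f"beta[{edge}]", b)


@dataclass(frozen=True)
class LinearSourceParams:
    """Linear model with an exponentially decaying influx source.

    ``dM_i/dt = (p - c) M_i + s0_i exp(-lam t) + spreading``.
    """

    p: float
    c: float
    s0: Mapping[str, float]
    lam: float
    m0: Mapping[str, float]
    volume: Mapping[str, VolumeParams]
    beta: Mapping[Edge, float] = field(default_factory=dict)
    lam_ext: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p", "c", "lam", "lam_ext"):
            _require_nonneg(name, getattr(self, name))
        for layer, v in {**self.s0, **self.m0}.items():
            _require_nonneg(f"s0/m0[{layer}]", v)
        for edge, b in self.beta.items():
            _require_nonneg(f"beta[{edge}]", b)


@dataclass(frozen=True)
class TwoPopParams:
    """Two-population model: proliferative (A) and quiescent (B) microglia.

    Proliferation (``a1``) and differentiation (``a2``) each decompose into an
    intrinsic rate and an extrinsic coefficient multiplying the environmental
    factor ``E_i(t) = V_i(t)/v_inf_i``:

    ``dA_i/dt = (a1_int_A + a1_ext_A E) A - (a2_int_AB + a2_ext_AB E) A
                + (a2_int_BA + a2_ext_BA E) B - c_A A + spreading_A``
    ``dB_i/dt = (a2_int_AB + a2_ext_AB E) A + (a1_int_B + a1_ext_B E) B
                - (a2_int_BA + a2_ext_BA E) B - c_B B + spreading_B``

    Both differentiation directions are representable; the dominance of A->B
    is an inference result, not a structural constraint. Kinetic rates are
    shared across layers; initial densities and volume parameters are
    per-layer.
    """

    a1_int_A: float = 0.0
    a1_int_B: float = 0.0
    a1_ext_A: float = 0.0
    a1_ext_B: float = 0.0
    a2_int_AB: float = 0.0
    a2_ext_AB: float = 0.0
    a2_int_BA: float = 0.0
    a2_ext_BA: float = 0.0
    c_A: float = 0.0
    c_B: float = 0.0
    A0: Mapping[str, float] = field(default_factory=dict)
    B0: Mapping[str, float] = field(default_factory=dict)
    volume: Mapping[str, VolumeParams] = field(default_factory=dict)
    beta_A: Mapping[Edge, float] = field(default_factory=dict)
    beta_B: Mapping[Edge, float] = field(default_factory=dict)
    lam_ext: float = 0.0

    _RATE_FIELDS = (
        "a1_int_A", "a1_int_B", "a1_ext_A", "a1_ext_B",
        "a2_int_AB", "a2_ext_AB", "a2_int_BA", "a2_ext_BA",
        "c_A", "c_B", "lam_ext",
    )

    def __post_init__(self) -> None:
        for name in self._RATE_FIELDS:
            _require_nonneg(name, getattr(self, name))
        for layer, v in {**self.A0, **self.B0}.items():
            _require_nonneg(f"initial density [{layer}]", v)
        for mapping in (self.beta_A, self.beta_B):
            for edge, b in mapping.items():
                _require_nonneg(f"beta[{edge}]", b)

    def swapped(self) -> "TwoPopParams":
        """Parameters with the A and B labels exchanged (relabeling symmetry)."""
        return TwoPopParams(
            a1_int_A=self.a1_int_B, a1_int_B=self.a1_int_A,
            a1_ext_A=self.a1_ext_B, a1_ext_B=self.a1_ext_A,
            a2_int_AB=self.a2_int_BA, a2_int_BA=self.a2_int_AB,
            a2_ext_AB=self.a2_ext_BA, a2_ext_BA=self.a2_ext_AB,
            c_A=self.c_B, c_B=self.c_A,
            A0=dict(self.B0), B0=dict(self.A0),
            volume=dict(self.volume),
            beta_A=dict(self.beta_B), beta_B=dict(self.beta_A),
            lam_ext=self.lam_ext,
        )


# ---------------------------------------------------------------------------
# Elementary maps
# ---------------------------------------------------------------------------


def volume_trajectory(vp: VolumeParams, t):
    """Logistic volume ``V(t)`` of a layer at postnatal age ``t`` (days)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("postnatal age t must be >= 0")
    out = vp.v_inf / (1.0 + (vp.v_inf / vp.v0 - 1.0) * np.exp(-vp.g * t))
    return out if out.ndim else float(out)


def environmental_factor(v, v_ref: float):
    """Dimensionless environmental signal ``E = V / v_ref`` in [0, ~1].

    ``v_ref`` is the asymptotic volume of the layer, so E rises from
    ``v0/v_inf`` toward 1 as the structure grows.
    """
    if v_ref <= 0:
        raise InvalidParameterError(f"v_ref must be > 0, got {v_ref}")
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise InvalidParameterError("volume must be >= 0")
    out = v / v_ref
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------


class _VolumeArrays:
    """Vectorized V(t) and E(t) across the ordered layers of a topology."""

    def __init__(self, volume: Mapping[str, VolumeParams], topo: RegionTopology):
        missing = [l for l in topo.layers if l not in volume]
        if missing:
            raise InvalidParameterError(f"missing volume parameters for layers {missing}")
        self.v0 = np.array([volume[l].v0 for l in topo.layers])
        self.v_inf = np.array([volume[l].v_inf for l in topo.layers])
        self.g = np.array([volume[l].g for l in topo.layers])
        self._ratio = self.v_inf / self.v0 - 1.0

    def volume(self, t: float) -> np.ndarray:
        return self.v_inf / (1.0 + self._ratio * np.exp(-self.g * t))

    def env(self, t: float) -> np.ndarray:
        return self.volume(t) / self.v_inf


def _edge_indices(
    beta: Mapping[Edge, float], topo: RegionTopology
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split spreading rates into internal (src,dst,rate) and external (dst,rate)."""
    declared = set(topo.edges)
    unknown = [e for e in beta if tuple(e) not in declared]
    if unknown:
        raise InvalidParameterError(f"spreading rates for undeclared edges {unknown}")
    src, dst, rate, ext_dst, ext_rate = [], [], [], [], []
    for (s, d), b in beta.items():
        if s == EXTERNAL:
            ext_dst.append(topo.layer_index(d))
            ext_rate.append(b)
        else:
            src.append(topo.layer_index(s))
            dst.append(topo.layer_index(d))
            rate.append(b)
    return (
        np.array(src, dtype=int), np.array(dst, dtype=int), np.array(rate),
        np.array(ext_dst, dtype=int), np.array(ext_rate),
    )


def _spread_terms(m, vol, src, dst, rate, ext_dst, ext_rate, t, lam_ext):
    """Count-conserving spreading plus decaying EXTERNAL influx, as densities."""
    out = np.zeros_like(m)
    if src.size:
        flux_cells = rate * m[src] * vol[src]  # cells/day leaving each source
        np.add.at(out, dst, flux_cells / vol[dst])
        np.add.at(out, src, -rate * m[src])
    if ext_dst.size:
        np.add.at(out, ext_dst, ext_rate * np.exp(-lam_ext * t))
    return out


def _compile_rhs(kind: str, params, topo: RegionTopology) -> Callable:
    """Build a fast ``f(t, y)`` closure for the requested model class."""
    va = _VolumeArrays(params.volume, topo)
    if kind == "logistic":
        se = _edge_indices(params.beta, topo)
        r, kappa, c, lam_ext = params.r, params.kappa, params.c, params.lam_ext

        def f(t, y):
            vol = va.volume(t)
            growth = r * y * (1.0 - y * vol / kappa)
            return growth - c * y + _spread_terms(y, vol, *se, t, lam_ext)

        return f
    if kind == "linear":
        se = _edge_indices(params.beta, topo)
        s0 = np.array([params.s0.get(l, 0.0) for l in topo.layers])
        p, c, lam, lam_ext = params.p, params.c, params.lam, params.lam_ext

        def f(t, y):
            vol = va.volume(t)
            return (p - c) * y + s0 * np.exp(-lam * t) + _spread_terms(
                y, vol, *se, t, lam_ext
            )

        return f
    if kind == "two_pop":
        seA = _edge_indices(params.beta_A, topo)
        seB = _edge_indices(params.beta_B, topo)
        n = topo.n_layers
        pr = params

        def f(t, y):
            a, b = y[:n], y[n:]
            vol = va.volume(t)
            e = vol / va.v_inf
            a1A = pr.a1_int_A + pr.a1_ext_A * e
            a1B = pr.a1_int_B + pr.a1_ext_B * e
            a2AB = pr.a2_int_AB + pr.a2_ext_AB * e
            a2BA = pr.a2_int_BA + pr.a2_ext_BA * e
            da = (a1A - a2AB - pr.c_A) * a + a2BA * b + _spread_terms(
                a, vol, *seA, t, pr.lam_ext
            )
            db = a2AB * a + (a1B - a2BA - pr.c_B) * b + _spread_terms(
                b, vol, *seB, t, pr.lam_ext
            )
            return np.concatenate([da, db])

        return f
    raise ValueError(f"unknown model kind {kind!r}; expected logistic|linear|two_pop")


def _check_state(state, topo: RegionTopology, n_per_layer: int) -> np.ndarray:
    y = np.asarray(state, dtype=float).ravel()
    expected = n_per_layer * topo.n_layers
    if y.size != expected:
        raise ValueError(
            f"state has {y.size} entries; topology {topo.region_name!r} with "
            f"{topo.n_layers} layers requires {expected}"
        )
    return y


def rhs_logistic(state, t: float, params: LogisticParams, topo: RegionTopology):
    """Time derivative of per-layer density under the modified logistic model."""
    return _compile_rhs("logistic", params, topo)(t, _check_state(state, topo, 1))


def rhs_linear_source(state, t: float, params: LinearSourceParams, topo: RegionTopology):
    """Time derivative under the linear model with a decaying influx source."""
    return _compile_rhs("linear", params, topo)(t, _check_state(state, topo, 1))


def rhs_two_population(state, t: float, params: TwoPopParams, topo: RegionTopology):
    """Time derivative of the stacked (A layers..., B layers...) state."""
    return _compile_rhs("two_pop", params, topo)(t, _check_state(state, topo, 2))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverConfig:
    """Solver settings: implicit BDF by default.

    ``method="RK4"`` selects a compiled fixed-grid Runge–Kutta fast path
    (substeps no longer than ``rk4_step`` days) for calibration workloads
    that need thousands of solves; its agreement with BDF is test-covered.
    """

    method: str = "BDF"
    rtol: float = 1e-8
    atol: float = 1e-10
    neg_tol: float = 1e-6  # tolerated undershoot below zero before clamping
    rk4_step: float = 0.1  # days, fixed-grid fast path only


@dataclass
class Trajectory:
    """ODE solution on a time grid, per layer, plus bookkeeping.

    ``A``/``B`` are None for one-population models; ``M = A + B`` (or the
    single population) is always present. Arrays are (n_layers, n_times).
    """

    times: np.ndarray
    topo: RegionTopology
    model_kind: str
    M: np.ndarray
    V: np.ndarray
    params: object
    A: np.ndarray | None = None
    B: np.ndarray | None = None
    provenance: str = ""

    @property
    def is_two_pop(self) -> bool:
        return self.A is not None

    def layer_index(self, layer: str) -> int:
        return self.topo.layer_index(layer)


_EMPTY_EDGES = (
    np.empty(0, dtype=np.int64),
    np.empty(0, dtype=np.int64),
    np.empty(0, dtype=np.float64),
    np.empty(0, dtype=np.int64),
    np.empty(0, dtype=np.float64),
)


def _fast_path(kind: str, params, topo: RegionTopology, t_grid, y0, cfg) -> np.ndarray:
    """Dispatch to the compiled fixed-grid RK4 integrator."""
    from .fastsolve import KIND_CODES, rk4_solve

    va = _VolumeArrays(params.volume, topo)
    n = topo.n_layers
    s0 = np.zeros(n)
    if kind == "logistic":
        se_a, se_b = _edge_indices(params.beta, topo), _EMPTY_EDGES
        rates = np.array([params.r, params.kappa, params.c, params.lam_ext])
    elif kind == "linear":
        se_a, se_b = _edge_indices(params.beta, topo), _EMPTY_EDGES
        rates = np.array([params.p, params.c, params.lam, params.lam_ext])
        s0 = np.array([params.s0.get(l, 0.0) for l in topo.layers])
    else:
        se_a = _edge_indices(params.beta_A, topo)
        se_b = _edge_indices(params.beta_B, topo)
        p = params
        rates = np.array(
            [p.a1_int_A, p.a1_int_B, p.a1_ext_A, p.a1_ext_B,
             p.a2_int_AB, p.a2_ext_AB, p.a2_int_BA, p.a2_ext_BA,
             p.c_A, p.c_B, p.lam_ext]
        )
    out = rk4_solve(
        KIND_CODES[kind], t_grid, cfg.rk4_step, y0.astype(float), n, rates,
        va.v0, va.v_inf, va.g,
        se_a[0].astype(np.int64), se_a[1].astype(np.int64), se_a[2].astype(np.float64),
        se_a[3].astype(np.int64), se_a[4].astype(np.float64),
        se_b[0].astype(np.int64), se_b[1].astype(np.int64), se_b[2].astype(np.float64),
        se_b[3].astype(np.int64), se_b[4].astype(np.float64),
        s0,
    )
    return out.T  # (state, time)


def _provenance(kind: str, params) -> str:
    digest = hashlib.sha1(repr(params).encode()).hexdigest()[:12]
    return f"{kind}:{digest}"


def simulate_model(
    kind: str,
    params,
    topo: RegionTopology,
    t_grid,
    solver_cfg: SolverConfig | None = None,
) -> Trajectory:
    """Integrate a colonization model and return its trajectory on ``t_grid``.

    ``t_grid`` must be strictly increasing and starts at the first observed
    age (t=0 is birth; ages are postnatal days). Small negative solver
    excursions (within ``neg_tol``) are clamped to zero; larger ones raise
    :class:`IntegrationError`.
    """
    cfg = solver_cfg or SolverConfig()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array of >= 2 ages")

    f = _compile_rhs(kind, params, topo)
    n = topo.n_layers
    if kind == "two_pop":
        y0 = np.array(
            [params.A0.get(l, 0.0) for l in topo.layers]
            + [params.B0.get(l, 0.0) for l in topo.layers]
        )
    else:
        y0 = np.array([params.m0.get(l, 0.0) for l in topo.layers])

    if cfg.method.upper() == "RK4":
        y = _fast_path(kind, params, topo, t_grid, y0, cfg)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"fixed-grid solution not finite for {_provenance(kind, params)}"
            )
    else:
        sol = solve_ivp(
            f,
            (t_grid[0], t_grid[-1]),
            y0,
            method=cfg.method,
            t_eval=t_grid,
            rtol=cfg.rtol,
            atol=cfg.atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed for {_provenance(kind, params)}: {sol.message}"
            )
        y = sol.y
    if y.min(initial=0.0) < -cfg.neg_tol:
        raise IntegrationError(
            f"state fell below -neg_tol ({y.min():.3e}) for {_provenance(kind, params)}"
        )
    y = np.clip(y, 0.0, None)

    va = _VolumeArrays(params.volume, topo)
    V = np.stack([va.volume(t) for t in t_grid], axis=1)
    if kind == "two_pop":
        A, B = y[:n], y[n:]
        return Trajectory(
            times=t_grid, topo=topo, model_kind=kind, M=A + B, V=V,
            params=params, A=A, B=B, provenance=_provenance(kind, params),
        )
    return Trajectory(
        times=t_grid, topo=topo, model_kind=kind, M=y, V=V,
        params=params, provenance=_provenance(kind, params),
    )


# ---------------------------------------------------------------------------
# Observables and derived milestones
# ---------------------------------------------------------------------------


@dataclass
class ObservableSeries:
    """Model-predicted observables on the trajectory grid.

    ``pct_ki67`` maps the model's per-capita birth rate to the fraction of
    microglia scored Ki67+: a cell is Ki67+ if it entered the cycle within
    the visibility window ``tau_k`` (days), so
    ``%Ki67 = 100 * tau_k * (population-weighted proliferation rate)``,
    capped at 100.
    """

    times: np.ndarray
    layers: tuple[str, ...]
    density: np.ndarray
    volume: np.ndarray
    pct_ki67: np.ndarray
    tau_k: float


def _percapita_birth_rate(traj: Trajectory) -> np.ndarray:
    """Per-capita rate of new-cell production, per layer and time."""
    p = traj.params
    if traj.model_kind == "two_pop":
        va = _VolumeArrays(p.volume, traj.topo)
        E = np.stack([va.env(t) for t in traj.times], axis=1)
        a1A = p.a1_int_A + p.a1_ext_A * E
        a1B = p.a1_int_B + p.a1_ext_B * E
        total = traj.M
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(total > 0, (a1A * traj.A + a1B * traj.B) / np.where(total > 0, total, 1.0), 0.0)
        if np.any(total == 0):
            warnings.warn("zero total density at some evaluation points; %Ki67 set to 0")
        return rate
    if traj.model_kind == "logistic":
        K = p.kappa / traj.V  # equilibrium density
        return p.r * np.clip(1.0 - traj.M / K, 0.0, None)
    if traj.model_kind == "linear":
        source = np.array([p.s0.get(l, 0.0) for l in traj.topo.layers])[:, None] * np.exp(
            -p.lam * traj.times
        )[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            per_capita_src = np.where(traj.M > 0, source / np.where(traj.M > 0, traj.M, 1.0), 0.0)
        return p.p + per_capita_src
    raise ValueError(f"unknown model kind {traj.model_kind!r}")


def predict_observables(traj: Trajectory, params=None, tau_k: float = 0.25) -> ObservableSeries:
    """Map a trajectory to (density, volume, %Ki67) predictions.

    ``tau_k`` is the Ki67 visibility window in days, bounded in (0, 1.5].
    """
    if not (0 < tau_k <= 1.5):
        raise InvalidParameterError(f"tau_k must be in (0, 1.5], got {tau_k}")
    rate = _percapita_birth_rate(traj)
    pct = np.clip(100.0 * tau_k * rate, 0.0, 100.0)
    return ObservableSeries(
        times=traj.times,
        layers=traj.topo.layers,
        density=traj.M,
        volume=traj.V,
        pct_ki67=pct,
        tau_k=tau_k,
    )


def subpopulation_fractions(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Fractions A/(A+B) and B/(A+B) per layer over time (NaN where A+B=0)."""
    if not traj.is_two_pop:
        raise UnsupportedModelError(
            "subpopulation fractions require a two-population trajectory"
        )
    total = traj.M
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(total > 0, traj.A / np.where(total > 0, total, 1.0), np.nan)
    return fa, 1.0 - fa


def switch_time(traj: Trajectory, layer: str) -> float | None:
    """Earliest time the quiescent fraction crosses 1/2 from below.

    The proliferative-to-quiescent (P/Q) switch time: located by linear
    interpolation between grid points of fraction_B; None if the fraction
    never reaches 1/2 in the simulated window.
    """
    _, fb = subpopulation_fractions(traj)
    fb = fb[traj.layer_index(layer)]
    t = traj.times
    valid = ~np.isnan(fb)
    if not valid.any():
        return None
    if fb[valid][0] >= 0.5:
        return float(t[valid][0])
    for k in range(1, t.size):
        if np.isnan(fb[k]) or np.isnan(fb[k - 1]):
            continue
        if fb[k - 1] < 0.5 <= fb[k]:
            frac = (0.5 - fb[k - 1]) / (fb[k] - fb[k - 1])
            return float(t[k - 1] + frac * (t[k] - t[k - 1]))
    return None


def doubling_time(traj: Trajectory, layer: str, t: float) -> float:
    """Population doubling time ``ln 2 / (per-capita growth)`` at age ``t``.

    The growth rate is evaluated from the model right-hand side (not finite
    differences) on the state linearly interpolated to ``t``. Returns ``inf``
    when per-capita growth is <= 1e-12 (shrinking or static population).
    """
    times = traj.times
    if not (times[0] <= t <= times[-1]):
        raise ValueError(f"t={t} outside simulated window [{times[0]}, {times[-1]}]")
    i = traj.layer_index(layer)
    n = traj.topo.n_layers
    if traj.is_two_pop:
        state = np.concatenate(
            [
                [np.interp(t, times, traj.A[j]) for j in range(n)],
                [np.interp(t, times, traj.B[j]) for j in range(n)],
            ]
        )
        deriv = rhs_two_population(state, t, traj.params, traj.topo)
        m = state[i] + state[n + i]
        dm = deriv[i] + deriv[n + i]
    else:
        state = np.array([np.interp(t, times, traj.M[j]) for j in range(n)])
        rhs = rhs_logistic if traj.model_kind == "logistic" else rhs_linear_source
        deriv = rhs(state, t, traj.params, traj.topo)
        m, dm = state[i], deriv[i]
    if m <= 0:
        raise ValueError(f"total density is zero at t={t}; doubling time undefined")
    growth = dm / m
    if growth <= EPS_GROWTH:
        return float("inf")
    return float(np.log(2.0) / growth)
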