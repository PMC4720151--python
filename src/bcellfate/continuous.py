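"""Continuous (fuzzy-logic sigmoid ODE) dynamics.

Each node carries a normalized activation x_i in [0,1]. Ruled nodes obey

    dx_i/dt = f_h(omega_i) - gamma_i * x_i

where omega_i is the node's logic rule fuzzified with AND -> min, OR -> max,
NOT -> 1-x, and f_h is a sigmoid normalized to pass through (0,0),
(0.5,0.5) and (1,1) for every gain h > 0:

    f_h(w) = (-e^{h/2} + e^{-h(w-1/2)}) / ((1 - e^{h/2})(1 + e^{-h(w-1/2)}))

Regulator-free (input) nodes have no activation term and simply decay,
dx/dt = -gamma x. At h = 50 (the default) the sigmoid is nearly a step
function, so every Boolean fixed point of the synchronous model is an exact
equilibrium here; additional equilibria with half-activated nodes exist
because f_h(0.5) = 0.5 exactly.

Two integrators are provided: an adaptive stiff-capable LSODA path (used
for perturbation and pulse protocols, where trajectories can pass close to
separatrices) and a vectorized fixed-step RK4 path for bulk random-start
sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .expr import FuzzyExpr
from .network import LogicRule, RegulatoryNetwork

__all__ = [
    "ContinuousParams",
    "ContinuousState",
    "ContinuousAttractor",
    "fuzzify",
    "sigmoid",
    "derivative",
    "ContinuousSystem",
    "relax",
    "sample_attractors",
    "perturbation_search",
    "parameter_sweep",
    "PerturbationRecord",
]


def fuzzify(rule: LogicRule) -> FuzzyExpr:
    """Structure-preserving fuzzification of a logic rule."""
    return rule.expression.to_fuzzy()


def sigmoid(omega, h):
    """Normalized sigmoid activation; exact at omega in {0, 0.5, 1}.

    Evaluated in a form that never exponentiates a positive multiple of h,
    so large gains (h = 50, 100) do not overflow:

        f(w) = (e^{-h w} - 1) * expit(h(w - 1/2)) / (e^{-h/2} - 1)
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(np.asarray(h) <= 0):
        raise ValueError("sigmoid gain h must be positive")
    u = h * (omega - 0.5)
    num = np.expm1(-u - 0.5 * h) * expit(u)
    den = np.expm1(-0.5 * np.asarray(h, dtype=float))
    return num / den


@dataclass(frozen=True)
class ContinuousParams:
    """Parameters of the continuous system.

    h : sigmoid gain (dimensionless), scalar or per-node map. Default 50
        (near-step response).
    gamma : first-order decay rate (per unit time), scalar or per-node map.
        Default 1, the value for which activations stay in [0,1].
    convergence_tol : steady-state residual max|dx/dt| required of a
        converged state.
    max_time : give up flagging non-convergence after this much model time.
    rtol, atol : LSODA tolerances for trajectory integration.
    dt : fixed step of the vectorized RK4 bulk integrator.
    merge_decimals : attractors are merged after rounding levels to this
        many decimals.
    snap_levels, snap_tol : converged states are polished onto the exact
        equilibrium grid (the analytic fixed points of the model sit at
        activation 0, 0.5 or 1): any level within snap_tol of a grid value
        is snapped, and the snap is kept only if the snapped state's
        residual still certifies an equilibrium.
    """

    h: float | Mapping[str, float] = 50.0
    gamma: float | Mapping[str, float] = 1.0
    convergence_tol: float = 1e-10
    max_time: float = 500.0
    rtol: float = 1e-6
    atol: float = 1e-6
    dt: float = 0.02
    merge_decimals: int = 6
    snap_levels: tuple[float, ...] = (0.0, 0.5, 1.0)
    snap_tol: float = 1e-5

    def h_vector(self, names: Sequence[str]) -> np.ndarray:
        return _per_node(self.h, names, "h")

    def gamma_vector(self, names: Sequence[str]) -> np.ndarray:
        return _per_node(self.gamma, names, "gamma")


def _per_node(value, names, what) -> np.ndarray:
    if isinstance(value, Mapping):
        vec = np.array([float(value.get(n, 50.0 if what == "h" else 1.0)) for n in names])
    else:
        vec = np.full(len(names), float(value))
    if np.any(vec <= 0):
        raise ValueError(f"{what} must be positive")
    return vec


@dataclass(frozen=True)
class ContinuousState:
    """Activation levels for all nodes at a time point."""

    levels: Mapping[str, float]
    time: float = 0.0


@dataclass(frozen=True)
class ContinuousAttractor:
    """A converged steady state of the continuous system."""

    levels: dict[str, float]
    residual: float
    support_count: int = 0
    discovered_by: str = "random_start"
    label: str | None = None
    converged: bool = True

    def key(self, decimals: int = 6) -> tuple[float, ...]:
        return tuple(abs(round(v, decimals)) + 0.0 for v in self.levels.values())

    def vector(self, net: RegulatoryNetwork) -> np.ndarray:
        return np.array([self.levels[n] for n in net.node_names])

    def pattern(self, nodes: Iterable[str], decimals: int = 3) -> tuple[float, ...]:
        return tuple(abs(round(self.levels[n], decimals)) + 0.0 for n in nodes)

    def with_label(self, label: str) -> "ContinuousAttractor":
        return replace(self, label=label)


class ContinuousSystem:
    """Compiled vector field of a network under fixed parameters/clamps."""

    def __init__(
        self,
        net: RegulatoryNetwork,
        params: ContinuousParams | None = None,
        clamps: Mapping[str, float] | None = None,
    ):
        self.net = net
        self.params = params or ContinuousParams()
        self.clamps = dict(clamps or {})
        self.names = net.node_names
        self.n = len(self.names)
        self._index = {n: i for i, n in enumerate(self.names)}
        self.h = self.params.h_vector(self.names)
        self.gamma = self.params.gamma_vector(self.names)
        self._fuzzy = [
            fuzzify(net.rules[n]) if n in net.rules else None for n in self.names
        ]
        self._clamp_idx = np.array(
            [self._index[n] for n in self.clamps], dtype=int
        )
        self._clamp_val = np.array([float(v) for v in self.clamps.values()])

    # X has shape (batch, n); scalars are promoted.
    def omega(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        env = {name: X[:, i] for i, name in enumerate(self.names)}
        out = np.zeros_like(X)
        for i, fz in enumerate(self._fuzzy):
            if fz is not None:
                out[:, i] = fz.eval(env)
        return out

    def derivative(self, X: np.ndarray, pinned: np.ndarray | None = None) -> np.ndarray:
        """dx/dt for a batch of states; pinned entries get rate 0."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        env = {name: X[:, i] for i, name in enumerate(self.names)}
        D = np.empty_like(X)
        for i, fz in enumerate(self._fuzzy):
            if fz is None:
                D[:, i] = -self.gamma[i] * X[:, i]
            else:
                D[:, i] = sigmoid(fz.eval(env), self.h[i]) - self.gamma[i] * X[:, i]
        if self._clamp_idx.size:
            D[:, self._clamp_idx] = 0.0
        if pinned is not None:
            D[pinned] = 0.0
        return D

    def apply_clamps(self, X: np.ndarray) -> np.ndarray:
        X = np.array(np.atleast_2d(X), dtype=float)
        if self._clamp_idx.size:
            X[:, self._clamp_idx] = self._clamp_val
        return X

    def residual(self, x: np.ndarray) -> float:
        return float(np.abs(self.derivative(x)).max())

    def snap(self, x: np.ndarray) -> np.ndarray:
        """Polish a converged state onto the exact equilibrium grid.

        Levels within ``snap_tol`` of a grid value are replaced by it; the
        snapped state is kept only if its residual certifies it as an (at
        least as good) equilibrium.
        """
        grid = np.asarray(self.params.snap_levels)
        snapped = x.copy()
        dist = np.abs(x[:, None] - grid[None, :])
        nearest = np.argmin(dist, axis=1)
        close = dist[np.arange(len(x)), nearest] <= self.params.snap_tol
        snapped[close] = grid[nearest[close]]
        if self._clamp_idx.size:
            snapped[self._clamp_idx] = self._clamp_val
        if self.residual(snapped) <= max(self.residual(x), self.params.convergence_tol):
            return snapped
        return x

    # -- single-trajectory adaptive integration ------------------------------

    def integrate(
        self,
        x0: np.ndarray,
        duration: float,
        pinned_nodes: Sequence[str] = (),
        t_eval: np.ndarray | None = None,
    ):
        """Integrate for a fixed duration with LSODA; returns (times, states)."""
        pin_idx = np.array([self._index[n] for n in pinned_nodes], dtype=int)

        def rhs(t, x):
            d = self.derivative(x)[0]
            if pin_idx.size:
                d[pin_idx] = 0.0
            return d

        sol = solve_ivp(
            rhs,
            (0.0, duration),
            np.asarray(x0, dtype=float),
            method="LSODA",
            rtol=self.params.rtol,
            atol=self.params.atol,
            t_eval=t_eval,
        )
        if not sol.success:  # pragma: no cover - LSODA failure is exceptional
            raise RuntimeError(f"integration failed: {sol.message}")
        return sol.t, sol.y.T

    def relax(self, x0: np.ndarray, chunk: float = 25.0) -> ContinuousAttractor:
        """Integrate until max|dx/dt| < convergence_tol or max_time."""
        x = self.apply_clamps(x0)[0]
        t = 0.0
        while True:
            res = self.residual(x)
            if res < self.params.convergence_tol or t >= self.params.max_time:
                break
            _, states = self.integrate(x, min(chunk, self.params.max_time - t))
            x = states[-1]
            t += chunk
        x = self.snap(x)
        res = self.residual(x)
        return ContinuousAttractor(
            levels=dict(zip(self.names, (float(v) for v in x))),
            residual=res,
            converged=bool(res < self.params.convergence_tol),
        )

    # -- vectorized fixed-step integration -----------------------------------

    def relax_batch(
        self, X0: np.ndarray, pinned: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Classic RK4 relaxation of a batch; returns (states, converged).

        Runs in blocks of 50 steps, freezing the whole batch once every
        run's residual is below the convergence tolerance.
        """
        X = self.apply_clamps(X0)
        dt = self.params.dt
        t = 0.0
        while t < self.params.max_time:
            for _ in range(50):
                k1 = self.derivative(X, pinned)
                k2 = self.derivative(X + 0.5 * dt * k1, pinned)
                k3 = self.derivative(X + 0.5 * dt * k2, pinned)
                k4 = self.derivative(X + dt * k3, pinned)
                X = X + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                t += dt
            resid = np.abs(self.derivative(X, pinned)).max(axis=1)
            if resid.max() < self.params.convergence_tol:
                break
        X = np.array([self.snap(row) for row in X])
        resid = np.abs(self.derivative(X, pinned)).max(axis=1)
        return X, resid < self.params.convergence_tol

    def integrate_batch(
        self, X0: np.ndarray, duration: float, pinned: np.ndarray | None = None
    ) -> np.ndarray:
        """Fixed-duration batch RK4 integration (no convergence stop)."""
        X = np.array(np.atleast_2d(X0), dtype=float)
        dt = self.params.dt
        nsteps = max(1, int(round(duration / dt)))
        for _ in range(nsteps):
            k1 = self.derivative(X, pinned)
            k2 = self.derivative(X + 0.5 * dt * k1, pinned)
            k3 = self.derivative(X + 0.5 * dt * k2, pinned)
            k4 = self.derivative(X + dt * k3, pinned)
            X = X + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        return X


def derivative(
    net: RegulatoryNetwork,
    params: ContinuousParams,
    state: Mapping[str, float] | np.ndarray,
    clamps: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-node rates dx/dt at a single state."""
    sys = ContinuousSystem(net, params, clamps)
    if isinstance(state, Mapping):
        x = np.array([float(state[n]) for n in net.node_names])
    else:
        x = np.asarray(state, dtype=float)
    d = sys.derivative(x)[0]
    return dict(zip(net.node_names, (float(v) for v in d)))


def relax(
    net: RegulatoryNetwork,
    params: ContinuousParams,
    x0: Mapping[str, float] | np.ndarray,
    clamps: Mapping[str, float] | None = None,
) -> ContinuousAttractor:
    """Relax one initial state to a steady state (adaptive integration).

    Non-convergence within ``params.max_time`` is flagged on the result
    (``converged=False``), never silent.
    """
    sys = ContinuousSystem(net, params, clamps)
    if isinstance(x0, Mapping):
        x0 = np.array([float(x0.get(n, 0.0)) for n in net.node_names])
    return sys.relax(np.asarray(x0, dtype=float))


def _merge(
    attractors: Iterable[ContinuousAttractor], decimals: int
) -> list[ContinuousAttractor]:
    merged: dict[tuple, ContinuousAttractor] = {}
    for att in attractors:
        key = att.key(decimals)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(
                prev,
                support_count=prev.support_count + att.support_count,
                residual=min(prev.residual, att.residual),
            )
        else:
            merged[key] = att
    return sorted(merged.values(), key=lambda a: (-a.support_count, a.key(decimals)))


def sample_attractors(
    net: RegulatoryNetwork,
    params: ContinuousParams | None = None,
    n_runs: int = 5000,
    seed: int = 0,
    clamps: Mapping[str, float] | None = None,
) -> list[ContinuousAttractor]:
    """Steady states reached from uniform random initial states.

    Draws ``n_runs`` initial states uniformly in [0,1]^n with the given
    seed, relaxes each with the vectorized integrator, and clusters the
    converged states within the merge tolerance.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    params = params or ContinuousParams()
    sys = ContinuousSystem(net, params, clamps)
    rng = np.random.default_rng(seed)
    X0 = rng.uniform(0.0, 1.0, size=(n_runs, sys.n))
    X, converged = sys.relax_batch(X0)
    atts = []
    for x, ok in zip(X, converged):
        atts.append(
            ContinuousAttractor(
                levels=dict(zip(sys.names, (float(v) for v in x))),
                residual=sys.residual(x),
                support_count=1,
                discovered_by="random_start",
                converged=bool(ok),
            )
        )
    return _merge(atts, params.merge_decimals)


@dataclass(frozen=True)
class PerturbationRecord:
    """A single perturbation trial: source attractor, change, destination."""

    source: tuple[float, ...]
    node: str
    level: float
    destination: tuple[float, ...]


def _perturb_relax(
    sys: ContinuousSystem, x0: np.ndarray, node: str, level: float, duration: float
) -> ContinuousAttractor:
    x = np.array(x0, dtype=float)
    x[sys._index[node]] = level
    if duration > 0:
        _, states = sys.integrate(x, duration, pinned_nodes=(node,))
        x = states[-1]
    return sys.relax(x)


def perturbation_search(
    net: RegulatoryNetwork,
    params: ContinuousParams | None = None,
    base_attractors: Sequence[ContinuousAttractor] | None = None,
    levels: Sequence[float] = (0.0, 0.5, 1.0),
    duration: float = 0.0,
    clamps: Mapping[str, float] | None = None,
    closure: bool = False,
) -> tuple[list[ContinuousAttractor], list[PerturbationRecord]]:
    """Discover additional fixed points by single-node perturbations.

    Every (attractor, node, level) combination is tried: the node's level
    is set to the target value — instantaneously by default, or held
    clamped for ``duration`` time units — after which the free system is
    relaxed. Newly found steady states are flagged
    ``discovered_by='perturbation'``. By default only the supplied base
    attractors are perturbed (one round); with ``closure=True`` newly
    found states are themselves perturbed until no further states appear,
    which can walk onto additional saddle equilibria reachable only
    through exact half-activation manifolds.

    Returns the union of distinct attractors and the full list of
    (source, perturbation, destination) records.
    """
    params = params or ContinuousParams()
    sys = ContinuousSystem(net, params, clamps)
    if base_attractors is None:
        base_attractors = sample_attractors(net, params, n_runs=1000, seed=0, clamps=clamps)
    dec = params.merge_decimals
    known: dict[tuple, ContinuousAttractor] = {a.key(dec): a for a in base_attractors}
    records: list[PerturbationRecord] = []
    queue = list(known.keys())
    while queue:
        src_key = queue.pop(0)
        src = known[src_key]
        x0 = src.vector(net)
        for node in net.node_names:
            for level in levels:
                if abs(x0[sys._index[node]] - level) < 10 ** (-dec):
                    continue  # no-op perturbation
                res = _perturb_relax(sys, x0, node, float(level), duration)
                res = replace(res, discovered_by="perturbation")
                key = res.key(dec)
                records.append(
                    PerturbationRecord(src_key, node, float(level), key)
                )
                if key not in known:
                    known[key] = res
                    if closure:
                        queue.append(key)
    atts = sorted(
        known.values(),
        key=lambda a: (a.discovered_by != "random_start", -a.support_count, a.key(dec)),
    )
    return atts, records


def parameter_sweep(
    net: RegulatoryNetwork,
    sweep: str,
    grid: Sequence[float],
    params: ContinuousParams | None = None,
    start_states: Mapping[str, Mapping[str, float]] | None = None,
):
    """Attractor locations as a function of h or gamma.

    For each grid value the wild-type binary attractor patterns (or the
    supplied ``start_states``) are relaxed under the modified parameters;
    the converged level of every node is reported.

    Returns a pandas DataFrame with columns (parameter, value, start,
    node, level, residual, converged).
    """
    import pandas as pd

    if sweep not in ("h", "gamma"):
        raise ValueError("sweep must be 'h' or 'gamma'")
    if any(v <= 0 for v in grid):
        raise ValueError("grid values must be positive")
    params = params or ContinuousParams()
    if start_states is None:
        from .fate import DEFAULT_SIGNATURES

        start_states = {
            sig.label: {n: float(v) for n, v in zip(sig.nodes, sig.pattern)}
            for sig in DEFAULT_SIGNATURES
        }
    rows = []
    for value in grid:
        p = replace(params, **{sweep: float(value)})
        for start, levels in start_states.items():
            x0 = {n: float(levels.get(n, 0.0)) for n in net.node_names}
            att = relax(net, p, x0)
            for node, level in att.levels.items():
                rows.append(
                    {
                        "parameter": sweep,
                        "value": float(value),
                        "start": start,
                        "node": node,
                        "level": level,
                        "residual": att.residual,
                        "converged": att.converged,
                    }
                )
    return pd.DataFrame(rows)
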