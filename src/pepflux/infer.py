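"""Stationary expected amounts and constrained least-squares fitting.

At equilibrium the particle flow through every peptide node balances:
creation (sources only) plus production by cleavage of longer peptides
equals consumption by cleavage plus complete degradation (leaves only).
Because every event's products are shorter than its substrate, the
balance system is triangular in topological order and the expected
amounts Phi(z) follow by a three-case recursion:

* source v:    phi_v = phi*_v / sum_out(v)
* interior v:  phi_v = inflow(v) / sum_out(v)
* leaf v:      phi_v = inflow(v) / phi-bot_v

with sum_out(v) = sum of rho*lambda over events cleaving v and inflow(v)
the rho*lambda-weighted amounts of v's parents (counted once per event in
which v appears as prefix or suffix).

The parameter vector z stacks creation rates (one per source), complete
degradation rates (one per leaf) and peptidase activities lambda (one per
peptidase).  Fitting minimises the residuals phi_v(z) - y_v over the
observed nodes O by Levenberg-Marquardt, with positivity enforced by
optimising log z, restarted from several random initial points.  Phi is
invariant under joint scaling of all parameters, so activities are
identified only up to a global scale (resolved downstream by simplex
normalisation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .graph import CleavageGraph, _node_sort_key, topological_order

__all__ = [
    "ModelParameters",
    "FitResult",
    "expected_amounts",
    "balance_residuals",
    "objective",
    "fit",
    "relative_squared_error",
    "activity_constraint_matrix",
]


@dataclass
class ModelParameters:
    """The parameter vector z = (creation, degradation, activities).

    ``creation`` maps each source node to its creation rate phi*,
    ``degradation`` each leaf node to its complete-degradation rate
    phi-bot, and ``activities`` each peptidase to its activity lambda.
    All entries are strictly positive.
    """

    creation: dict[str, float]
    degradation: dict[str, float]
    activities: dict[str, float]

    def __post_init__(self) -> None:
        for group in (self.creation, self.degradation, self.activities):
            for key, value in group.items():
                if value <= 0:
                    raise ValueError(f"parameter for {key!r} must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.creation) + len(self.degradation) + len(self.activities)

    def scaled(self, c: float) -> "ModelParameters":
        """Joint rescaling of every rate by ``c`` (leaves Phi unchanged)."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return ModelParameters(
            {k: c * v for k, v in self.creation.items()},
            {k: c * v for k, v in self.degradation.items()},
            {k: c * v for k, v in self.activities.items()},
        )

    def to_dict(self) -> dict:
        return {
            "creation": dict(self.creation),
            "degradation": dict(self.degradation),
            "activities": dict(self.activities),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ModelParameters":
        return cls(dict(payload["creation"]), dict(payload["degradation"]),
                   dict(payload["activities"]))


@dataclass
class FitResult:
    """Outcome of the multi-start Levenberg-Marquardt fit."""

    z_hat: ModelParameters
    y_hat: dict[str, float]
    rse: float
    n_starts: int
    iterations_per_start: list[int]
    best_start_index: int
    converged: bool
    seed: int
    rse_per_start: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "z_hat": self.z_hat.to_dict(),
            "y_hat": self.y_hat,
            "rse": self.rse,
            "n_starts": self.n_starts,
            "iterations_per_start": self.iterations_per_start,
            "best_start_index": self.best_start_index,
            "converged": self.converged,
            "seed": self.seed,
            "rse_per_start": self.rse_per_start,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        p = json.loads(Path(path).read_text())
        return cls(ModelParameters.from_dict(p["z_hat"]), p["y_hat"], p["rse"],
                   p["n_starts"], p["iterations_per_start"], p["best_start_index"],
                   p["converged"], p["seed"], p.get("rse_per_start", []))


class _CompiledGraph:
    """Index-based view of a pruned graph for fast repeated Phi evaluation.

    Parameter vector layout: sources (topological order), then leaves
    (topological order), then peptidases (lexicographic).
    """

    def __init__(self, graph: CleavageGraph):
        order = topological_order(graph)
        sources, leaves = graph.sources(), graph.leaves()
        both = sources & leaves
        if both:
            raise ValueError(
                "graph is not pruned: node(s) with neither parent nor child "
                f"remain, e.g. {sorted(both)[0]!r} (S and L must be disjoint)"
            )
        self.order = order
        self.index = {seq: i for i, seq in enumerate(order)}
        self.source_order = [s for s in order if s in sources]
        self.leaf_order = [s for s in order if s in leaves]
        self.pep_order = sorted(graph.peptidases())
        pep_index = {p: i for i, p in enumerate(self.pep_order)}
        n = len(order)
        self.n_nodes = n
        self.n_sources = len(self.source_order)
        self.n_leaves = len(self.leaf_order)
        self.n_params = self.n_sources + self.n_leaves + len(self.pep_order)
        # kind: 0 source, 1 interior, 2 leaf
        self.kind = [0 if s in sources else 2 if s in leaves else 1 for s in order]
        self.param_index = [-1] * n
        for j, s in enumerate(self.source_order):
            self.param_index[self.index[s]] = j
        for j, s in enumerate(self.leaf_order):
            self.param_index[self.index[s]] = self.n_sources + j
        self.out_ev: list[list[tuple[float, int]]] = [[] for _ in range(n)]
        self.in_ev: list[list[tuple[int, float, int]]] = [[] for _ in range(n)]
        for e in graph.events:
            sub = self.index[e.substrate]
            p = pep_index[e.peptidase_id]
            self.out_ev[sub].append((e.rho, p))
            self.in_ev[self.index[e.prefix]].append((sub, e.rho, p))
            self.in_ev[self.index[e.suffix]].append((sub, e.rho, p))

    def pack(self, z: ModelParameters) -> np.ndarray:
        if (set(z.creation) != set(self.source_order)
                or set(z.degradation) != set(self.leaf_order)
                or set(z.activities) != set(self.pep_order)):
            raise ValueError("parameter domains must be exactly (S, L, P) of the graph")
        return np.array(
            [z.creation[s] for s in self.source_order]
            + [z.degradation[s] for s in self.leaf_order]
            + [z.activities[p] for p in self.pep_order]
        )

    def unpack(self, zvec: np.ndarray) -> ModelParameters:
        ns, nl = self.n_sources, self.n_leaves
        return ModelParameters(
            dict(zip(self.source_order, zvec[:ns].tolist())),
            dict(zip(self.leaf_order, zvec[ns:ns + nl].tolist())),
            dict(zip(self.pep_order, zvec[ns + nl:].tolist())),
        )

    def phi(self, zvec: np.ndarray) -> np.ndarray:
        """Expected amounts in topological order (the three-case recursion)."""
        lam = zvec[self.n_sources + self.n_leaves:]
        phi = np.empty(self.n_nodes)
        for i in range(self.n_nodes):
            kind = self.kind[i]
            if kind != 2:
                out = 0.0
                for rho, p in self.out_ev[i]:
                    out += rho * lam[p]
                if out <= 0.0:
                    raise ValueError(
                        f"node {self.order[i]!r} has no active cleavage"
                    )
            if kind == 0:
                phi[i] = zvec[self.param_index[i]] / out
            else:
                inflow = 0.0
                for j, rho, p in self.in_ev[i]:
                    inflow += phi[j] * rho * lam[p]
                phi[i] = inflow / (zvec[self.param_index[i]] if kind == 2 else out)
        return phi


def expected_amounts(graph: CleavageGraph, z: ModelParameters) -> dict[str, float]:
    """Stationary expected amount of every peptide node under parameters z."""
    compiled = _CompiledGraph(graph)
    phi = compiled.phi(compiled.pack(z))
    return dict(zip(compiled.order, phi.tolist()))


def balance_residuals(
    graph: CleavageGraph, z: ModelParameters, phi: Mapping[str, float]
) -> dict[str, float]:
    """Net stationary flow imbalance at every node for amounts ``phi``.

    (creation + inflow) minus (outflow + degradation); identically zero at
    phi = expected_amounts(graph, z).
    """
    lam = z.activities
    residuals: dict[str, float] = {}
    inflow: dict[str, float] = {s: 0.0 for s in graph.nodes}
    outrate: dict[str, float] = {s: 0.0 for s in graph.nodes}
    for e in graph.events:
        flux = lam[e.peptidase_id] * e.rho
        outrate[e.substrate] += flux
        inflow[e.prefix] += phi[e.substrate] * flux
        inflow[e.suffix] += phi[e.substrate] * flux
    for seq in graph.nodes:
        creation = z.creation.get(seq, 0.0)
        degradation = z.degradation.get(seq, 0.0)
        residuals[seq] = (creation + inflow[seq]
                          - phi[seq] * (degradation + outrate[seq]))
    return residuals


def activity_constraint_matrix(
    graph: CleavageGraph, phi: Mapping[str, float]
) -> tuple[np.ndarray, list[str]]:
    """Linear constraints that interior balances place on the activities.

    At stationarity every interior node v satisfies
    ``inflow(v) = phi_v * outflow_rate(v)``, which is linear and
    homogeneous in the activity vector lambda once the amounts ``phi``
    are known (sources and leaves impose nothing on lambda — their free
    creation/degradation rates absorb any activity rescaling).  Returns
    the (interior nodes x peptidases) coefficient matrix and the
    peptidase order.  The activities are identifiable up to the global
    scale gauge exactly when this matrix has rank |P| - 1; a peptidase
    with an all-zero column is structurally unidentifiable.
    """
    peps = sorted(graph.peptidases())
    pidx = {p: i for i, p in enumerate(peps)}
    sources, leaves = graph.sources(), graph.leaves()
    interior = [s for s in topological_order(graph)
                if s not in sources and s not in leaves]
    m = np.zeros((len(interior), len(peps)))
    vidx = {v: i for i, v in enumerate(interior)}
    for e in graph.events:
        j = pidx[e.peptidase_id]
        for product in (e.prefix, e.suffix):
            if product in vidx:
                m[vidx[product], j] += phi[e.substrate] * e.rho
        if e.substrate in vidx:
            m[vidx[e.substrate], j] -= phi[e.substrate] * e.rho
    return m, peps


def _observed_in_order(compiled: _CompiledGraph, observed: Mapping[str, float]) -> tuple[list[int], np.ndarray]:
    idx = [compiled.index[s] for s in compiled.order if s in observed]
    y = np.array([observed[compiled.order[i]] for i in idx], dtype=float)
    return idx, y


def objective(
    graph: CleavageGraph, z: ModelParameters, observed: Mapping[str, float]
) -> np.ndarray:
    """Residual vector (phi_v(z) - y_v) over observed nodes, topologically ordered."""
    compiled = _CompiledGraph(graph)
    m, n = len(observed), compiled.n_params
    if m < n:
        raise ValueError(f"under-determined: m={m} < n={n}")
    idx, y = _observed_in_order(compiled, observed)
    phi = compiled.phi(compiled.pack(z))
    return phi[idx] - y


def relative_squared_error(y_hat: Mapping[str, float], y: Mapping[str, float]) -> float:
    """Residual sum of squares over total sum of squares about the mean."""
    if set(y_hat) != set(y):
        raise ValueError("y_hat and y must share the same key set")
    if not y:
        raise ValueError("empty observation set")
    keys = sorted(y)
    yv = np.array([y[k] for k in keys], dtype=float)
    yh = np.array([y_hat[k] for k in keys], dtype=float)
    denom = float(np.sum((yv.mean() - yv) ** 2))
    if denom == 0.0:
        raise ValueError("zero denominator: observed amounts are constant")
    return float(np.sum((yh - yv) ** 2) / denom)


_START_LOG_LO, _START_LOG_HI = math.log(1e-2), math.log(1e2)


def fit(
    graph: CleavageGraph,
    observed: Mapping[str, float] | None = None,
    n_starts: int = 7,
    max_iter: int = 200,
    seed: int = 0,
    ftol: float = 1e-10,
    xtol: float = 1e-10,
) -> FitResult:
    """Multi-start Levenberg-Marquardt fit of the degradation parameters.

    Parameters are optimised in log space (strict positivity by
    construction); ``n_starts`` initial points are drawn log-uniformly
    from [1e-2, 1e2] using ``seed`` and each run is capped at roughly
    ``max_iter`` LM iterations (``max_iter * (n + 1)`` function
    evaluations under forward-difference Jacobians).  The start with the
    lowest final relative squared error wins.  Deterministic given
    (graph, observed, options, seed).
    """
    if observed is None:
        observed = graph.observed()
    compiled = _CompiledGraph(graph)
    m, n = len(observed), compiled.n_params
    if m < n:
        raise ValueError(f"under-determined: m={m} < n={n}")
    idx, y = _observed_in_order(compiled, observed)
    if np.any(y <= 0):
        raise ValueError("observed amounts must be strictly positive on O")
    tss = float(np.sum((y.mean() - y) ** 2))
    if tss == 0.0:
        raise ValueError("zero denominator: observed amounts are constant")

    def residuals(theta: np.ndarray) -> np.ndarray:
        # clip wandering steps so exp never under/overflows, and feed the
        # solver a large finite penalty instead of inf/nan so bad regions
        # are retreated from rather than fatal
        phi = compiled.phi(np.exp(np.clip(theta, -46.0, 46.0)))
        r = phi[idx] - y
        return np.where(np.isfinite(r), r, 1e100)

    rng = np.random.default_rng(seed)
    starts = rng.uniform(_START_LOG_LO, _START_LOG_HI, size=(n_starts, n))
    max_nfev = max_iter * (n + 1)
    best = None
    nfevs: list[int] = []
    rses: list[float] = []
    for s in range(n_starts):
        try:
            sol = least_squares(residuals, starts[s], method="lm",
                                max_nfev=max_nfev, ftol=ftol, xtol=xtol, gtol=1e-10)
        except Exception:  # a start may blow up numerically; others can still win
            nfevs.append(0)
            rses.append(float("inf"))
            continue
        nfevs.append(int(sol.nfev))
        if not np.all(np.isfinite(sol.fun)):
            rses.append(float("inf"))
            continue
        rse_s = float(np.sum(sol.fun ** 2) / tss)
        rses.append(rse_s)
        if best is None or rse_s < best[1]:
            best = (s, rse_s, sol)
    if best is None:
        raise RuntimeError("optimization diverged: no start produced finite residuals")
    s_best, rse_best, sol = best
    zvec = np.exp(np.clip(sol.x, -46.0, 46.0))  # same clipping as the residuals
    phi = compiled.phi(zvec)
    y_hat = {compiled.order[i]: float(phi[i]) for i in idx}
    return FitResult(
        z_hat=compiled.unpack(zvec),
        y_hat=y_hat,
        rse=rse_best,
        n_starts=n_starts,
        iterations_per_start=nfevs,
        best_start_index=s_best,
        converged=bool(sol.status > 0),
        seed=seed,
        rse_per_start=rses,
    )
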