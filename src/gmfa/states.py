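"""Disease-progression extent and distances between health states.

The progression of a chronic disease is described not on the time axis but
on an *extent* coordinate xi stretching between two reference states: A, a
healthy individual, and B, fully manifested advanced disease.  Under the
quasi-linearity assumption, a patient's position along the A->B segment is
the scalar projection of their state onto the segment direction.

Two metrics compare health states defined by generalized flux vectors:

* plain Euclidean distance in flux space;
* the *health state distance*, a manifold geodesic: shortest-path length
  through a symmetric k-nearest-neighbor graph built over the cohort's flux
  vectors (Isomap-style), which respects the shape of the population's state
  manifold rather than cutting across it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import cdist

from .network import GeneralizedStoichiometry
from .twin import DigitalTwin, StateVector

__all__ = [
    "ReferenceTrajectory",
    "HealthState",
    "ManifoldConfig",
    "extent_of",
    "euclidean_distance",
    "health_state_distance",
    "distances_to_state",
    "complication_free_state",
    "unit_flux_trajectory",
]


@dataclass(frozen=True)
class HealthState:
    """A point in flux space; ``extent`` is set once projected on a trajectory."""

    flux_vector: np.ndarray
    extent: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.flux_vector, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("flux vector contains non-finite values")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "flux_vector", arr)


@dataclass(frozen=True)
class ManifoldConfig:
    """k-NN graph settings for the health state distance."""

    k_neighbors: int = 10
    fallback: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass(frozen=True)
class ReferenceTrajectory:
    """States A (healthy) and B (advanced disease) plus a flux template.

    ``v_AB`` is the flux vector carrying the system from A to B over one
    extent unit: the bounded least-squares solution of S v = x_B - x_A.
    """

    x_A: StateVector
    x_B: StateVector
    v_AB: np.ndarray

    def __post_init__(self) -> None:
        if np.allclose(self.x_B.values, self.x_A.values):
            raise ValueError("trajectory endpoints coincide: ||x_B - x_A|| = 0")
        arr = np.asarray(self.v_AB, dtype=float).copy()
        arr.setflags(write=False)
        object.__setattr__(self, "v_AB", arr)

    @property
    def direction(self) -> np.ndarray:
        return np.asarray(self.x_B.values) - np.asarray(self.x_A.values)

    @classmethod
    def from_states(
        cls,
        model: GeneralizedStoichiometry,
        x_A: StateVector,
        x_B: StateVector,
    ) -> "ReferenceTrajectory":
        """Build the flux template by bounded least squares on S v = x_B - x_A."""
        lb, ub = model.flux_bounds()
        delta = np.asarray(x_B.values) - np.asarray(x_A.values)
        res = optimize.lsq_linear(np.asarray(model.S), delta, bounds=(lb, ub), tol=1e-12)
        return cls(x_A, x_B, res.x)


def unit_flux_trajectory(
    model: GeneralizedStoichiometry, x_A: StateVector | None = None
) -> ReferenceTrajectory:
    """Default reference trajectory: one extent unit of unit flux on every edge.

    With v_AB = 1 (clipped into the flux bounds), x_B = x_A + S v_AB is an
    advanced-disease state in which every modeled conversion has progressed
    by one normalized unit.  This is the packaged stand-in when no measured
    state table for A and B is supplied; both endpoints are overridable.
    """
    from .twin import reference_state

    if x_A is None:
        x_A = reference_state(model)
    lb, ub = model.flux_bounds()
    v_ab = np.clip(np.ones(model.n_fluxes), lb, ub)
    x_b = StateVector(
        np.asarray(x_A.values) + np.asarray(model.S) @ v_ab, tuple(model.node_ids)
    )
    return ReferenceTrajectory(x_A, x_b, v_ab)


def disease_state_from_cohort(
    model: GeneralizedStoichiometry,
    states: Sequence[StateVector],
    x_A: StateVector | None = None,
    percentile: float = 97.5,
) -> StateVector:
    """Advanced-disease endpoint B estimated from a cohort of fitted states.

    The cohort's mean displacement from A defines the disease direction;
    B is placed at the given percentile (97.5 by default) of the cohort's
    scalar projections onto that direction, i.e. just past the sickest
    patients observed.
    """
    from .twin import reference_state

    if x_A is None:
        x_A = reference_state(model)
    X = np.vstack([np.asarray(s.values) for s in states])
    xa = np.asarray(x_A.values)
    direction = X.mean(axis=0) - xa
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("cohort mean coincides with state A; no disease direction")
    direction = direction / norm
    projections = (X - xa) @ direction
    radius = float(np.percentile(projections, percentile))
    return StateVector(xa + radius * direction, tuple(model.node_ids))


def extent_of(x: StateVector, traj: ReferenceTrajectory) -> float:
    """Scalar projection of a state onto the A->B segment: 0 at A, 1 at B.

    Linear (affine) in x and deliberately unclipped, so states beyond the
    segment report extents below 0 or above 1.
    """
    d = traj.direction
    denom = float(d @ d)
    if denom == 0.0:
        raise ValueError("zero-length trajectory")
    return float((np.asarray(x.values) - np.asarray(traj.x_A.values)) @ d / denom)


def _as_flux(a) -> np.ndarray:
    if isinstance(a, HealthState):
        return np.asarray(a.flux_vector, dtype=float)
    if isinstance(a, DigitalTwin):
        return np.asarray(a.v, dtype=float)
    return np.asarray(a, dtype=float)


def euclidean_distance(a, b) -> float:
    """Plain l2 distance between two flux-space states."""
    va, vb = _as_flux(a), _as_flux(b)
    if va.shape != vb.shape:
        raise ValueError(f"flux dimension mismatch: {va.shape} vs {vb.shape}")
    return float(np.linalg.norm(va - vb))


#: Zero-length edges (coincident states) are stored with this weight because
#: sparse graph routines treat explicit zeros as absent edges.
_ZERO_EDGE = 1e-300


def _knn_graph(points: np.ndarray, k: int) -> csr_matrix:
    """Symmetric k-NN graph (union of directed k-NN edges, Euclidean weights)."""
    n = len(points)
    D = cdist(points, points)
    rows, cols, vals = [], [], []
    order = np.argsort(D, axis=1, kind="stable")
    for i in range(n):
        for j in order[i, 1 : k + 1]:
            rows.append(i)
            cols.append(int(j))
            vals.append(max(D[i, j], _ZERO_EDGE))
    G = csr_matrix((vals, (rows, cols)), shape=(n, n))
    return G.maximum(G.T)


def _insert_point(
    G: csr_matrix, points: np.ndarray, p: np.ndarray, k: int
) -> csr_matrix:
    """Augment the graph with one external point wired to its k nearest cohort points."""
    n = G.shape[0]
    d = np.linalg.norm(points - p, axis=1)
    nearest = np.argsort(d, kind="stable")[:k]
    G = G.tolil(copy=True)
    G.resize((n + 1, n + 1))
    for j in nearest:
        w = max(d[j], _ZERO_EDGE)
        G[n, j] = w
        G[j, n] = w
    return G.tocsr()


def health_state_distance(
    cohort_fluxes: Sequence[np.ndarray] | np.ndarray,
    a,
    b,
    cfg: ManifoldConfig | None = None,
) -> float:
    """Manifold (k-NN graph geodesic) distance between two health states.

    The graph is built over the cohort's flux vectors; ``a`` and ``b`` are
    inserted with edges to their k nearest cohort points, and the shortest
    path a -> b is returned.  If the two ends are disconnected, falls back to
    the Euclidean distance (with a warning), per ``cfg.fallback``.
    """
    cfg = cfg or ManifoldConfig()
    pts = np.asarray([_as_flux(p) for p in cohort_fluxes], dtype=float)
    va, vb = _as_flux(a), _as_flux(b)
    if len(pts) <= cfg.k_neighbors:
        raise ValueError(
            f"cohort of {len(pts)} points is too small for k={cfg.k_neighbors}"
        )
    if np.array_equal(va, vb):
        return 0.0
    # Both states are wired to their k nearest *cohort* points only.
    G = _knn_graph(pts, cfg.k_neighbors)
    G = _insert_point(G, pts, va, cfg.k_neighbors)
    G = _insert_point(G, pts, vb, cfg.k_neighbors)
    n = len(pts)
    dist = dijkstra(G, directed=False, indices=n)
    d = float(dist[n + 1])
    if not np.isfinite(d):
        if cfg.fallback == "euclidean":
            warnings.warn("health state graph disconnected; falling back to Euclidean")
            return euclidean_distance(va, vb)
        raise ValueError("health state graph disconnected between the two states")
    return d


def distances_to_state(
    cohort_fluxes: Sequence[np.ndarray] | np.ndarray,
    state,
    cfg: ManifoldConfig | None = None,
    metric: str = "manifold",
) -> np.ndarray:
    """Distance from every cohort member to one reference state.

    With ``metric='manifold'``, a single-source shortest path from the
    inserted reference state over the cohort k-NN graph (cohort members are
    themselves graph vertices); disconnected members fall back to Euclidean
    with a warning.  With ``metric='euclidean'``, plain norms.
    """
    pts = np.asarray([_as_flux(p) for p in cohort_fluxes], dtype=float)
    s = _as_flux(state)
    eucl = np.linalg.norm(pts - s, axis=1)
    if metric == "euclidean":
        return eucl
    if metric != "manifold":
        raise ValueError(f"unknown metric {metric!r}")
    cfg = cfg or ManifoldConfig()
    if len(pts) <= cfg.k_neighbors:
        raise ValueError(
            f"cohort of {len(pts)} points is too small for k={cfg.k_neighbors}"
        )
    G = _knn_graph(pts, cfg.k_neighbors)
    G = _insert_point(G, pts, s, cfg.k_neighbors)
    dist = dijkstra(G, directed=False, indices=len(pts))[: len(pts)]
    disconnected = ~np.isfinite(dist)
    if disconnected.any():
        warnings.warn(
            f"{int(disconnected.sum())} cohort member(s) disconnected from the "
            "reference state; using Euclidean fallback for them"
        )
        dist[disconnected] = eucl[disconnected]
    return dist


def complication_free_state(
    twins: Sequence[DigitalTwin], labels: Mapping[str, int]
) -> HealthState:
    """Component-wise median flux state over complication-free patients.

    ``labels`` maps patient id -> {0, 1}; patients with label 0 (no
    ophthalmic diagnosis) define the reference state.
    """
    free = [t for t in twins if t.ok and not labels.get(t.patient_id, 0)]
    if not free:
        raise ValueError("no complication-free patients in the cohort")
    V = np.vstack([t.v for t in free])
    return HealthState(np.median(V, axis=0))
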