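"""Per-patient digital-twin construction by constrained quadratic optimization.

A twin is the generalized flux vector ``v`` that best explains one patient's
readings under the stoichiometric state equation.  With a single
cross-sectional time point, the state equation is linearized over one unit of
the progression extent:

    x = x_A + S v        (all in z-score state units)

and the fit solves

    minimize_v   sum_i w_i (x_i - y_i)^2  +  ridge * ||v||^2
    subject to   lb <= v <= ub
                 fitted raw value of each observed node within the
                 +-window_fraction soft-data band around its reading

where ``y`` is the patient's normalized reading vector.  The small ridge term
makes the program strictly convex (unique twin) even when S is column-rank
deficient.  If the band and the flux bounds are jointly infeasible, the band
constraints are relaxed with quadratically penalized slack instead of
failing, so cohort pipelines never halt on an outlier patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .network import GeneralizedStoichiometry

__all__ = [
    "PatientRecord",
    "StateVector",
    "FitConfig",
    "DigitalTwin",
    "impute_missing",
    "normalize_readings",
    "denormalize_state",
    "reference_state",
    "fit_twin",
    "fit_cohort",
]

#: Raw values closer to zero than this get an absolute soft band of
#: 0.2 * reference_sd instead of the degenerate relative band.
_NEAR_ZERO = 1e-9


@dataclass
class PatientRecord:
    """One patient's raw readings, demographics and diagnoses.

    ``readings`` maps node id -> raw value in the node's own unit; a missing
    key means the reading was not taken.  ``imputed`` records which entries
    were filled in by :func:`impute_missing`.
    """

    patient_id: str
    readings: dict[str, float] = field(default_factory=dict)
    age: float | None = None
    diabetes_duration: float | None = None
    diagnoses_baseline: dict[str, int] = field(default_factory=dict)
    diagnoses_followup: dict[str, int] = field(default_factory=dict)
    imputed: set[str] = field(default_factory=set)

    def observed_nodes(self) -> set[str]:
        return set(self.readings)


@dataclass(frozen=True)
class StateVector:
    """Length-M state in normalized (z-score) units, ordered like the model."""

    values: np.ndarray
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size != len(self.node_ids):
            raise ValueError("state length does not match node list")
        if not np.all(np.isfinite(arr)):
            raise ValueError("state vector contains non-finite values")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))

    def __getitem__(self, node_id: str) -> float:
        return float(self.values[self.node_ids.index(node_id)])


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the twin quadratic program.

    window_fraction
        Half-width of the soft data band, relative to each raw reading
        (0.20 means the fitted value may deviate +-20%).
    ridge_weight
        Strict-convexity regularizer on ``v``; small enough not to bias the
        fit, large enough for a unique reproducible solution.
    objective_weights
        Per-node weight overrides; nodes absent from the record are always
        weighted 0 and carry no band constraint.
    """

    window_fraction: float = 0.20
    ridge_weight: float = 1e-6
    objective_weights: Mapping[str, float] = field(default_factory=dict)
    relax_on_infeasible: bool = True
    slack_penalty: float = 1e3
    solver_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.window_fraction < 1.0:
            raise ValueError("window_fraction must be in (0, 1)")
        if not self.ridge_weight > 0:
            raise ValueError("ridge_weight must be positive")


@dataclass
class DigitalTwin:
    """The fitted flux vector plus the fitted state and fit diagnostics."""

    patient_id: str
    v: np.ndarray | None
    x_fit: StateVector | None
    objective_value: float
    residuals: dict[str, float]
    relaxed: bool
    solver_status: str  # optimal | relaxed_optimal | failed

    @property
    def ok(self) -> bool:
        return self.solver_status in ("optimal", "relaxed_optimal")


# ---------------------------------------------------------------------------
# imputation & normalization
# ---------------------------------------------------------------------------


def impute_missing(cohort: Sequence[PatientRecord]) -> list[PatientRecord]:
    """Fill missing readings with the population average of observed values.

    Nodes never observed in any patient are left absent everywhere (a
    warning names them); imputed entries are recorded per patient in
    ``record.imputed``.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cannot impute an empty cohort")

    all_nodes: set[str] = set()
    for r in cohort:
        all_nodes |= set(r.readings)
    means: dict[str, float] = {}
    for node in all_nodes:
        vals = [r.readings[node] for r in cohort if node in r.readings]
        means[node] = float(np.mean(vals))

    never_seen = {
        node
        for r in cohort
        for node in (set(all_nodes) - set(r.readings))
        if node not in all_nodes
    }
    if never_seen:  # pragma: no cover - defensive, all_nodes covers by construction
        warnings.warn(f"nodes never observed, excluded from fitting: {sorted(never_seen)}")

    out = []
    for r in cohort:
        filled = dict(r.readings)
        imputed = set(r.imputed)
        for node, mean in means.items():
            if node not in filled:
                filled[node] = mean
                imputed.add(node)
        out.append(replace(r, readings=filled, imputed=imputed))
    return out


def normalize_readings(
    record: PatientRecord, model: GeneralizedStoichiometry
) -> StateVector:
    """Map raw readings to the z-score state scale; unobserved nodes sit at 0.

    Uses each node's reference mean/SD; the transform is exactly invertible
    via :func:`denormalize_state`.
    """
    mean, sd = model.reference_stats()
    for node in model.nodes:
        if node.id in record.readings and node.has_reference and node.reference_sd == 0:
            raise ValueError(f"node {node.id!r} has zero reference_sd")
    values = np.zeros(model.n_nodes)
    for i, node in enumerate(model.nodes):
        if node.id in record.readings:
            values[i] = (record.readings[node.id] - mean[i]) / sd[i]
    return StateVector(values, tuple(model.node_ids))


def denormalize_state(
    state: StateVector, model: GeneralizedStoichiometry
) -> np.ndarray:
    """Inverse of normalization: z-score state back to raw units (array, node order)."""
    mean, sd = model.reference_stats()
    return mean + sd * np.asarray(state.values)


def reference_state(model: GeneralizedStoichiometry) -> StateVector:
    """The all-reference-means state: 0 in normalized units for every node."""
    return StateVector(np.zeros(model.n_nodes), tuple(model.node_ids))


# ---------------------------------------------------------------------------
# the quadratic program
# ---------------------------------------------------------------------------


def _band_limits(
    y_raw: float, mean: float, sd: float, window: float
) -> tuple[float, float]:
    """Soft-band limits for one observed node, in normalized units."""
    if abs(y_raw) < _NEAR_ZERO:
        lo_raw, hi_raw = y_raw - 0.2 * sd, y_raw + 0.2 * sd
    else:
        a, b = y_raw * (1.0 - window), y_raw * (1.0 + window)
        lo_raw, hi_raw = min(a, b), max(a, b)
    return (lo_raw - mean) / sd, (hi_raw - mean) / sd


def _objective_terms(
    model: GeneralizedStoichiometry,
    record: PatientRecord,
    cfg: FitConfig,
):
    """Assemble (S, target, weights, band rows) of the QP in normalized units."""
    S = np.asarray(model.S)
    y = normalize_readings(record, model).values
    mean, sd = model.reference_stats()
    w = np.zeros(model.n_nodes)
    obs_idx: list[int] = []
    lo = []
    hi = []
    for i, node in enumerate(model.nodes):
        if node.id not in record.readings:
            continue
        w[i] = float(cfg.objective_weights.get(node.id, 1.0))
        obs_idx.append(i)
        b = _band_limits(record.readings[node.id], mean[i], sd[i], cfg.window_fraction)
        lo.append(b[0])
        hi.append(b[1])
    return S, y, w, np.array(obs_idx, dtype=int), np.array(lo), np.array(hi)


def _base_objective(v, S, xa, y, w, ridge):
    x = xa + S @ v
    r = x - y
    return float(np.sum(w * r * r) + ridge * np.dot(v, v))


def fit_twin(
    model: GeneralizedStoichiometry,
    record: PatientRecord,
    x_A: StateVector,
    cfg: FitConfig | None = None,
) -> DigitalTwin:
    """Fit one digital twin by strictly convex quadratic programming.

    Solver strategy: a bounded ridge least-squares solve first (fast path);
    if the result violates a soft band, the full QP with band constraints is
    solved; if band and bounds are jointly infeasible, the bands are relaxed
    with quadratically penalized slack and the twin is flagged ``relaxed``.
    """
    cfg = cfg or FitConfig()
    S, y, w, obs_idx, lo, hi = _objective_terms(model, record, cfg)
    xa = np.asarray(x_A.values)
    lb, ub = model.flux_bounds()
    n = model.n_fluxes
    tol = cfg.solver_tolerance

    if not obs_idx.size:
        warnings.warn(f"patient {record.patient_id}: no observed nodes; twin is v=0")
        v = np.zeros(n)
        return _package(model, record, v, xa, S, y, w, obs_idx, cfg, False, "optimal")

    sw = np.sqrt(w[obs_idx])
    A = np.vstack([sw[:, None] * S[obs_idx], np.sqrt(cfg.ridge_weight) * np.eye(n)])
    b = np.concatenate([sw * (y - xa)[obs_idx], np.zeros(n)])

    res = optimize.lsq_linear(A, b, bounds=(lb, ub), tol=1e-12, method="bvls")
    v = res.x
    x_obs = xa[obs_idx] + S[obs_idx] @ v
    feas_tol = max(tol, 1e-9)
    if np.all(x_obs >= lo - feas_tol) and np.all(x_obs <= hi + feas_tol):
        return _package(model, record, v, xa, S, y, w, obs_idx, cfg, False, "optimal")

    # Bands bind: full QP with linear band constraints.
    W = np.diag(w[obs_idx])
    H = 2.0 * (S[obs_idx].T @ W @ S[obs_idx] + cfg.ridge_weight * np.eye(n))
    g0 = 2.0 * (S[obs_idx].T @ (w[obs_idx] * (xa - y)[obs_idx]))

    def fun(vv):
        return _base_objective(vv, S[obs_idx], xa[obs_idx], y[obs_idx], w[obs_idx], cfg.ridge_weight)

    def grad(vv):
        return H @ vv + g0

    constraint = optimize.LinearConstraint(S[obs_idx], lo - xa[obs_idx], hi - xa[obs_idx])
    x0 = np.clip(v, lb, ub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = optimize.minimize(
            fun,
            x0,
            jac=grad,
            hess=lambda vv: H,
            bounds=optimize.Bounds(lb, ub),
            constraints=[constraint],
            method="trust-constr",
            options={"gtol": 1e-10, "xtol": 1e-14, "barrier_tol": 1e-12, "maxiter": 2000},
        )
    v = _polish_active_set(sol.x, H, g0, S[obs_idx], lo, hi, xa[obs_idx], lb, ub, fun)
    x_obs = xa[obs_idx] + S[obs_idx] @ v
    violation = float(
        max(np.max(lo - x_obs, initial=0.0), np.max(x_obs - hi, initial=0.0))
    )
    if violation <= 1e-6 and sol.status in (1, 2):
        return _package(model, record, v, xa, S, y, w, obs_idx, cfg, False, "optimal")

    if not cfg.relax_on_infeasible:
        return DigitalTwin(record.patient_id, None, None, np.inf, {}, False, "failed")

    # Relaxed solve: squared-hinge penalty on band violation, box bounds only.
    pen = cfg.slack_penalty

    def fun_relaxed(vv):
        x_o = xa[obs_idx] + S[obs_idx] @ vv
        under = np.maximum(lo - x_o, 0.0)
        over = np.maximum(x_o - hi, 0.0)
        return (
            _base_objective(vv, S[obs_idx], xa[obs_idx], y[obs_idx], w[obs_idx], cfg.ridge_weight)
            + pen * float(np.sum(under**2) + np.sum(over**2))
        )

    def grad_relaxed(vv):
        x_o = xa[obs_idx] + S[obs_idx] @ vv
        under = np.maximum(lo - x_o, 0.0)
        over = np.maximum(x_o - hi, 0.0)
        return H @ vv + g0 + 2.0 * pen * (S[obs_idx].T @ (over - under))

    sol = optimize.minimize(
        fun_relaxed,
        x0,
        jac=grad_relaxed,
        bounds=optimize.Bounds(lb, ub),
        method="L-BFGS-B",
        options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 5000},
    )
    if not sol.success and not np.all(np.isfinite(sol.x)):
        warnings.warn(f"patient {record.patient_id}: twin fit failed after relaxation")
        return DigitalTwin(record.patient_id, None, None, np.inf, {}, True, "failed")
    return _package(
        model, record, sol.x, xa, S, y, w, obs_idx, cfg, True, "relaxed_optimal"
    )


def _polish_active_set(
    v: np.ndarray,
    H: np.ndarray,
    g0: np.ndarray,
    A: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    xa: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    fun,
    active_tol: float = 1e-4,
) -> np.ndarray:
    """Snap an interior-point solution onto its active constraint set.

    Solves the equality-constrained QP restricted to the constraints the
    interior-point solver left (nearly) active; the polished point is kept
    only if it is feasible and does not worsen the objective.
    """
    n = v.size
    x = xa + A @ v
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    for i in range(A.shape[0]):
        if x[i] - lo[i] < active_tol:
            rows.append(A[i])
            rhs.append(lo[i] - xa[i])
        elif hi[i] - x[i] < active_tol:
            rows.append(A[i])
            rhs.append(hi[i] - xa[i])
    eye = np.eye(n)
    for j in range(n):
        if v[j] - lb[j] < active_tol:
            rows.append(eye[j])
            rhs.append(lb[j])
        elif ub[j] - v[j] < active_tol:
            rows.append(eye[j])
            rhs.append(ub[j])
    if rows:
        E = np.vstack(rows)
        k = E.shape[0]
        KKT = np.block([[H, E.T], [E, np.zeros((k, k))]])
        target = np.concatenate([-g0, rhs])
        sol, *_ = np.linalg.lstsq(KKT, target, rcond=None)
        cand = sol[:n]
    else:
        cand = np.linalg.solve(H, -g0)
    x_c = xa + A @ cand
    feasible = (
        np.all(cand >= lb - 1e-9)
        and np.all(cand <= ub + 1e-9)
        and np.all(x_c >= lo - 1e-9)
        and np.all(x_c <= hi + 1e-9)
    )
    if feasible and fun(cand) <= fun(v) + 1e-12:
        return cand
    return v


def _package(
    model: GeneralizedStoichiometry,
    record: PatientRecord,
    v: np.ndarray,
    xa: np.ndarray,
    S: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    obs_idx: np.ndarray,
    cfg: FitConfig,
    relaxed: bool,
    status: str,
) -> DigitalTwin:
    x = xa + S @ v
    state = StateVector(x, tuple(model.node_ids))
    mean, sd = model.reference_stats()
    raw_fit = mean + sd * x
    residuals = {
        model.nodes[i].id: float(raw_fit[i] - record.readings[model.nodes[i].id])
        for i in obs_idx
    }
    obj = _base_objective(v, S[obs_idx], xa[obs_idx], y[obs_idx], w[obs_idx], cfg.ridge_weight) if obs_idx.size else float(
        cfg.ridge_weight * np.dot(v, v)
    )
    return DigitalTwin(
        patient_id=record.patient_id,
        v=np.asarray(v, dtype=float),
        x_fit=state,
        objective_value=obj,
        residuals=residuals,
        relaxed=relaxed,
        solver_status=status,
    )


def fit_cohort(
    model: GeneralizedStoichiometry,
    cohort: Iterable[PatientRecord],
    x_A: StateVector,
    cfg: FitConfig | None = None,
) -> list[DigitalTwin]:
    """Fit every patient, in input order; failures are flagged, never raised."""
    cohort = list(cohort)
    if not cohort:
        warnings.warn("fit_cohort called with an empty cohort")
        return []
    cfg = cfg or FitConfig()
    twins = [fit_twin(model, record, x_A, cfg) for record in cohort]
    failed = [t.patient_id for t in twins if not t.ok]
    if failed:
        warnings.warn(f"twin fitting failed for {len(failed)} patient(s): {failed[:5]}")
    return twins
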