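"""Shared test infrastructure: small-model builder and independent oracles.

The oracles here deliberately avoid the code paths they check: the QP oracle
is a dense grid search over the feasible box, and the rank-test oracles
enumerate permutations directly.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import rankdata

from gmfa.network import FluxSpec, GeneralizedStoichiometry, NodeSpec
from gmfa.twin import PatientRecord


def make_model(S, lb=None, ub=None, means=None, sds=None) -> GeneralizedStoichiometry:
    """Build a small model straight from a signed stoichiometry matrix."""
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    lb = np.full(n, -10.0) if lb is None else np.asarray(lb, dtype=float)
    ub = np.full(n, 10.0) if ub is None else np.asarray(ub, dtype=float)
    means = np.zeros(m) if means is None else np.asarray(means, dtype=float)
    sds = np.ones(m) if sds is None else np.asarray(sds, dtype=float)
    nodes = tuple(
        NodeSpec(
            f"n{i}", node_class="metabolite", reference_mean=means[i], reference_sd=sds[i]
        )
        for i in range(m)
    )
    fluxes = []
    for j in range(n):
        subs = tuple((f"n{i}", -S[i, j]) for i in range(m) if S[i, j] < 0)
        prods = tuple((f"n{i}", S[i, j]) for i in range(m) if S[i, j] > 0)
        fluxes.append(FluxSpec(f"f{j}", subs, prods, lb[j], ub[j]))
    return GeneralizedStoichiometry(nodes, tuple(fluxes))


# ---------------------------------------------------------------------------
# twin QP vs dense grid search
# ---------------------------------------------------------------------------


def random_qp_instance(rng: np.random.Generator):
    """Random 3-node / 3-flux instance whose 20% bands contain a grid point.

    Readings are placed at y = (S v*)(1 + delta) with v* interior to the
    bounds, every |S v*| >= 0.3 and |delta| <= 0.05; at grid step 0.01 the
    worst-case band shrinkage leaves >= 0.015 absolute slack, so the grid
    search oracle always has a feasible point.
    """
    while True:
        S = rng.integers(-2, 3, size=(3, 3)).astype(float)
        if np.any(np.all(S == 0, axis=0)) or np.any(np.all(S == 0, axis=1)):
            continue
        lb = np.round(rng.uniform(-0.6, -0.2, 3), 2)
        ub = np.round(rng.uniform(0.2, 0.6, 3), 2)
        for _ in range(25):
            v_star = rng.uniform(lb, ub)
            x = S @ v_star
            if np.all(np.abs(x) >= 0.3):
                y = x * (1 + rng.uniform(-0.05, 0.05, 3))
                model = make_model(S, lb=lb, ub=ub)
                record = PatientRecord(
                    "p", {f"n{i}": float(y[i]) for i in range(3)}
                )
                return model, record


def grid_search_objective(
    model: GeneralizedStoichiometry,
    record: PatientRecord,
    window: float = 0.20,
    ridge: float = 1e-6,
    step: float = 0.01,
) -> float | None:
    """Best objective over the dense flux grid; None if no grid point is feasible."""
    S = np.asarray(model.S)
    lb, ub = model.flux_bounds()
    axes = [np.arange(lb[j], ub[j] + step / 2, step) for j in range(model.n_fluxes)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, model.n_fluxes)
    X = grid @ S.T
    y = np.array([record.readings[n.id] for n in model.nodes])
    lo = np.minimum(y * (1 - window), y * (1 + window))
    hi = np.maximum(y * (1 - window), y * (1 + window))
    feasible = np.all((X >= lo - 1e-12) & (X <= hi + 1e-12), axis=1)
    if not feasible.any():
        return None
    objective = ((X - y) ** 2).sum(axis=1) + ridge * (grid**2).sum(axis=1)
    return float(objective[feasible].min())


# ---------------------------------------------------------------------------
# rank-test oracles
# ---------------------------------------------------------------------------


def permutation_wmw_p(x, y) -> float:
    """Two-sided WMW P by direct rank-sum enumeration over label assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    observed = ranks[:n1].sum()
    sums = np.array([ranks[list(c)].sum() for c in combinations(range(n), n1)])
    mu = sums.mean()
    eps = 1e-9
    p_le = np.mean(sums <= observed + eps)
    p_ge = np.mean(sums >= observed - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def closed_form_by(p_values) -> np.ndarray:
    """Benjamini-Yekutieli adjustment computed literally from its definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    raw = p[order] * (m / np.arange(1, m + 1)) * c_m
    monotone = np.minimum.accumulate(raw[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(monotone, 1.0)
    return adjusted
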