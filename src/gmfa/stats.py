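"""Association screening of readings and fluxes against phenotypes.

Every reading variable and every fitted flux is tested as an independent
predictor of a binary phenotype with the two-sided Wilcoxon-Mann-Whitney
test; multiplicity is controlled with the Benjamini-Yekutieli false
discovery rate (valid under arbitrary dependence), and associations with
FDR at or below a cap (15% by default) are reported.  Readings and fluxes
are adjusted as two separate families, matching the two-table structure the
screen reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .twin import DigitalTwin, PatientRecord

__all__ = [
    "TestResult",
    "wmw_test",
    "by_fdr",
    "association_screen",
    "kendall_tau",
]

#: Below this smaller-group size the WMW null distribution is enumerated
#: exactly (ties handled exactly too); above it, the normal approximation
#: with tie correction and continuity correction is used.
EXACT_WMW_MAX_N = 8

#: Kendall tau switches to exact permutation enumeration at or below this n.
EXACT_TAU_MAX_N = 6


@dataclass(frozen=True)
class TestResult:
    variable_id: str
    statistic: float
    p_value: float
    fdr: float | None
    group_medians: tuple[float, float]
    n_per_group: tuple[int, int]


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of group x against group y, via midranks (ties get 0.5)."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    n1 = len(x)
    return float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)


def _exact_wmw_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact P by full enumeration of group-label assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    offset = n1 * (n1 + 1) / 2.0
    idx = np.fromiter(
        (i for combo in combinations(range(n), n1) for i in combo), dtype=np.intp
    ).reshape(-1, n1)
    us = ranks[idx].sum(axis=1) - offset
    mu = n1 * (n - n1) / 2.0
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wmw_test(values: Sequence[float], group_labels: Sequence[int]) -> TestResult:
    """Two-sided Wilcoxon-Mann-Whitney test of a variable between two groups.

    Exact (full enumeration of label assignments) when the smaller group has
    at most 8 members; otherwise the normal approximation with tie and
    continuity correction.  The statistic is the Mann-Whitney U of group 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    x = values[labels == 1]
    y = values[labels == 0]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u = _mann_whitney_u(x, y)
    if min(len(x), len(y)) <= EXACT_WMW_MAX_N:
        p = _exact_wmw_p(x, y, u)
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
    p = min(1.0, max(p, np.finfo(float).tiny))
    return TestResult(
        variable_id="",
        statistic=u,
        p_value=p,
        fdr=None,
        group_medians=(float(np.median(x)), float(np.median(y))),
        n_per_group=(len(x), len(y)),
    )


def by_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli adjusted P-values, input order preserved.

    adjusted_(i) is the monotone envelope of p_(i) * (m/i) * c(m) with
    c(m) = sum_{k=1..m} 1/k, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def association_screen(
    twins: Sequence[DigitalTwin],
    readings: Sequence[PatientRecord],
    phenotype_labels: Mapping[str, int],
    fdr_cap: float = 0.15,
    flux_ids: Sequence[str] | None = None,
) -> dict[str, list[TestResult]]:
    """Screen every reading variable and every flux against one phenotype.

    Returns ``{"readings": [...], "fluxes": [...]}``; each family is
    BY-adjusted separately, filtered to ``fdr <= fdr_cap`` and sorted by P.
    Constant variables are skipped with a warning.  Readings of imputed
    entries are excluded from that variable's test.
    """
    ok_twins = [t for t in twins if t.ok]
    ids = [t.patient_id for t in ok_twins]
    labels = np.array([phenotype_labels[i] for i in ids])
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need at least two patients per phenotype group")
    rec_by_id = {r.patient_id: r for r in readings}

    out: dict[str, list[TestResult]] = {}

    # family 1: raw readings (imputed entries do not count as observations)
    node_ids: list[str] = []
    for r in rec_by_id.values():
        node_ids.extend(k for k in r.readings if k not in r.imputed)
    node_ids = sorted(set(node_ids))
    reading_results: list[TestResult] = []
    for node in node_ids:
        vals, labs = [], []
        for pid, lab in zip(ids, labels):
            r = rec_by_id.get(pid)
            if r is not None and node in r.readings and node not in r.imputed:
                vals.append(r.readings[node])
                labs.append(lab)
        reading_results.extend(_screen_one(node, vals, labs))
    out["readings"] = _adjust_family(reading_results, fdr_cap)

    # family 2: fitted generalized fluxes
    flux_results: list[TestResult] = []
    if ok_twins:
        V = np.vstack([t.v for t in ok_twins])
        n_fluxes = V.shape[1]
        flux_names = list(flux_ids) if flux_ids else [f"flux_{j}" for j in range(n_fluxes)]
        for j in range(n_fluxes):
            flux_results.extend(_screen_one(flux_names[j], V[:, j], labels))
    out["fluxes"] = _adjust_family(flux_results, fdr_cap)
    return out


def _screen_one(name: str, vals, labs) -> list[TestResult]:
    vals = np.asarray(vals, dtype=float)
    labs = np.asarray(labs)
    if (labs == 1).sum() < 2 or (labs == 0).sum() < 2:
        warnings.warn(f"variable {name!r}: fewer than 2 observations per group; skipped")
        return []
    if np.ptp(vals) == 0:
        warnings.warn(f"variable {name!r} is constant; skipped")
        return []
    res = wmw_test(vals, labs)
    return [
        TestResult(
            name, res.statistic, res.p_value, None, res.group_medians, res.n_per_group
        )
    ]


def _adjust_family(results: list[TestResult], fdr_cap: float) -> list[TestResult]:
    if not results:
        return []
    fdr = by_fdr([r.p_value for r in results])
    adjusted = [
        TestResult(r.variable_id, r.statistic, r.p_value, float(q), r.group_medians, r.n_per_group)
        for r, q in zip(results, fdr)
    ]
    kept = [r for r in adjusted if r.fdr <= fdr_cap]
    return sorted(kept, key=lambda r: r.p_value)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall tau-b with two-sided P; exact permutation P for n <= 6.

    Raises on constant input, where tau is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Kendall tau is undefined for constant input")
    tau = float(stats.kendalltau(x, y).statistic)
    n = len(x)
    if n <= EXACT_TAU_MAX_N:
        taus = np.array(
            [stats.kendalltau(x, np.asarray(perm).astype(float)).statistic
             for perm in permutations(y)]
        )
        p = float(np.mean(np.abs(taus) >= abs(tau) - 1e-12))
    else:
        p = float(stats.kendalltau(x, y, method="asymptotic").pvalue)
    return tau, min(1.0, p)
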