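"""Flux-based logistic risk models and risk-group stratification.

The risk pipeline mirrors a balanced-resampling design: per iteration, half
of the positive cases plus an equally sized random draw of negatives train a
binomial logistic model on the generalized fluxes (optionally with age and
diabetes duration); the held-out remainder is scored and its ROC AUC
recorded.  Median AUC and its IQR over the iterations summarize model
quality; coefficients are averaged over the first ten refits and parametrize
the final scoring function.

Downstream, the logistic score is combined with the distance from each
patient's flux state to the complication-free state: patients in the upper
quartile of both are high risk, patients in the lower quartile of both are
low risk, and Fisher's exact test measures the coincidence of risk group and
actual diagnosis.  A "twilight zone" filter can exclude patients whose score
falls in a central percentile band before evaluating discrimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ResampleConfig",
    "RiskModel",
    "RiskGroups",
    "fit_logistic_resampled",
    "roc_auc",
    "twilight_exclusion",
    "TWILIGHT_PRESETS",
    "quadrant_risk_groups",
    "fisher_association",
    "median_flux_profile",
]

#: Central percentile bands for twilight-zone exclusion; "quantile_50" is the
#: degenerate no-exclusion preset.
TWILIGHT_PRESETS: dict[str, tuple[float, float]] = {
    "quantile_45": (45.0, 55.0),
    "quantile_40": (40.0, 60.0),
    "quantile_35": (35.0, 65.0),
    "quantile_33": (33.0, 67.0),
    "quantile_25": (25.0, 75.0),
    "quantile_50": (50.0, 50.0),
}

#: Standardized coefficients beyond this magnitude signal quasi-separation;
#: the fold is refit with a small ridge penalty.
_SEPARATION_CAP = 50.0
_RIDGE_ALPHA = 1e-4


@dataclass(frozen=True)
class ResampleConfig:
    n_iterations: int = 50
    positive_fraction: float = 0.5
    coefficient_averaging_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")


@dataclass
class RiskModel:
    feature_ids: list[str]
    coefficients: np.ndarray  # standardized scale
    intercept: float
    iteration_aucs: np.ndarray
    median_auc: float
    auc_iqr: tuple[float, float]
    scores: dict[str, float]
    feature_means: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    feature_sds: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def score(self, features: np.ndarray) -> np.ndarray:
        """Logistic score in [0, 1] for rows of raw (unstandardized) features."""
        Z = (np.atleast_2d(features) - self.feature_means) / self.feature_sds
        eta = Z @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class RiskGroups:
    assignments: dict[str, str]  # patient -> low | high | intermediate
    score_quartiles: tuple[float, float]
    distance_quartiles: tuple[float, float]

    def members(self, group: str) -> list[str]:
        return [p for p, g in self.assignments.items() if g == group]


def _fit_fold(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """One logistic fit on standardized features, ridge refit on separation."""
    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Z, y)
    coef = clf.coef_.ravel()
    if np.max(np.abs(coef)) > _SEPARATION_CAP:
        warnings.warn("quasi-separation detected; refitting with ridge penalty")
        clf = LogisticRegression(C=1.0 / _RIDGE_ALPHA, solver="lbfgs", max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Z, y)
        coef = clf.coef_.ravel()
    return coef, float(clf.intercept_[0])


def fit_logistic_resampled(
    features: np.ndarray,
    labels: Sequence[int],
    cfg: ResampleConfig | None = None,
    feature_ids: Sequence[str] | None = None,
    patient_ids: Sequence[str] | None = None,
) -> RiskModel:
    """Balanced-resampling logistic risk model.

    Per iteration: draw (without replacement) ``positive_fraction`` of the
    positives and an equal number of negatives as the training fold,
    standardize on the fold, fit, and record the held-out AUC.  Coefficients
    are the mean over the first ``coefficient_averaging_iterations`` refits;
    final scores are computed for every patient from the averaged
    coefficients (features standardized with full-sample statistics).
    Deterministic for a fixed seed.
    """
    cfg = cfg or ResampleConfig()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    n_train_pos = max(1, int(round(cfg.positive_fraction * pos.size)))
    if n_train_pos >= pos.size or n_train_pos >= neg.size:
        n_train_pos = min(pos.size - 1, neg.size - 1)
    if n_train_pos < 1:
        raise ValueError("too few cases per class for balanced resampling")

    rng = np.random.default_rng(cfg.seed)
    aucs = []
    coef_stack = []
    intercept_stack = []
    for _ in range(cfg.n_iterations):
        train_pos = rng.choice(pos, size=n_train_pos, replace=False)
        train_neg = rng.choice(neg, size=n_train_pos, replace=False)
        train = np.concatenate([train_pos, train_neg])
        test = np.setdiff1d(np.arange(y.size), train)
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        coef, icept = _fit_fold((X[train] - mu) / sd, y[train])
        coef_stack.append(coef)
        intercept_stack.append(icept)
        eta = (X[test] - mu) / sd @ coef + icept
        if len(np.unique(y[test])) == 2:
            aucs.append(roc_auc(1.0 / (1.0 + np.exp(-eta)), y[test])[0])
        else:  # pragma: no cover - requires pathological class split
            aucs.append(np.nan)

    n_avg = min(cfg.coefficient_averaging_iterations, len(coef_stack))
    coefficients = np.mean(coef_stack[:n_avg], axis=0)
    intercept = float(np.mean(intercept_stack[:n_avg]))
    aucs = np.asarray(aucs, dtype=float)

    mu_all = X.mean(axis=0)
    sd_all = X.std(axis=0)
    sd_all[sd_all == 0] = 1.0
    eta_all = (X - mu_all) / sd_all @ coefficients + intercept
    score_vec = 1.0 / (1.0 + np.exp(-eta_all))
    pids = list(patient_ids) if patient_ids is not None else [str(i) for i in range(y.size)]

    return RiskModel(
        feature_ids=list(feature_ids) if feature_ids is not None else [
            f"f{j}" for j in range(X.shape[1])
        ],
        coefficients=coefficients,
        intercept=intercept,
        iteration_aucs=aucs,
        median_auc=float(np.nanmedian(aucs)),
        auc_iqr=(
            float(np.nanpercentile(aucs, 25)),
            float(np.nanpercentile(aucs, 75)),
        ),
        scores=dict(zip(pids, score_vec.astype(float))),
        feature_means=mu_all,
        feature_sds=sd_all,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, np.ndarray]:
    """AUC as the Mann-Whitney concordance probability, plus ROC vertices.

    Ties between a positive and a negative score count 0.5, which makes
    AUC(scores) + AUC(-scores) = 1 exactly and equals the trapezoidal area
    under the tie-aware step curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = np.sum(ranks[y == 1]) - pos.size * (pos.size + 1) / 2.0
    auc = float(u / (pos.size * neg.size))

    # step-curve vertices: sweep thresholds from high to low
    order = np.argsort(-s, kind="stable")
    sorted_s = s[order]
    sorted_y = y[order]
    distinct = np.r_[np.flatnonzero(np.diff(sorted_s) != 0), sorted_y.size - 1]
    tps = np.cumsum(sorted_y)[distinct]
    fps = np.cumsum(1 - sorted_y)[distinct]
    tpr = np.r_[0.0, tps / pos.size]
    fpr = np.r_[0.0, fps / neg.size]
    return auc, np.column_stack([fpr, tpr])


def twilight_exclusion(
    scores: Sequence[float], band: tuple[float, float] | str = "quantile_40"
) -> np.ndarray:
    """Indices retained after removing the central score band.

    ``band`` is a (lower, upper) percentile pair, or a preset name; samples
    whose score lies strictly inside the open percentile interval are
    removed.  The degenerate (50, 50) preset retains everyone.
    """
    if isinstance(band, str):
        try:
            band = TWILIGHT_PRESETS[band]
        except KeyError:
            raise ValueError(f"unknown twilight preset {band!r}") from None
    lower, upper = band
    if not (0 < lower <= upper < 100):
        raise ValueError("band percentiles must satisfy 0 < lower <= upper < 100")
    s = np.asarray(scores, dtype=float)
    lo = np.percentile(s, lower)
    hi = np.percentile(s, upper)
    keep = ~((s > lo) & (s < hi))
    return np.flatnonzero(keep)


def quadrant_risk_groups(
    scores: Mapping[str, float], distances: Mapping[str, float]
) -> RiskGroups:
    """Joint-quartile risk groups from logistic score and health-state distance.

    High risk: score >= Q3(scores) and distance >= Q3(distances); low risk:
    both <= Q1; everyone else intermediate.  Quartiles use linear
    interpolation between order statistics.
    """
    if set(scores) != set(distances):
        raise ValueError("scores and distances must cover the same patients")
    if len(scores) < 4:
        raise ValueError("need at least 4 patients for quartile grouping")
    pids = sorted(scores)
    s = np.array([scores[p] for p in pids])
    d = np.array([distances[p] for p in pids])
    s_q1, s_q3 = np.percentile(s, [25, 75])
    d_q1, d_q3 = np.percentile(d, [25, 75])
    assignments = {}
    for p, sv, dv in zip(pids, s, d):
        if sv >= s_q3 and dv >= d_q3:
            assignments[p] = "high"
        elif sv <= s_q1 and dv <= d_q1:
            assignments[p] = "low"
        else:
            assignments[p] = "intermediate"
    return RiskGroups(assignments, (float(s_q1), float(s_q3)), (float(d_q1), float(d_q3)))


def fisher_association(
    groups: RiskGroups | Sequence[Sequence[int]],
    diagnosis: Mapping[str, int] | None = None,
) -> tuple[np.ndarray, float]:
    """2x2 risk-group x diagnosis table and the two-sided Fisher exact P.

    Accepts either a :class:`RiskGroups` plus a patient->diagnosis map (the
    table is built over low- and high-risk patients only), or an explicit
    2x2 table.  The P-value is the sum of hypergeometric probabilities of
    tables at most as probable as the observed one.
    """
    if isinstance(groups, RiskGroups):
        if diagnosis is None:
            raise ValueError("diagnosis map required with RiskGroups input")
        low = groups.members("low")
        high = groups.members("high")
        if not low or not high:
            raise ValueError("both low- and high-risk groups must be non-empty")
        table = np.array(
            [
                [sum(1 - diagnosis[p] for p in low), sum(diagnosis[p] for p in low)],
                [sum(1 - diagnosis[p] for p in high), sum(diagnosis[p] for p in high)],
            ]
        )
    else:
        table = np.asarray(groups, dtype=int)
        if table.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return table, p


def median_flux_profile(
    twins: Sequence, group_ids: Sequence[str], flux_ids: Sequence[str] | None = None
) -> dict[str, float]:
    """Group median fluxes as IQR-normalized deviations from the population.

    deviation_j = (median_group v_j - median_pop v_j) / IQR_pop v_j, sign
    preserved (negative = below the population median).  Fluxes with zero
    population IQR report deviation 0.
    """
    ok = [t for t in twins if t.ok]
    if not ok:
        raise ValueError("no successful twins")
    group = set(group_ids)
    V = np.vstack([t.v for t in ok])
    in_group = np.array([t.patient_id in group for t in ok])
    if not in_group.any():
        raise ValueError("group has no successfully fitted members")
    med_pop = np.median(V, axis=0)
    q1, q3 = np.percentile(V, [25, 75], axis=0)
    iqr = q3 - q1
    med_grp = np.median(V[in_group], axis=0)
    names = list(flux_ids) if flux_ids else [f"flux_{j}" for j in range(V.shape[1])]
    out = {}
    for j, name in enumerate(names):
        if iqr[j] == 0:
            warnings.warn(f"flux {name!r} has zero population IQR; deviation set to 0")
            out[name] = 0.0
        else:
            out[name] = float((med_grp[j] - med_pop[j]) / iqr[j])
    return out
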