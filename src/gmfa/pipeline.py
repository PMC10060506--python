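"""End-to-end cohort pipeline: fit -> distances -> associations -> risk.

Driven by a YAML config; every stage writes its artifacts into the run
directory together with a JSON log capturing seeds, solver statuses, family
sizes and the config echo, so identical (config, seed) reruns produce
byte-identical numeric tables.
"""

from __future__ import annotations

import json
import platform
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_cohort, twins_to_frame, write_cohort, write_table
from .network import GeneralizedStoichiometry, example_diabetes_map, load_model
from .risk import (
    ResampleConfig,
    fisher_association,
    fit_logistic_resampled,
    median_flux_profile,
    quadrant_risk_groups,
    roc_auc,
    twilight_exclusion,
)
from .states import ManifoldConfig, complication_free_state, distances_to_state
from .stats import association_screen
from .synthetic import LabelModel, SyntheticConfig, generate_cohort
from .twin import FitConfig, fit_cohort, impute_missing, reference_state

__all__ = ["run_pipeline", "PipelineError"]

_STAGES = ("fit", "distances", "associations", "risk")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    return yaml.safe_load(Path(config).read_text()) or {}


def _resolve_model(spec) -> GeneralizedStoichiometry:
    if spec in (None, "example"):
        return example_diabetes_map()
    return load_model(spec)


def _synthetic_config(model, section: Mapping, seed: int) -> SyntheticConfig:
    section = dict(section or {})
    perturbed = dict(section.pop("perturbed_fluxes", {}) or {})
    label = dict(section.pop("label_model", {}) or {})
    return SyntheticConfig(
        model=model,
        n_patients=int(section.pop("n_patients", 300)),
        perturbed_flux_ids=tuple(perturbed),
        effect_sizes=tuple(float(v) for v in perturbed.values()),
        label_model=LabelModel(
            intercept=float(label.get("intercept", -2.5)),
            beta_extent=float(label.get("beta_extent", 2.0)),
            beta_flux=float(label.get("beta_flux", 2.0)),
            flux_id=label.get("flux_id"),
        ),
        seed=seed,
        **section,
    )


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages and return the run directory.

    Stage selection: the ``stages`` list picks which artifact families are
    written; computational prerequisites (twin fitting for everything,
    distances for risk grouping) run regardless, silently.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("out_dir", "gmfa_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = list(cfg.get("stages", _STAGES))
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise PipelineError(f"stage config: unknown stage(s) {unknown}")
    phenotype = cfg.get("phenotype", "complication")
    log: dict = {
        "gmfa_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "stages": stages,
        "config_echo": {k: v for k, v in cfg.items() if k != "model_object"},
    }

    model = _resolve_model(cfg.get("model"))

    # --- cohort ----------------------------------------------------------
    try:
        if "cohort" in cfg:
            records = read_cohort(cfg["cohort"], model=model)
        else:
            syn_cfg = _synthetic_config(model, cfg.get("synthetic", {}), seed)
            records, gt = generate_cohort(syn_cfg)
            write_cohort(records, out / "cohort.csv")
            truth = pd.DataFrame(
                {
                    "patient_id": gt.patient_ids,
                    "true_extent": gt.extent,
                    "true_label": gt.labels,
                    "true_label_probability": gt.label_probability,
                }
            )
            write_table(truth, out / "ground_truth.csv")
    except Exception as exc:
        raise PipelineError(f"cohort stage failed: {exc}") from exc

    labels = {
        r.patient_id: int(r.diagnoses_baseline.get(phenotype, 0)) for r in records
    }

    # --- twin fitting ----------------------------------------------------
    try:
        fit_cfg = FitConfig(**(cfg.get("fit") or {}))
        cohort = impute_missing(records)
        x_a = reference_state(model)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            twins = fit_cohort(model, cohort, x_a, fit_cfg)
        ok = [t for t in twins if t.ok]
        log["fit"] = {
            "n_patients": len(twins),
            "n_fitted": len(ok),
            "n_relaxed": sum(t.relaxed for t in twins),
            "solver_statuses": sorted({t.solver_status for t in twins}),
        }
        if "fit" in stages:
            write_table(twins_to_frame(twins, model), out / "twins.csv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"fit stage failed: {exc}") from exc

    if not ok:
        raise PipelineError("fit stage failed: no patient could be fitted")

    need_distances = "distances" in stages or "risk" in stages
    distances = None
    if need_distances:
        try:
            man_cfg = ManifoldConfig(**(cfg.get("manifold") or {}))
            metric = cfg.get("distance_metric", "manifold")
            ref = complication_free_state(ok, labels)
            flux_mat = np.vstack([t.v for t in ok])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dist_vec = distances_to_state(flux_mat, ref, man_cfg, metric=metric)
            distances = {t.patient_id: float(d) for t, d in zip(ok, dist_vec)}
            if "distances" in stages:
                write_table(
                    pd.DataFrame(
                        {"patient_id": list(distances), "distance": list(distances.values()),
                         "metric": metric}
                    ),
                    out / "distances.csv",
                )
            log["distances"] = {"metric": metric, "k_neighbors": man_cfg.k_neighbors}
        except Exception as exc:
            raise PipelineError(f"distances stage failed: {exc}") from exc

    if "associations" in stages:
        try:
            screen = association_screen(
                ok, cohort, labels, fdr_cap=float(cfg.get("fdr_cap", 0.15)),
                flux_ids=model.flux_ids,
            )
            for family in ("readings", "fluxes"):
                rows = [
                    {
                        "variable": r.variable_id,
                        "statistic": r.statistic,
                        "p_value": r.p_value,
                        "fdr": r.fdr,
                        "median_with": r.group_medians[0],
                        "median_without": r.group_medians[1],
                        "n_with": r.n_per_group[0],
                        "n_without": r.n_per_group[1],
                    }
                    for r in screen[family]
                ]
                write_table(pd.DataFrame(rows), out / f"associations_{family}.csv")
            log["associations"] = {f: len(screen[f]) for f in screen}
        except Exception as exc:
            raise PipelineError(f"associations stage failed: {exc}") from exc

    if "risk" in stages:
        try:
            res_cfg = ResampleConfig(seed=seed, **(cfg.get("resample") or {}))
            demo = bool(cfg.get("use_demographics", True))
            features, feature_ids = _feature_matrix(ok, cohort, model, demo)
            y = np.array([labels[t.patient_id] for t in ok])
            rm = fit_logistic_resampled(
                features, y, res_cfg,
                feature_ids=feature_ids,
                patient_ids=[t.patient_id for t in ok],
            )
            write_table(
                pd.DataFrame(
                    {"feature": rm.feature_ids, "coefficient": rm.coefficients}
                ),
                out / "risk_coefficients.csv",
            )
            scores = np.array([rm.scores[t.patient_id] for t in ok])
            band = cfg.get("twilight_band", "quantile_50")
            retained = twilight_exclusion(scores, band if isinstance(band, str) else tuple(band))
            auc_all, roc_points = roc_auc(scores, y)
            write_table(
                pd.DataFrame(roc_points, columns=["fpr", "tpr"]), out / "roc_points.csv"
            )
            groups = quadrant_risk_groups(rm.scores, distances)
            write_table(
                pd.DataFrame(
                    {
                        "patient_id": list(groups.assignments),
                        "risk_group": list(groups.assignments.values()),
                        "score": [rm.scores[p] for p in groups.assignments],
                        "distance": [distances[p] for p in groups.assignments],
                    }
                ),
                out / "risk_groups.csv",
            )
            fisher: dict = {}
            if groups.members("low") and groups.members("high"):
                table, p = fisher_association(groups, labels)
                fisher = {"table": table.tolist(), "p_value": p}
            profiles = {}
            for grp in ("low", "high"):
                members = groups.members(grp)
                if members:
                    profiles[grp] = median_flux_profile(ok, members, model.flux_ids)
            if profiles:
                write_table(
                    pd.DataFrame(profiles).rename_axis("flux").reset_index(),
                    out / "flux_profiles.csv",
                )
            log["risk"] = {
                "median_auc": rm.median_auc,
                "auc_iqr": list(rm.auc_iqr),
                "apparent_auc": auc_all,
                "twilight_band": band,
                "n_retained_after_twilight": int(retained.size),
                "fisher": fisher,
                "group_sizes": {
                    g: len(groups.members(g)) for g in ("low", "intermediate", "high")
                },
            }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"risk stage failed: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return out


def _feature_matrix(twins, cohort, model, use_demographics: bool):
    """Flux features, optionally with age and diabetes duration appended."""
    rec = {r.patient_id: r for r in cohort}
    V = np.vstack([t.v for t in twins])
    ids = list(model.flux_ids)
    if use_demographics:
        ages = [rec[t.patient_id].age for t in twins]
        durs = [rec[t.patient_id].diabetes_duration for t in twins]
        if all(a is not None for a in ages):
            V = np.column_stack([V, ages])
            ids.append("age")
        if all(d is not None for d in durs):
            V = np.column_stack([V, durs])
            ids.append("diabetes_duration")
    return V, ids
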