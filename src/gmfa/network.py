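"""Generalized stoichiometry networks.

A generalized metabolic network mixes ordinary metabolite pools (glucose,
LDL, ferritin, ...) with physiological read-outs (pulse wave velocity,
carotid intima-media thickness, reactive hyperemia index, ...) as nodes of
one stoichiometric system.  Edges are *generalized fluxes*: net conversion
rates, in extent-normalized units, connecting the nodes.  The signed
stoichiometric coefficients form the M x N matrix ``S`` with the usual
flux-analysis convention: substrate entries negative, product entries
positive, so a positive flux value means net conversion substrate -> product.

The module owns representation, validation and (de)serialization; everything
downstream (twin fitting, distances, risk models) is model-agnostic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "NodeSpec",
    "FluxSpec",
    "GeneralizedStoichiometry",
    "ValidationIssue",
    "ValidationReport",
    "NetworkFormatError",
    "NetworkValidationError",
    "load_model",
    "save_model",
    "validate_model",
    "example_diabetes_map",
]

NODE_CLASSES = ("metabolite", "physiological", "source_sink")

#: Default flux bounds, in extent-normalized (z-score state) units, used when
#: a network spec omits them.  Wide enough to be non-binding for plausible
#: cohorts while keeping the quadratic program bounded.
DEFAULT_FLUX_BOUNDS = (-10.0, 10.0)


class NetworkFormatError(ValueError):
    """A network spec file could not be parsed."""


class NetworkValidationError(ValueError):
    """A network spec parsed but violates a structural invariant."""


@dataclass(frozen=True)
class NodeSpec:
    """One node of the generalized network.

    ``reference_mean`` / ``reference_sd`` are the population reference
    statistics (in the node's own unit) used to place heterogeneous units on
    a common z-score state scale.  ``source_sink`` nodes are unobserved
    boundary pools and carry no reference statistics.
    """

    id: str
    label: str = ""
    node_class: str = "metabolite"
    unit: str = ""
    reference_mean: float | None = None
    reference_sd: float | None = None

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", self.id)

    @property
    def has_reference(self) -> bool:
        return self.reference_mean is not None and self.reference_sd is not None


@dataclass(frozen=True)
class FluxSpec:
    """One generalized flux: substrates -> products with positive coefficients."""

    id: str
    substrates: tuple[tuple[str, float], ...] = ()
    products: tuple[tuple[str, float], ...] = ()
    lower_bound: float = DEFAULT_FLUX_BOUNDS[0]
    upper_bound: float = DEFAULT_FLUX_BOUNDS[1]
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "substrates", tuple((str(n), float(c)) for n, c in self.substrates)
        )
        object.__setattr__(
            self, "products", tuple((str(n), float(c)) for n, c in self.products)
        )

    def participant_ids(self) -> list[str]:
        return [n for n, _ in self.substrates] + [n for n, _ in self.products]


@dataclass(frozen=True)
class ValidationIssue:
    kind: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.message}"


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:
        return self.ok

    def kinds(self) -> list[str]:
        return [i.kind for i in self.issues]


@dataclass(frozen=True)
class GeneralizedStoichiometry:
    """An ordered node list, an ordered flux list, and the signed matrix S.

    ``S`` is assembled from the flux specs and is time-independent; column j
    is exactly the signed coefficient pattern of flux j.
    """

    nodes: tuple[NodeSpec, ...]
    fluxes: tuple[FluxSpec, ...]
    S: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "fluxes", tuple(self.fluxes))
        if self.S is None:
            object.__setattr__(self, "S", _assemble_matrix(self.nodes, self.fluxes))
        arr = np.asarray(self.S, dtype=float)
        arr.setflags(write=False)
        object.__setattr__(self, "S", arr)

    # -- shape ------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_fluxes(self) -> int:
        return len(self.fluxes)

    # -- lookups ----------------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    @property
    def flux_ids(self) -> list[str]:
        return [f.id for f in self.fluxes]

    def node_index(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(f"unknown node id: {node_id!r}") from None

    def flux_index(self, flux_id: str) -> int:
        try:
            return self.flux_ids.index(flux_id)
        except ValueError:
            raise KeyError(f"unknown flux id: {flux_id!r}") from None

    def node(self, node_id: str) -> NodeSpec:
        return self.nodes[self.node_index(node_id)]

    def flux(self, flux_id: str) -> FluxSpec:
        return self.fluxes[self.flux_index(flux_id)]

    def flux_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([f.lower_bound for f in self.fluxes])
        ub = np.array([f.upper_bound for f in self.fluxes])
        return lb, ub

    def reference_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-node (mean, sd) on the raw scale; source/sink nodes map to (0, 1).

        The (0, 1) convention makes the z-score state of an unobserved
        boundary pool equal to its raw state, which is only ever touched
        through S.
        """
        mean = np.array(
            [n.reference_mean if n.has_reference else 0.0 for n in self.nodes]
        )
        sd = np.array(
            [n.reference_sd if n.has_reference else 1.0 for n in self.nodes]
        )
        return mean, sd


def _assemble_matrix(
    nodes: Sequence[NodeSpec], fluxes: Sequence[FluxSpec]
) -> np.ndarray:
    index = {n.id: i for i, n in enumerate(nodes)}
    S = np.zeros((len(nodes), len(fluxes)))
    for j, flux in enumerate(fluxes):
        for node_id, coef in flux.substrates:
            if node_id in index:
                S[index[node_id], j] -= coef
        for node_id, coef in flux.products:
            if node_id in index:
                S[index[node_id], j] += coef
    return S


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_model(model: GeneralizedStoichiometry) -> ValidationReport:
    """Check every structural invariant; never raises, always reports."""
    issues: list[ValidationIssue] = []

    seen: set[str] = set()
    for node in model.nodes:
        if node.id in seen:
            issues.append(
                ValidationIssue("duplicate_id", f"node id {node.id!r} appears twice")
            )
        seen.add(node.id)
        if node.node_class not in NODE_CLASSES:
            issues.append(
                ValidationIssue(
                    "node_class",
                    f"node {node.id!r} has unknown class {node.node_class!r}",
                )
            )
        if node.node_class == "source_sink":
            if node.reference_mean is not None or node.reference_sd is not None:
                issues.append(
                    ValidationIssue(
                        "reference_stats",
                        f"source/sink node {node.id!r} carries reference statistics",
                    )
                )
        elif node.has_reference and not node.reference_sd > 0:
            issues.append(
                ValidationIssue(
                    "reference_stats",
                    f"node {node.id!r} has non-positive reference_sd",
                )
            )

    node_ids = set(model.node_ids)
    seen_flux: set[str] = set()
    for j, flux in enumerate(model.fluxes):
        if flux.id in seen_flux:
            issues.append(
                ValidationIssue("duplicate_id", f"flux id {flux.id!r} appears twice")
            )
        seen_flux.add(flux.id)
        if not flux.substrates and not flux.products:
            issues.append(
                ValidationIssue("empty_flux", f"flux {flux.id!r} has no participants")
            )
        dangling = [n for n in flux.participant_ids() if n not in node_ids]
        if dangling:
            issues.append(
                ValidationIssue(
                    "dangling_reference",
                    f"flux {flux.id!r} references unknown node(s): "
                    + ", ".join(sorted(set(dangling))),
                )
            )
        for name, coef in list(flux.substrates) + list(flux.products):
            if not coef > 0:
                issues.append(
                    ValidationIssue(
                        "coefficient",
                        f"flux {flux.id!r} has non-positive coefficient for {name!r}",
                    )
                )
        if flux.lower_bound > flux.upper_bound:
            issues.append(
                ValidationIssue("bounds", f"flux {flux.id!r} has lower_bound > upper_bound")
            )
        if not dangling and model.S.shape[0] and not np.any(model.S[:, j]):
            issues.append(
                ValidationIssue(
                    "zero_column",
                    f"flux {flux.id!r} has an all-zero stoichiometry column",
                )
            )

    for val, what in ((model.S.shape, (model.n_nodes, model.n_fluxes)),):
        if val != what:
            issues.append(
                ValidationIssue("shape", f"S has shape {val}, expected {what}")
            )

    return ValidationReport(tuple(issues))


def _require_valid(model: GeneralizedStoichiometry) -> GeneralizedStoichiometry:
    report = validate_model(model)
    if not report.ok:
        raise NetworkValidationError(
            "invalid network model:\n" + "\n".join(str(i) for i in report.issues)
        )
    return model


# ---------------------------------------------------------------------------
# serialization: JSON dialect and two-file TSV dialect
# ---------------------------------------------------------------------------


def _node_to_dict(n: NodeSpec) -> dict:
    d: dict = {"id": n.id, "label": n.label, "node_class": n.node_class, "unit": n.unit}
    if n.reference_mean is not None:
        d["reference_mean"] = n.reference_mean
    if n.reference_sd is not None:
        d["reference_sd"] = n.reference_sd
    return d


def _flux_to_dict(f: FluxSpec) -> dict:
    return {
        "id": f.id,
        "substrates": [[n, c] for n, c in f.substrates],
        "products": [[n, c] for n, c in f.products],
        "lower_bound": f.lower_bound,
        "upper_bound": f.upper_bound,
        "source": f.source,
    }


def _node_from_dict(d: dict, where: str) -> NodeSpec:
    try:
        return NodeSpec(
            id=str(d["id"]),
            label=str(d.get("label", "") or d["id"]),
            node_class=str(d.get("node_class", "metabolite")),
            unit=str(d.get("unit", "")),
            reference_mean=_opt_float(d.get("reference_mean"), where, "reference_mean"),
            reference_sd=_opt_float(d.get("reference_sd"), where, "reference_sd"),
        )
    except KeyError as exc:
        raise NetworkFormatError(f"{where}: missing field {exc}") from None


def _opt_float(value, where: str, fieldname: str) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise NetworkFormatError(
            f"{where}: field {fieldname!r} is not numeric: {value!r}"
        ) from None


def _flux_from_dict(d: dict, where: str) -> FluxSpec:
    try:
        subs = tuple((str(n), float(c)) for n, c in d.get("substrates", []))
        prods = tuple((str(n), float(c)) for n, c in d.get("products", []))
    except (TypeError, ValueError):
        raise NetworkFormatError(
            f"{where}: substrates/products must be [node, coefficient] pairs"
        ) from None
    try:
        return FluxSpec(
            id=str(d["id"]),
            substrates=subs,
            products=prods,
            lower_bound=float(d.get("lower_bound", DEFAULT_FLUX_BOUNDS[0])),
            upper_bound=float(d.get("upper_bound", DEFAULT_FLUX_BOUNDS[1])),
            source=str(d.get("source", "")),
        )
    except KeyError as exc:
        raise NetworkFormatError(f"{where}: missing field {exc}") from None
    except (TypeError, ValueError) as exc:
        raise NetworkFormatError(f"{where}: {exc}") from None


def load_model(path: str | Path) -> GeneralizedStoichiometry:
    """Load a network spec from JSON, or from a nodes.tsv/fluxes.tsv pair.

    For the TSV dialect, pass either the nodes file or the directory holding
    ``nodes.tsv`` and ``fluxes.tsv``.  Node/flux order is preserved from the
    file; the model is validated before it is returned.
    """
    path = Path(path)
    if path.is_dir():
        return _load_tsv(path / "nodes.tsv", path / "fluxes.tsv")
    if path.suffix.lower() == ".json":
        return _load_json(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        fluxes = path.with_name(path.name.replace("nodes", "fluxes"))
        return _load_tsv(path, fluxes)
    raise NetworkFormatError(f"unrecognized network spec format: {path}")


def _load_json(path: Path) -> GeneralizedStoichiometry:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise NetworkFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}")
    if not isinstance(payload, dict) or "nodes" not in payload or "fluxes" not in payload:
        raise NetworkFormatError(f"{path}: expected an object with 'nodes' and 'fluxes'")
    nodes = tuple(
        _node_from_dict(d, f"{path} nodes[{i}]") for i, d in enumerate(payload["nodes"])
    )
    fluxes = tuple(
        _flux_from_dict(d, f"{path} fluxes[{i}]") for i, d in enumerate(payload["fluxes"])
    )
    return _require_valid(GeneralizedStoichiometry(nodes, fluxes))


_NODE_COLUMNS = ["id", "label", "node_class", "unit", "reference_mean", "reference_sd"]
_FLUX_COLUMNS = ["id", "substrates", "products", "lower_bound", "upper_bound", "source"]


def _parse_side(text: str, where: str) -> tuple[tuple[str, float], ...]:
    text = text.strip()
    if not text:
        return ()
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        node, sep, coef = chunk.rpartition(":")
        if not sep:
            node, coef = chunk, "1"
        try:
            out.append((node.strip(), float(coef)))
        except ValueError:
            raise NetworkFormatError(f"{where}: bad node:coef chunk {chunk!r}") from None
    return tuple(out)


def _read_tsv_rows(path: Path, columns: list[str]) -> list[dict]:
    if not path.exists():
        raise NetworkFormatError(f"network spec file not found: {path}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise NetworkFormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in columns[:1] if c not in header]
    if missing:
        raise NetworkFormatError(f"{path}: header lacks column(s) {missing}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.rstrip("\n").split("\t")
        if len(cells) > len(header):
            raise NetworkFormatError(f"{path}:{lineno}: more cells than header columns")
        row = dict(zip(header, cells))
        row["__where__"] = f"{path}:{lineno}"
        rows.append(row)
    return rows


def _load_tsv(nodes_path: Path, fluxes_path: Path) -> GeneralizedStoichiometry:
    nodes = tuple(
        _node_from_dict(r, r["__where__"]) for r in _read_tsv_rows(nodes_path, _NODE_COLUMNS)
    )
    fluxes = []
    for r in _read_tsv_rows(fluxes_path, _FLUX_COLUMNS):
        where = r["__where__"]
        fluxes.append(
            FluxSpec(
                id=str(r["id"]),
                substrates=_parse_side(r.get("substrates", ""), where),
                products=_parse_side(r.get("products", ""), where),
                lower_bound=float(r.get("lower_bound") or DEFAULT_FLUX_BOUNDS[0]),
                upper_bound=float(r.get("upper_bound") or DEFAULT_FLUX_BOUNDS[1]),
                source=str(r.get("source", "")),
            )
        )
    return _require_valid(GeneralizedStoichiometry(nodes, tuple(fluxes)))


def save_model(model: GeneralizedStoichiometry, path: str | Path) -> Path:
    """Write a model; JSON for ``*.json`` paths, else the two-file TSV dialect."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "nodes": [_node_to_dict(n) for n in model.nodes],
            "fluxes": [_flux_to_dict(f) for f in model.fluxes],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path
    path.mkdir(parents=True, exist_ok=True)
    node_lines = ["\t".join(_NODE_COLUMNS)]
    for n in model.nodes:
        d = _node_to_dict(n)
        node_lines.append("\t".join(str(d.get(c, "")) for c in _NODE_COLUMNS))
    (path / "nodes.tsv").write_text("\n".join(node_lines) + "\n")
    flux_lines = ["\t".join(_FLUX_COLUMNS)]
    for f in model.fluxes:
        flux_lines.append(
            "\t".join(
                [
                    f.id,
                    ";".join(f"{n}:{c:g}" for n, c in f.substrates),
                    ";".join(f"{n}:{c:g}" for n, c in f.products),
                    str(f.lower_bound),
                    str(f.upper_bound),
                    f.source,
                ]
            )
        )
    (path / "fluxes.tsv").write_text("\n".join(flux_lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# packaged example: a coarse-grain type 2 diabetes map
# ---------------------------------------------------------------------------


def example_diabetes_map() -> GeneralizedStoichiometry:
    """Example coarse-grain glucose/lipid/vascular map for type 2 diabetes.

    Nodes cover routine biochemistry (glucose, HbA1c, lipoproteins, ferritin,
    bilirubin, creatinine, haemoglobin, hs-CRP, reactive oxygen metabolites)
    plus vascular physiology embedded as generalized nodes (pulse wave
    velocity, left/right carotid intima-media thickness, reactive hyperemia
    index, systolic blood pressure, BMI).  Reference means/SDs are cohort
    summary statistics typical of a type 2 diabetes population; nodes without
    published summaries carry standard clinical reference values.  Boundary
    pools (Food, Inflammation, Bile) are sources/sinks without reference
    statistics.

    The edge set is an *example* reconstruction wiring every named node into
    the glucose, lipid, iron/oxidation, heme-catabolism and vascular arms;
    stoichiometric coefficients for physiological couplings default to 1.
    All downstream code is model-agnostic, so users can load their own map.
    """

    def met(id, label, unit, mean, sd):
        return NodeSpec(id, label, "metabolite", unit, mean, sd)

    def phys(id, label, unit, mean, sd):
        return NodeSpec(id, label, "physiological", unit, mean, sd)

    def pool(id, label):
        return NodeSpec(id, label, "source_sink")

    nodes = (
        pool("Food", "Dietary intake"),
        met("Protein", "Serum total protein", "g/L", 70.0, 5.0),
        phys("Urine-pH", "Urine pH", "pH", 6.0, 0.7),
        met("HDL", "HDL cholesterol", "mmol/L", 1.12, 0.30),
        met("VLDL", "VLDL cholesterol", "mmol/L", 0.84, 0.40),
        met("LDL", "LDL cholesterol", "mmol/L", 2.51, 0.84),
        met("ox-LDL", "Oxidized LDL", "IU/L", 55.92, 21.65),
        met("Ferritin", "Serum ferritin", "ug/L", 109.48, 123.43),
        pool("Inflammation", "Inflammatory drive"),
        met("Bilirubin", "Total bilirubin", "umol/L", 10.0, 5.0),
        pool("Bile", "Biliary excretion"),
        phys("RHI", "Reactive hyperemia index (ln)", "lnRHI", 0.67, 0.25),
        phys("CIMT-avg-L", "Carotid intima-media thickness, left", "mm", 0.65, 0.13),
        phys("CIMT-avg-R", "Carotid intima-media thickness, right", "mm", 0.65, 0.13),
        phys("Pulse-wave-velocity", "Pulse wave velocity", "m/s", 8.35, 1.74),
        met("HbA1c", "Glycated haemoglobin", "%", 8.60, 1.84),
        met("ROM", "Reactive oxygen metabolites", "U.CARR", 271.0, 53.0),
        met("hs-CRP", "High-sensitivity C-reactive protein", "mg/L", 1.45, 2.30),
        met("Glucose", "Fasting glucose", "mmol/L", 8.89, 3.18),
        met("Triglycerides", "Triglycerides", "mmol/L", 1.85, 2.17),
        met("Creatinine", "Serum creatinine", "umol/L", 74.2, 26.85),
        met("Haemoglobin", "Haemoglobin", "g/dL", 14.0, 1.5),
        phys("Systolic-BP", "Systolic blood pressure", "mm Hg", 133.2, 14.78),
        phys("BMI", "Body mass index", "kg/m^2", 27.7, 4.99),
    )

    def flux(id, subs, prods, source):
        return FluxSpec(
            id,
            substrates=tuple(subs),
            products=tuple(prods),
            lower_bound=DEFAULT_FLUX_BOUNDS[0],
            upper_bound=DEFAULT_FLUX_BOUNDS[1],
            source=source,
        )

    fluxes = (
        flux("food_protein", [("Food", 1)], [("Protein", 1)], "dietary protein intake"),
        flux(
            "protein_urine_ph",
            [("Protein", 1)],
            [("Urine-pH", 1)],
            "protein catabolism acidifies urine; coupling coefficient 1",
        ),
        flux("food_glucose", [("Food", 1)], [("Glucose", 1)], "carbohydrate intake"),
        flux("food_bmi", [("Food", 1)], [("BMI", 1)], "caloric balance"),
        flux("food_hdl", [("Food", 1)], [("HDL", 1)], "hepatic HDL output"),
        flux("food_vldl", [("Food", 1)], [("VLDL", 1)], "hepatic VLDL output"),
        flux(
            "hdl_vldl_ldl",
            [("HDL", 1), ("VLDL", 1)],
            [("LDL", 1)],
            "hepatic lipoprotein remodeling",
        ),
        flux("ldl_oxldl", [("LDL", 1)], [("ox-LDL", 1)], "LDL oxidation"),
        flux(
            "ferritin_oxldl",
            [("Ferritin", 1)],
            [("ox-LDL", 1)],
            "iron-catalyzed LDL oxidation",
        ),
        flux(
            "inflammation_ferritin",
            [("Inflammation", 1)],
            [("Ferritin", 1)],
            "acute-phase ferritin induction",
        ),
        flux(
            "inflammation_hscrp",
            [("Inflammation", 1)],
            [("hs-CRP", 1)],
            "acute-phase CRP induction",
        ),
        flux(
            "glucose_rom",
            [("Glucose", 1)],
            [("ROM", 1)],
            "hyperglycemic oxidative stress",
        ),
        flux(
            "glucose_triglycerides",
            [("Glucose", 1)],
            [("Triglycerides", 1)],
            "de novo lipogenesis",
        ),
        flux("rom_hba1c", [("ROM", 1)], [("HbA1c", 1)], "oxidative glycation drive"),
        flux(
            "glucose_hba1c",
            [("Glucose", 1)],
            [("HbA1c", 1)],
            "non-enzymatic haemoglobin glycation",
        ),
        flux(
            "haemoglobin_hba1c",
            [("Haemoglobin", 1)],
            [("HbA1c", 1)],
            "glycatable haemoglobin pool",
        ),
        flux(
            "haemoglobin_bilirubin",
            [("Haemoglobin", 1)],
            [("Bilirubin", 1)],
            "heme catabolism",
        ),
        flux("bilirubin_bile", [("Bilirubin", 1)], [("Bile", 1)], "biliary excretion"),
        flux(
            "protein_creatinine",
            [("Protein", 1)],
            [("Creatinine", 1)],
            "muscle protein turnover",
        ),
        flux(
            "oxldl_pwv",
            [("ox-LDL", 1)],
            [("Pulse-wave-velocity", 1)],
            "ox-LDL-driven arterial stiffening; coupling coefficient 1",
        ),
        flux(
            "pwv_sbp",
            [("Pulse-wave-velocity", 1)],
            [("Systolic-BP", 1)],
            "stiffness raises systolic pressure",
        ),
        flux(
            "rhi_cimt_l",
            [("RHI", 1)],
            [("CIMT-avg-L", 1)],
            "endothelial dysfunction to left carotid wall thickening",
        ),
        flux(
            "rhi_cimt_r",
            [("RHI", 1)],
            [("CIMT-avg-R", 1)],
            "endothelial dysfunction to right carotid wall thickening",
        ),
        flux(
            "bmi_sbp",
            [("BMI", 1)],
            [("Systolic-BP", 1)],
            "adiposity raises blood pressure",
        ),
    )

    return _require_valid(GeneralizedStoichiometry(nodes, fluxes))


def with_flux_bounds(
    model: GeneralizedStoichiometry, lower: float, upper: float
) -> GeneralizedStoichiometry:
    """Return a copy of the model with uniform flux bounds (testing helper)."""
    fluxes = tuple(replace(f, lower_bound=lower, upper_bound=upper) for f in model.fluxes)
    return GeneralizedStoichiometry(model.nodes, fluxes)
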