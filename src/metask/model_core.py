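"""Domain types for metabolic models and tasks, plus format readers/writers.

A :class:`MetabolicModel` is a stoichiometric network — metabolites with
compartments, bounded reactions with gene-protein-reaction rules, and
the gene set those rules reference.  A :class:`TaskDefinition` describes
a metabolic function operationally: which substrate metabolites may be
taken up (and in what quantity) and which product metabolites must be
produced at a minimum rate.

Supported model formats: SBML Level 3 + FBC (read/written through
cobrapy) and a BiGG-compatible JSON dialect parsed directly.  Tasks
travel as CSV (one row per metabolite, grouped by ``task_id``) or as an
equivalent JSON document with explicit input/output arrays.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .gpr import GPRParseError, GPRRule, format_gpr, gpr_genes, parse_gpr

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "TaskMetabolite",
    "TaskDefinition",
    "TaskEssentialSet",
    "ModelValidationError",
    "TaskSchemaError",
    "read_model",
    "write_model",
    "read_task_list",
    "write_task_list",
    "read_task_essential_sets",
    "write_task_essential_sets",
    "load_curated_tasks",
    "resolve_metabolite",
]

TASK_CSV_COLUMNS = [
    "task_id",
    "description",
    "system",
    "subsystem",
    "in_metabolite",
    "in_compartment",
    "in_lb",
    "in_ub",
    "out_metabolite",
    "out_compartment",
    "out_lb",
    "out_ub",
]

SYSTEMS = (
    "energy",
    "nucleotide",
    "carbohydrates",
    "amino acid",
    "lipid",
    "vitamin & cofactor",
    "glycan",
)


class ModelValidationError(ValueError):
    """A model violates a structural invariant (duplicate ids, dangling refs)."""


class TaskSchemaError(ValueError):
    """A task table violates the canonical schema."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = ""
    name: str = ""


@dataclass
class Reaction:
    """A bounded reaction: stoichiometry maps metabolite id -> signed coefficient."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: Optional[GPRRule] = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_boundary(self) -> bool:
        """Single-metabolite reactions exchange mass with the environment."""
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr)

    @property
    def gpr_text(self) -> str:
        return format_gpr(self.gpr)


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        dup = [m for m, c in Counter(met_ids).items() if c > 1]
        if dup:
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        dup = [r for r, c in Counter(rxn_ids).items() if c > 1]
        if dup:
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolites: "
                    f"{sorted(missing)}"
                )
        gpr_gene_union = frozenset().union(*(r.genes for r in self.reactions)) if self.reactions else frozenset()
        if not self.genes:
            self.genes = gpr_gene_union
        elif not gpr_gene_union <= self.genes:
            raise ModelValidationError(
                f"GPR genes absent from model gene list: {sorted(gpr_gene_union - self.genes)}"
            )

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)


@dataclass(frozen=True)
class TaskMetabolite:
    """One task substrate or product with its flux bounds.

    For inputs, bounds are non-negative maximum-uptake magnitudes; for
    outputs, a strictly positive ``lower_bound`` on at least one product
    states the required production.
    """

    metabolite: str
    compartment: str = ""
    lower_bound: float = 0.0
    upper_bound: float = 1000.0


@dataclass
class TaskDefinition:
    id: str
    description: str = ""
    system: str = ""
    subsystem: str = ""
    inputs: list[TaskMetabolite] = field(default_factory=list)
    outputs: list[TaskMetabolite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(o.lower_bound > 0 for o in self.outputs):
            raise TaskSchemaError(
                f"task {self.id!r}: requires at least one output with a "
                "strictly positive production lower bound"
            )
        for inp in self.inputs:
            if inp.lower_bound < 0 or inp.upper_bound < 0:
                raise TaskSchemaError(
                    f"task {self.id!r}: uptake bounds are magnitudes and must "
                    f"be non-negative (got {inp})"
                )
        for tm in list(self.inputs) + list(self.outputs):
            if tm.lower_bound > tm.upper_bound:
                raise TaskSchemaError(
                    f"task {self.id!r}: lower bound exceeds upper bound for "
                    f"{tm.metabolite}"
                )


@dataclass
class TaskEssentialSet:
    """Minimal reaction set (pFBA support) and its genes for one task."""

    task_id: str
    feasible: bool
    reactions: list[str] = field(default_factory=list)
    genes: frozenset[str] = field(default_factory=frozenset)
    flux_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.feasible and (self.reactions or self.genes):
            raise ValueError(
                f"task {self.task_id!r}: infeasible set must have empty "
                "reactions and genes"
            )


# ---------------------------------------------------------------------------
# metabolite namespace resolution


def _strip_compartment(met_id: str) -> str:
    """Strip a trailing compartment tag: 'glc_D_c' -> 'glc_D', 'atp[c]' -> 'atp'."""
    if met_id.endswith("]") and "[" in met_id:
        return met_id[: met_id.rindex("[")]
    if "_" in met_id:
        head, _, tail = met_id.rpartition("_")
        if len(tail) <= 2 and tail.isalnum():
            return head
    return met_id


def resolve_metabolite(
    model: MetabolicModel,
    met_id: str,
    compartment: str = "",
    mapping: Optional[Mapping[str, str]] = None,
) -> Optional[str]:
    """Find the model metabolite matching a task metabolite reference.

    Tries, in order: a user alias map, the exact id, common id+compartment
    spellings (``id_c``, ``id[c]``), and finally a compartment-stripped
    match.  Returns the model metabolite id, or ``None``.
    """
    if mapping and met_id in mapping:
        met_id = mapping[met_id]
    ids = set(model.metabolite_ids)
    if met_id in ids:
        return met_id
    if compartment:
        for candidate in (f"{met_id}_{compartment}", f"{met_id}[{compartment}]"):
            if candidate in ids:
                return candidate
    stripped = {_strip_compartment(m.id): m.id for m in model.metabolites}
    if met_id in stripped:
        resolved = stripped[met_id]
        if not compartment:
            return resolved
        comp = next(m.compartment for m in model.metabolites if m.id == resolved)
        if comp == compartment:
            return resolved
    return None


# ---------------------------------------------------------------------------
# model I/O


def read_model(path: str | Path, format: Optional[str] = None) -> MetabolicModel:
    """Read a genome-scale model from SBML (L3+FBC) or BiGG-style JSON.

    Unparseable GPR strings are reported via warnings and treated as
    empty associations.
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        return _read_json_model(path)
    if format == "sbml":
        return _read_sbml_model(path)
    raise ValueError(f"unknown model format {format!r}")


def _parse_gpr_safe(text: str, rxn_id: str) -> Optional[GPRRule]:
    try:
        return parse_gpr(text)
    except GPRParseError as exc:
        warnings.warn(f"reaction {rxn_id!r}: unparseable GPR {text!r}: {exc}")
        return None


def _read_json_model(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"{path}: not valid JSON: {exc}") from exc
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelValidationError(f"{path}: missing top-level key {key!r}")
    metabolites = [
        Metabolite(
            id=m["id"],
            compartment=m.get("compartment", ""),
            name=m.get("name", ""),
        )
        for m in doc["metabolites"]
    ]
    reactions = []
    for r in doc["reactions"]:
        reactions.append(
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", -1000.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                gpr=_parse_gpr_safe(r.get("gene_reaction_rule", ""), r["id"]),
                name=r.get("name", ""),
            )
        )
    genes = frozenset(
        g["id"] if isinstance(g, dict) else str(g) for g in doc.get("genes", [])
    )
    return MetabolicModel(
        id=doc.get("id", path.stem),
        metabolites=metabolites,
        reactions=reactions,
        genes=genes or frozenset(),
    )


def _read_sbml_model(path: Path) -> MetabolicModel:
    import cobra.io

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cm = cobra.io.read_sbml_model(str(path))
    metabolites = [
        Metabolite(id=m.id, compartment=m.compartment or "", name=m.name or "")
        for m in cm.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: coeff for m, coeff in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gpr=_parse_gpr_safe(r.gene_reaction_rule, r.id),
            name=r.name or "",
        )
        for r in cm.reactions
    ]
    return MetabolicModel(
        id=cm.id or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        genes=frozenset(g.id for g in cm.genes),
    )


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model in the BiGG-compatible JSON dialect (canonically ordered)."""
    doc = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "compartment": m.compartment, "name": m.name}
            for m in sorted(model.metabolites, key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr_text,
            }
            for r in sorted(model.reactions, key=lambda r: r.id)
        ],
        "genes": [{"id": g} for g in sorted(model.genes)],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# task I/O


def _tasks_from_dataframe(df: pd.DataFrame, source: str) -> list[TaskDefinition]:
    unknown = [c for c in df.columns if c not in TASK_CSV_COLUMNS]
    if unknown:
        warnings.warn(f"{source}: ignoring unknown columns {unknown}")
        df = df.drop(columns=unknown)
    if "task_id" not in df.columns:
        raise TaskSchemaError(f"{source}: missing required column 'task_id'")
    tasks = []
    for task_id, group in df.groupby("task_id", sort=False):
        inputs, outputs = [], []
        first = group.iloc[0]
        for _, row in group.iterrows():
            if _present(row.get("in_metabolite")):
                inputs.append(
                    TaskMetabolite(
                        metabolite=str(row["in_metabolite"]),
                        compartment=_text(row.get("in_compartment")),
                        lower_bound=_num(row.get("in_lb"), 0.0),
                        upper_bound=_num(row.get("in_ub"), 1000.0),
                    )
                )
            if _present(row.get("out_metabolite")):
                outputs.append(
                    TaskMetabolite(
                        metabolite=str(row["out_metabolite"]),
                        compartment=_text(row.get("out_compartment")),
                        lower_bound=_num(row.get("out_lb"), 0.0),
                        upper_bound=_num(row.get("out_ub"), 1000.0),
                    )
                )
        tasks.append(
            TaskDefinition(
                id=str(task_id),
                description=_text(first.get("description")),
                system=_text(first.get("system")),
                subsystem=_text(first.get("subsystem")),
                inputs=inputs,
                outputs=outputs,
            )
        )
    per_system = Counter(t.system for t in tasks)
    logger.info(
        "read %d tasks from %s (%s)",
        len(tasks),
        source,
        ", ".join(f"{s}: {n}" for s, n in sorted(per_system.items())),
    )
    return tasks


def _present(value) -> bool:
    return value is not None and not pd.isna(value) and str(value).strip() != ""


def _text(value) -> str:
    return str(value) if _present(value) else ""


def _num(value, default: float) -> float:
    return float(value) if _present(value) else default


def read_task_list(path: str | Path) -> list[TaskDefinition]:
    """Read task definitions from canonical CSV/TSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        return [
            TaskDefinition(
                id=t["id"],
                description=t.get("description", ""),
                system=t.get("system", ""),
                subsystem=t.get("subsystem", ""),
                inputs=[TaskMetabolite(**i) for i in t.get("inputs", [])],
                outputs=[TaskMetabolite(**o) for o in t.get("outputs", [])],
            )
            for t in doc["tasks"]
        ]
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    return _tasks_from_dataframe(df, str(path))


def write_task_list(tasks: Sequence[TaskDefinition], path: str | Path) -> None:
    """Write tasks as canonical CSV (one row per metabolite, task-grouped)."""
    rows = []
    for task in tasks:
        n = max(len(task.inputs), len(task.outputs), 1)
        for i in range(n):
            row = {c: "" for c in TASK_CSV_COLUMNS}
            row["task_id"] = task.id
            if i == 0:
                row["description"] = task.description
                row["system"] = task.system
                row["subsystem"] = task.subsystem
            if i < len(task.inputs):
                inp = task.inputs[i]
                row.update(
                    in_metabolite=inp.metabolite,
                    in_compartment=inp.compartment,
                    in_lb=inp.lower_bound,
                    in_ub=inp.upper_bound,
                )
            if i < len(task.outputs):
                out = task.outputs[i]
                row.update(
                    out_metabolite=out.metabolite,
                    out_compartment=out.compartment,
                    out_lb=out.lower_bound,
                    out_ub=out.upper_bound,
                )
            rows.append(row)
    pd.DataFrame(rows, columns=TASK_CSV_COLUMNS).to_csv(path, index=False)


def load_curated_tasks() -> list[TaskDefinition]:
    """Load the packaged task collection.

    The packaged table is a *synthetic* stand-in instance of the
    canonical 195-task/7-system collection layout: it reproduces the
    schema, the task count and the system structure with synthetic
    metabolite content, so format handling and counting logic can be
    exercised without external downloads.
    """
    path = Path(__file__).parent / "data" / "curated_tasks_synthetic.csv"
    return read_task_list(path)


# ---------------------------------------------------------------------------
# essential-set artifact


def write_task_essential_sets(
    sets: Sequence[TaskEssentialSet], path: str | Path
) -> None:
    """Write essential sets as a canonical, byte-stable JSON artifact."""
    if not sets:
        raise ValueError("no essential sets to write")
    doc = {
        "task_essential_sets": [
            {
                "task_id": s.task_id,
                "feasible": s.feasible,
                "reactions": sorted(s.reactions),
                "genes": sorted(s.genes),
                "flux_values": {k: s.flux_values[k] for k in sorted(s.flux_values)},
            }
            for s in sorted(sets, key=lambda s: s.task_id)
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_task_essential_sets(path: str | Path) -> list[TaskEssentialSet]:
    doc = json.loads(Path(path).read_text())
    return [
        TaskEssentialSet(
            task_id=s["task_id"],
            feasible=s["feasible"],
            reactions=list(s["reactions"]),
            genes=frozenset(s["genes"]),
            flux_values=dict(s["flux_values"]),
        )
        for s in doc["task_essential_sets"]
    ]
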