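"""Synthetic models, tasks and expression data with known ground truth.

Every generator is deterministic given its seed and writes/returns the
same formats the real pipeline consumes, so fixtures double as format
conformance checks.  The toy models are collections of disjoint linear
pathways (optionally with a longer decoy bypass per pathway), each
paired with a task "convert the pathway input into its end product";
the minimal route per task is therefore known by construction and can
be compared against the pFBA extraction.  Expression matrices plant
binary task activity by scaling *all* genes of a task's essential set
above (active) or below (inactive) their expected thresholds, so that
min-based AND rules respond unambiguously.

The baseline expression is log-normal around a common scale — a
reasonable shape for RNA abundance, with no claim of platform realism
(no dropout, no batch structure, no gene-length effects).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gpr import parse_gpr
from .model_core import (
    Metabolite,
    MetabolicModel,
    Reaction,
    TaskDefinition,
    TaskMetabolite,
)
from .scoring import ExpressionDataset

__all__ = [
    "FixtureSpec",
    "make_toy_model",
    "make_expression",
    "make_synthetic_task_table",
    "SYNTHETIC_SYSTEM_COUNTS",
]


@dataclass
class FixtureSpec:
    """Parameters for the synthetic-data generators.

    ``activity_effect`` is the fold-change applied to a task's genes in
    samples where it is planted active; planted-inactive samples use
    ``inactive_effect`` (default the reciprocal).  ``noise_sd`` is the
    standard deviation of the log-normal baseline on the natural-log
    scale.
    """

    n_pathways: int = 3
    pathway_length: int = 3
    gpr_complexity: str = "isozyme"  # single | isozyme | complex | nested
    n_samples: int = 200
    active_tasks: Optional[Sequence[str]] = None
    activity_effect: float = 4.0
    inactive_effect: Optional[float] = None
    active_probability: float = 0.5
    noise_sd: float = 0.1
    base_scale: float = 10.0
    decoy_routes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gpr_complexity not in ("single", "isozyme", "complex", "nested"):
            raise ValueError(f"unknown gpr_complexity {self.gpr_complexity!r}")
        if self.n_pathways < 1 or self.pathway_length < 1 or self.n_samples < 1:
            raise ValueError("n_pathways, pathway_length, n_samples must be >= 1")
        if self.inactive_effect is None:
            self.inactive_effect = 1.0 / self.activity_effect


def _gpr_for(spec: FixtureSpec, pathway: int, step: int) -> str:
    stem = f"G{pathway}_{step}"
    return {
        "single": stem,
        "isozyme": f"{stem}a or {stem}b",
        "complex": f"{stem}a and {stem}b",
        "nested": f"({stem}a and {stem}b) or {stem}c",
    }[spec.gpr_complexity]


def make_toy_model(
    spec: FixtureSpec,
) -> tuple[MetabolicModel, list[TaskDefinition], dict[str, list[str]]]:
    """Build a toy model of disjoint pathways plus one task per pathway.

    Returns ``(model, tasks, truth_sets)`` where ``truth_sets`` maps
    each task id to its known minimal reaction route.  With
    ``decoy_routes`` every pathway also gets a strictly longer bypass
    from input to product, so parsimonious extraction must prefer the
    direct chain.
    """
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    tasks: list[TaskDefinition] = []
    truth_sets: dict[str, list[str]] = {}
    L = spec.pathway_length
    for p in range(1, spec.n_pathways + 1):
        mets = [f"M{p}_{j}" for j in range(L + 1)]
        metabolites.extend(Metabolite(m, compartment="c") for m in mets)
        chain = []
        for j in range(1, L + 1):
            rxn_id = f"R{p}_{j}"
            reactions.append(
                Reaction(
                    id=rxn_id,
                    stoichiometry={mets[j - 1]: -1.0, mets[j]: 1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    gpr=parse_gpr(_gpr_for(spec, p, j)),
                )
            )
            chain.append(rxn_id)
        # boundary exchanges for the pathway endpoints
        reactions.append(
            Reaction(
                id=f"EX_{mets[0]}",
                stoichiometry={mets[0]: -1.0},
                lower_bound=-1000.0,
                upper_bound=1000.0,
            )
        )
        reactions.append(
            Reaction(
                id=f"EX_{mets[-1]}",
                stoichiometry={mets[-1]: -1.0},
                lower_bound=-1000.0,
                upper_bound=1000.0,
            )
        )
        if spec.decoy_routes:
            # bypass of length L+1: strictly more total flux than the chain
            decoy_mets = [mets[0]] + [f"D{p}_{k}" for k in range(1, L + 1)] + [mets[-1]]
            metabolites.extend(
                Metabolite(m, compartment="c") for m in decoy_mets[1:-1]
            )
            for k in range(1, L + 2):
                reactions.append(
                    Reaction(
                        id=f"B{p}_{k}",
                        stoichiometry={
                            decoy_mets[k - 1]: -1.0,
                            decoy_mets[k]: 1.0,
                        },
                        lower_bound=0.0,
                        upper_bound=1000.0,
                        gpr=parse_gpr(f"H{p}_{k}"),
                    )
                )
        task_id = f"T{p}"
        tasks.append(
            TaskDefinition(
                id=task_id,
                description=f"convert {mets[0]} to {mets[-1]}",
                system="synthetic",
                inputs=[TaskMetabolite(mets[0], "c", 0.0, 10.0)],
                outputs=[TaskMetabolite(mets[-1], "c", 1.0, 10.0)],
            )
        )
        truth_sets[task_id] = chain
    model = MetabolicModel(
        id=f"toy_{spec.n_pathways}x{L}", metabolites=metabolites, reactions=reactions
    )
    return model, tasks, truth_sets


def make_expression(
    spec: FixtureSpec,
    model: MetabolicModel,
    tasks: Sequence[TaskDefinition],
    truth_sets: dict[str, list[str]],
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Expression matrix with planted task activity, plus the truth matrix.

    For each task in ``active_tasks`` (default: all), each sample is
    independently planted active with probability ``active_probability``;
    all genes of the task's minimal route are scaled by
    ``activity_effect`` (active) or ``inactive_effect`` (inactive) on
    top of the log-normal baseline.  Returns the expression dataset and
    the boolean task-by-sample ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    genes = sorted(model.genes)
    samples = [f"S{i+1}" for i in range(spec.n_samples)]
    log_noise = rng.normal(0.0, spec.noise_sd, size=(len(genes), len(samples)))
    values = spec.base_scale * np.exp(log_noise)
    expr = pd.DataFrame(values, index=genes, columns=samples)

    task_ids = [t.id for t in tasks]
    plantable = list(spec.active_tasks) if spec.active_tasks is not None else task_ids
    truth = pd.DataFrame(False, index=task_ids, columns=samples)
    gene_index = {g: i for i, g in enumerate(genes)}
    for task in tasks:
        task_genes = sorted(
            {
                g
                for rxn_id in truth_sets[task.id]
                for g in model.reaction(rxn_id).genes
            }
        )
        rows = [gene_index[g] for g in task_genes]
        if task.id in plantable:
            active = rng.random(len(samples)) < spec.active_probability
        else:
            active = np.zeros(len(samples), dtype=bool)
        truth.loc[task.id] = active
        factors = np.where(active, spec.activity_effect, spec.inactive_effect)
        expr.iloc[rows] = expr.iloc[rows].to_numpy() * factors[np.newaxis, :]
    return ExpressionDataset(expr), truth


# ---------------------------------------------------------------------------
# synthetic stand-in for the curated task collection

#: Seven metabolic systems with synthetic per-system task counts (sum 195).
SYNTHETIC_SYSTEM_COUNTS = {
    "energy": 21,
    "nucleotide": 25,
    "carbohydrates": 26,
    "amino acid": 38,
    "lipid": 44,
    "vitamin & cofactor": 28,
    "glycan": 13,
}


def make_synthetic_task_table(seed: int = 0) -> list[TaskDefinition]:
    """Deterministic synthetic instance of the curated task-collection layout.

    Reproduces the canonical schema and structure of the curated
    collection — 195 tasks over the seven metabolic systems — with
    synthetic metabolite content.  It is a stand-in for exercising the
    reader, counters and batch plumbing, not a biological resource.
    """
    rng = np.random.default_rng(seed)
    vocabulary = [f"met{i:03d}" for i in range(120)]
    tasks: list[TaskDefinition] = []
    counter = 0
    for system, count in SYNTHETIC_SYSTEM_COUNTS.items():
        stem = system.replace(" & ", "_").replace(" ", "_")
        for k in range(count):
            counter += 1
            n_in = int(rng.integers(1, 4))
            n_out = int(rng.integers(1, 3))
            mets = rng.choice(len(vocabulary), size=n_in + n_out, replace=False)
            inputs = [
                TaskMetabolite(vocabulary[m], "c", 0.0, float(rng.integers(1, 20)))
                for m in mets[:n_in]
            ]
            outputs = [
                TaskMetabolite(vocabulary[m], "c", 1.0, float(rng.integers(1, 20)))
                for m in mets[n_in:]
            ]
            tasks.append(
                TaskDefinition(
                    id=f"T{counter:04d}",
                    description=f"synthetic {system} task {k + 1}",
                    system=system,
                    subsystem=f"{stem}_sub{k % 5 + 1}",
                    inputs=inputs,
                    outputs=outputs,
                )
            )
    return tasks
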