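"""Task feasibility checking and parsimonious (pFBA) essential-set extraction.

A metabolic task is *feasible* in a model when a steady-state flux
vector exists (S·v = 0, bounds respected) in an environment where all
boundary exchanges are closed except task-declared uptakes and the task
outputs must be produced at their required minimum rates.  Because the
environment admits no side inputs, the economical solution of the
resulting LP traces the task's metabolic route.

The *essential set* of a task is the support of the parsimonious FBA
optimum: among all feasible flux vectors, minimize total absolute flux
through the model's own reactions (reversible reactions split into
irreversible pairs for an exact L1 encoding), then keep the reactions
carrying flux above a tolerance.  LP optima need not be unique, so a
second pass re-minimizes with a tiny lexicographic-rank perturbation of
the objective under a fixed total-flux budget, yielding a deterministic
canonical support.  The task's gene set is the union of all genes
appearing in the support reactions' GPR rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .model_core import (
    MetabolicModel,
    TaskDefinition,
    TaskEssentialSet,
    resolve_metabolite,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TaskEnvironment",
    "TaskResolutionError",
    "SolverError",
    "FeasibilityResult",
    "CoverageSummary",
    "check_task_feasibility",
    "extract_essential_set",
    "build_task_gene_map",
]

DEFAULT_FLUX_TOLERANCE = 1e-6
_LEX_DELTA = 1e-7  # lexicographic perturbation weight in the canonical pass
_BUDGET_SLACK = 1e-9


class TaskResolutionError(ValueError):
    """A task metabolite cannot be resolved in the model namespace."""

    def __init__(self, task_id: str, missing: Sequence[str]):
        super().__init__(
            f"task {task_id!r}: metabolites not resolvable in model: {list(missing)}"
        )
        self.missing = list(missing)


class SolverError(RuntimeError):
    """The LP solver failed for reasons other than infeasibility."""


@dataclass
class TaskEnvironment:
    """A model with task boundary constraints applied.

    Columns are the model's own reactions (with non-task boundary
    reactions closed) followed by one uptake column per task input
    (producing the metabolite, bounded by the declared uptake
    magnitudes) and one demand column per task output (consuming the
    metabolite, lower-bounded by the required production).
    """

    model: MetabolicModel
    task: TaskDefinition
    stoichiometry: "lil_matrix"
    lower: np.ndarray
    upper: np.ndarray
    n_model_reactions: int
    column_ids: list[str]


def build_task_environment(
    model: MetabolicModel,
    task: TaskDefinition,
    mapping: Optional[Mapping[str, str]] = None,
) -> TaskEnvironment:
    """Close non-task exchanges and add task uptake/demand columns."""
    missing = []
    resolved_in, resolved_out = [], []
    for tm in task.inputs:
        met = resolve_metabolite(model, tm.metabolite, tm.compartment, mapping)
        (resolved_in.append((met, tm)) if met else missing.append(tm.metabolite))
    for tm in task.outputs:
        met = resolve_metabolite(model, tm.metabolite, tm.compartment, mapping)
        (resolved_out.append((met, tm)) if met else missing.append(tm.metabolite))
    if missing:
        raise TaskResolutionError(task.id, missing)

    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    n_rxn = len(model.reactions)
    n_cols = n_rxn + len(resolved_in) + len(resolved_out)
    S = lil_matrix((len(met_index), n_cols))
    lower = np.zeros(n_cols)
    upper = np.zeros(n_cols)
    column_ids = []
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.stoichiometry.items():
            S[met_index[met], j] = coeff
        if rxn.is_boundary:
            lower[j] = upper[j] = 0.0  # only declared task metabolites cross
        else:
            lower[j], upper[j] = rxn.lower_bound, rxn.upper_bound
        column_ids.append(rxn.id)
    col = n_rxn
    for met, tm in resolved_in:
        S[met_index[met], col] = 1.0  # uptake produces the metabolite
        lower[col], upper[col] = tm.lower_bound, tm.upper_bound
        column_ids.append(f"__uptake__{met}")
        col += 1
    for met, tm in resolved_out:
        S[met_index[met], col] = -1.0  # demand consumes the product
        lower[col], upper[col] = tm.lower_bound, tm.upper_bound
        column_ids.append(f"__demand__{met}")
        col += 1
    return TaskEnvironment(
        model=model,
        task=task,
        stoichiometry=S,
        lower=lower,
        upper=upper,
        n_model_reactions=n_rxn,
        column_ids=column_ids,
    )


@dataclass
class FeasibilityResult:
    feasible: bool
    solver_status: str
    fluxes: Optional[dict[str, float]] = None


def _solve(c, A_eq, b_eq, bounds, context: str):
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status not in (0, 2):  # 0 optimal, 2 infeasible
        raise SolverError(f"{context}: solver status {res.status}: {res.message}")
    return res


def check_task_feasibility(
    model: MetabolicModel,
    task: TaskDefinition,
    mapping: Optional[Mapping[str, str]] = None,
) -> FeasibilityResult:
    """Decide whether the model can pass the task at steady state."""
    env = build_task_environment(model, task, mapping)
    S = env.stoichiometry.tocsr()
    bounds = list(zip(env.lower, env.upper))
    res = _solve(
        np.zeros(S.shape[1]), S, np.zeros(S.shape[0]), bounds,
        f"feasibility({task.id})",
    )
    if res.status == 2:
        return FeasibilityResult(False, "infeasible")
    fluxes = {
        env.column_ids[j]: float(res.x[j]) for j in range(env.n_model_reactions)
    }
    return FeasibilityResult(True, "optimal", fluxes)


def _pfba_lp(env: TaskEnvironment):
    """Irreversible-split LP data: returns (split matrix, bounds, index maps).

    Each model reaction j becomes a forward variable (and a backward
    variable when reversible); task boundary columns are non-negative
    by construction and are not penalized.
    """
    S = env.stoichiometry.tocsc()
    n_model = env.n_model_reactions
    n_total = S.shape[1]
    cols, lowers, uppers, owner, sign = [], [], [], [], []
    for j in range(n_model):
        lb, ub = env.lower[j], env.upper[j]
        cols.append(S[:, j])
        lowers.append(max(lb, 0.0))
        uppers.append(max(ub, 0.0))
        owner.append(j)
        sign.append(1.0)
        if lb < 0:
            cols.append(-S[:, j])
            lowers.append(0.0)
            uppers.append(-lb)
            owner.append(j)
            sign.append(-1.0)
    for j in range(n_model, n_total):
        cols.append(S[:, j])
        lowers.append(env.lower[j])
        uppers.append(env.upper[j])
        owner.append(j)
        sign.append(1.0)
    from scipy.sparse import hstack

    A = hstack(cols, format="csr")
    return A, np.array(lowers), np.array(uppers), owner, np.array(sign)


def extract_essential_set(
    model: MetabolicModel,
    task: TaskDefinition,
    flux_tolerance: float = DEFAULT_FLUX_TOLERANCE,
    mapping: Optional[Mapping[str, str]] = None,
) -> TaskEssentialSet:
    """Extract the canonical minimal-flux reaction set accomplishing a task.

    Infeasible tasks return a typed ``TaskEssentialSet(feasible=False)``
    rather than raising.
    """
    env = build_task_environment(model, task, mapping)
    A, lowers, uppers, owner, sign = _pfba_lp(env)
    n_model = env.n_model_reactions
    b_eq = np.zeros(A.shape[0])
    bounds = list(zip(lowers, uppers))
    penalized = np.array([1.0 if owner[k] < n_model else 0.0 for k in range(len(owner))])

    res = _solve(penalized, A, b_eq, bounds, f"pfba({task.id})")
    if res.status == 2:
        return TaskEssentialSet(task_id=task.id, feasible=False)
    total_flux = float(penalized @ res.x)

    # canonical pass: fix the L1 budget, perturb weights by lexicographic
    # rank of the owning reaction id to break degenerate alternate optima
    rank = {rid: i for i, rid in enumerate(sorted(model.reaction_ids))}
    weights = np.array(
        [
            (1.0 + _LEX_DELTA * rank[model.reactions[owner[k]].id])
            if owner[k] < n_model
            else 0.0
            for k in range(len(owner))
        ]
    )
    from scipy.sparse import csr_matrix

    budget_row = csr_matrix(penalized)
    A_ub = budget_row
    b_ub = np.array([total_flux + _BUDGET_SLACK * (1.0 + abs(total_flux))])
    res2 = linprog(
        weights, A_ub=A_ub, b_ub=b_ub, A_eq=A, b_eq=b_eq, bounds=bounds,
        method="highs",
    )
    x = res2.x if res2.status == 0 else res.x
    if res2.status != 0:
        logger.warning(
            "task %s: canonical pass failed (status %d); using first-pass optimum",
            task.id, res2.status,
        )

    net = np.zeros(n_model)
    for k, xk in enumerate(x):
        if owner[k] < n_model:
            net[owner[k]] += sign[k] * xk
    support = [
        model.reactions[j].id
        for j in range(n_model)
        if abs(net[j]) > flux_tolerance
    ]
    support.sort()
    genes = frozenset().union(
        *(model.reaction(r).genes for r in support)
    ) if support else frozenset()
    flux_values = {
        model.reactions[j].id: float(net[j])
        for j in range(n_model)
        if abs(net[j]) > flux_tolerance
    }
    return TaskEssentialSet(
        task_id=task.id,
        feasible=True,
        reactions=support,
        genes=genes,
        flux_values=flux_values,
    )


@dataclass
class CoverageSummary:
    """Batch extraction diagnostics: per-task sizes and model gene coverage."""

    n_tasks: int
    n_feasible: int
    gene_coverage_percent: float
    task_reaction_counts: dict[str, int] = field(default_factory=dict)
    task_gene_counts: dict[str, int] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


def build_task_gene_map(
    model: MetabolicModel,
    tasks: Sequence[TaskDefinition],
    flux_tolerance: float = DEFAULT_FLUX_TOLERANCE,
    mapping: Optional[Mapping[str, str]] = None,
) -> tuple[list[TaskEssentialSet], CoverageSummary]:
    """Extract essential sets for every task; failures never abort the batch."""
    sets: list[TaskEssentialSet] = []
    errors: dict[str, str] = {}
    for task in tasks:
        try:
            sets.append(extract_essential_set(model, task, flux_tolerance, mapping))
        except (TaskResolutionError, SolverError) as exc:
            errors[task.id] = str(exc)
            sets.append(TaskEssentialSet(task_id=task.id, feasible=False))
    covered = frozenset().union(*(s.genes for s in sets)) if sets else frozenset()
    coverage = 100.0 * len(covered) / len(model.genes) if model.genes else 0.0
    summary = CoverageSummary(
        n_tasks=len(tasks),
        n_feasible=sum(s.feasible for s in sets),
        gene_coverage_percent=coverage,
        task_reaction_counts={s.task_id: len(s.reactions) for s in sets},
        task_gene_counts={s.task_id: len(s.genes) for s in sets},
        errors=errors,
    )
    logger.info(
        "extracted %d/%d feasible tasks; gene coverage %.2f%%",
        summary.n_feasible, summary.n_tasks, coverage,
    )
    return sets, summary
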