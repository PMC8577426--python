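"""Independent reference implementations used only for cross-checking.

These are deliberately written without reusing the package's evaluation
paths: a direct recursive min/max evaluator for GPR trees, an
exhaustive subset search for minimal task-feasible reaction sets, and a
hypergeometric summation for the one-tailed Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import replace
from itertools import combinations

import numpy as np

from metask.gpr import GPRLeaf, GPRNode
from metask.model_core import MetabolicModel
from metask.task_extraction import check_task_feasibility


def brute_force_gpr_value(rule, scores, missing="drop"):
    """Recursive min/max evaluation; returns None when fully missing."""
    if isinstance(rule, GPRLeaf):
        if rule.gene in scores:
            return float(scores[rule.gene])
        return 0.0 if missing == "zero" else None
    vals = [brute_force_gpr_value(c, scores, missing) for c in rule.children]
    vals = [v for v in vals if v is not None]
    if not vals:
        return None
    return min(vals) if rule.op == "and" else max(vals)


def random_gpr_tree(rng: np.random.Generator, genes: list[str], max_leaves: int = 8):
    """Random expression tree over a gene alphabet (leaves may repeat)."""
    n_leaves = int(rng.integers(1, max_leaves + 1))
    nodes = [GPRLeaf(genes[rng.integers(len(genes))]) for _ in range(n_leaves)]
    while len(nodes) > 1:
        k = int(rng.integers(2, min(3, len(nodes)) + 1))
        idx = rng.choice(len(nodes), size=k, replace=False)
        children = tuple(nodes[i] for i in sorted(idx, reverse=True))
        for i in sorted(idx, reverse=True):
            nodes.pop(i)
        op = "and" if rng.random() < 0.5 else "or"
        # flatten same-op children to keep the tree canonical
        flat = []
        for c in children:
            if isinstance(c, GPRNode) and c.op == op:
                flat.extend(c.children)
            else:
                flat.append(c)
        nodes.append(GPRNode(op, tuple(flat)))
    return nodes[0]


def restricted_feasible(model: MetabolicModel, task, allowed: set[str]) -> bool:
    """Task feasibility when only ``allowed`` internal reactions may carry flux."""
    reactions = [
        r if (r.is_boundary or r.id in allowed) else replace(r, lower_bound=0.0, upper_bound=0.0)
        for r in model.reactions
    ]
    restricted = MetabolicModel(
        id=model.id, metabolites=list(model.metabolites), reactions=reactions,
        genes=model.genes,
    )
    return check_task_feasibility(restricted, task).feasible


def minimal_feasible_subsets(model: MetabolicModel, task) -> list[frozenset[str]]:
    """All inclusion-minimal internal-reaction subsets that pass the task.

    Exhaustive search by increasing subset size; supersets of found
    minimal sets are pruned.  Only usable on toy models (<= ~12 internal
    reactions).
    """
    internal = [r.id for r in model.reactions if not r.is_boundary]
    assert len(internal) <= 12, "exhaustive search only for toy models"
    minimal: list[frozenset[str]] = []
    for size in range(len(internal) + 1):
        for combo in combinations(internal, size):
            s = frozenset(combo)
            if any(m <= s for m in minimal):
                continue
            if restricted_feasible(model, task, set(s)):
                minimal.append(s)
    return minimal


def fisher_greater_p(a: int, b: int, c: int, d: int) -> float:
    """One-tailed (over-representation) Fisher p by hypergeometric summation.

    X ~ Hypergeom(N=a+b+c+d, K=a+c successes, n=a+b draws); p = P(X >= a).
    """
    N, K, n = a + b + c + d, a + c, a + b
    denom = math.comb(N, n)
    total = 0
    for k in range(a, min(K, n) + 1):
        total += math.comb(K, k) * math.comb(N - K, n - k)
    return total / denom
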