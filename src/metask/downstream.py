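"""Statistical procedures over task-score matrices.

Covers four analyses commonly run on task-by-sample activity matrices:
a permutation test for whether a labelled group of samples (e.g. the
tissues of one organ system) is metabolically tighter than random
same-size groups; partitioning of samples into clusters by the exact
binary-activity combination of a selected task subset; one-tailed
Fisher enrichment of categorical traits within each cluster; and
patient-level aggregation of cluster membership.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSimilarityResult",
    "MetabolicCluster",
    "EnrichmentResult",
    "group_similarity_test",
    "select_majority_active_tasks",
    "binary_combination_clusters",
    "cluster_trait_enrichment",
    "patient_cluster_proportions",
    "cluster_median_scores",
]


@dataclass
class GroupSimilarityResult:
    """Observed within-group mean distance against a random-group null.

    ``empirical_p`` is the proportion of null distances *strictly lower*
    than the observed distance (exact permutation p, no +1 correction by
    default).
    """

    group: str
    group_size: int
    observed_mean_distance: float
    null_distances: np.ndarray
    empirical_p: float


def _mean_pairwise_distance(matrix: np.ndarray) -> float:
    """Mean Euclidean distance over unordered column pairs."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least two entities for a pairwise distance")
    return float(pdist(matrix.T, metric="euclidean").mean())


def group_similarity_test(
    scores: pd.DataFrame,
    groups: Mapping[str, str],
    n_random: int = 10_000,
    seed: Optional[int] = None,
    min_group_size: int = 3,
    plus_one: bool = False,
) -> dict[str, GroupSimilarityResult]:
    """Permutation test of within-group metabolic similarity.

    Parameters
    ----------
    scores:
        Task-by-entity matrix (continuous scores by default; pass a
        binary matrix for the binary variant).
    groups:
        Entity -> group label.  Only groups with at least
        ``min_group_size`` members are tested; the random pool is the
        union of all such groups' members.
    n_random:
        Number of random same-size groups drawn (uniformly, without
        replacement within each draw) for the null.
    plus_one:
        Use the conservative ``(count+1)/(n_random+1)`` estimator
        instead of the plain proportion.
    """
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {}
    for entity, grp in groups.items():
        if entity not in scores.columns:
            raise KeyError(f"entity {entity!r} not found in score columns")
        by_group.setdefault(grp, []).append(entity)
    considered = {g: m for g, m in by_group.items() if len(m) >= min_group_size}
    pool = sorted({e for members in considered.values() for e in members})
    pool_matrix = scores[pool].to_numpy()
    results: dict[str, GroupSimilarityResult] = {}
    for grp, members in sorted(considered.items()):
        k = len(members)
        if k > len(pool):
            raise ValueError(f"group {grp!r} larger than the entity pool")
        observed = _mean_pairwise_distance(scores[members].to_numpy())
        null = np.empty(n_random)
        for i in range(n_random):
            idx = rng.choice(len(pool), size=k, replace=False)
            null[i] = _mean_pairwise_distance(pool_matrix[:, idx])
        count = int((null < observed).sum())
        p = (count + 1) / (n_random + 1) if plus_one else count / n_random
        results[grp] = GroupSimilarityResult(
            group=grp,
            group_size=k,
            observed_mean_distance=observed,
            null_distances=null,
            empirical_p=p,
        )
    return results


def select_majority_active_tasks(
    binary: pd.DataFrame, fraction: float = 0.5
) -> list[str]:
    """Tasks active in strictly more than ``fraction`` of samples."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    prop = binary.astype(float).mean(axis=1)
    return list(prop.index[prop > fraction])


@dataclass
class MetabolicCluster:
    """Samples sharing one exact binary activity signature."""

    label: str
    signature: tuple[int, ...]
    members: list[str] = field(default_factory=list)


def binary_combination_clusters(
    binary: pd.DataFrame,
) -> list[MetabolicCluster]:
    """Partition samples by their exact binary signature over the tasks.

    With k tasks the cluster universe has 2^k signatures; only realized
    signatures are returned.  Labels M1, M2, ... follow canonical
    signature order (all-active first, descending binary order), so the
    labelling is deterministic and independent of sample order.
    """
    if binary.shape[0] < 1:
        raise ValueError("need at least one task")
    sig_members: dict[tuple[int, ...], list[str]] = {}
    as_int = binary.astype(int)
    for sample in binary.columns:
        sig = tuple(as_int[sample])
        sig_members.setdefault(sig, []).append(sample)
    clusters = []
    for i, sig in enumerate(sorted(sig_members, reverse=True), start=1):
        clusters.append(
            MetabolicCluster(
                label=f"M{i}", signature=sig, members=sig_members[sig]
            )
        )
    return clusters


@dataclass
class EnrichmentResult:
    """One-tailed Fisher exact over-representation of a trait in a cluster."""

    cluster: str
    trait: str
    level: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float


def cluster_trait_enrichment(
    clusters: Sequence[MetabolicCluster],
    traits: pd.DataFrame | pd.Series,
) -> list[EnrichmentResult]:
    """Fisher over-representation of each trait level in each cluster.

    The 2x2 table per (cluster, trait level) is
    ``[[in-cluster & level, in-cluster & other],
    [out-cluster & level, out-cluster & other]]`` over the samples with
    a recorded trait value; samples missing a trait are excluded
    pairwise.  One-tailed p is the hypergeometric upper tail
    (``alternative="greater"``).
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_frame(name=traits.name or "trait")
    all_samples = [s for c in clusters for s in c.members]
    results = []
    for trait_name in traits.columns:
        col = traits[trait_name]
        known = [s for s in all_samples if s in col.index and pd.notna(col[s])]
        dropped = len(all_samples) - len(known)
        if dropped:
            logger.warning(
                "trait %s: excluding %d samples without a value", trait_name, dropped
            )
        levels = sorted(set(col[known].astype(str)))
        if len(levels) < 2:
            warnings.warn(f"trait {trait_name!r} has a single level; skipped")
            continue
        for cluster in clusters:
            members = set(cluster.members)
            if not members:
                continue
            for level in levels:
                a = sum(1 for s in known if s in members and str(col[s]) == level)
                b = sum(1 for s in known if s in members) - a
                c = sum(1 for s in known if str(col[s]) == level) - a
                d = len(known) - a - b - c
                _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
                results.append(
                    EnrichmentResult(
                        cluster=cluster.label,
                        trait=trait_name,
                        level=level,
                        table=((a, b), (c, d)),
                        p_value=float(p),
                    )
                )
    return results


def patient_cluster_proportions(
    clusters: Sequence[MetabolicCluster],
    sample_to_patient: Mapping[str, str],
    target_clusters: Sequence[str],
    labels: Optional[Mapping[str, object]] = None,
    positive_label: object = 1,
) -> pd.DataFrame:
    """Rank patients by the fraction of their samples in target clusters.

    Returns a DataFrame indexed by patient with columns ``n_samples``,
    ``proportion`` (descending).  When binary ``labels`` are supplied,
    adds a ``predicted`` column from thresholding the ranking at the
    label prevalence (the top-k patients are called positive, k = number
    of positive labels) and stores the resulting classification accuracy
    in ``df.attrs["accuracy"]``.
    """
    targets = set(target_clusters)
    unknown = targets - {c.label for c in clusters}
    if unknown:
        raise KeyError(f"unknown target clusters: {sorted(unknown)}")
    in_target = {s for c in clusters if c.label in targets for s in c.members}
    per_patient: dict[str, list[str]] = {}
    for c in clusters:
        for s in c.members:
            if s not in sample_to_patient:
                raise KeyError(f"sample {s!r} has no patient mapping")
            per_patient.setdefault(str(sample_to_patient[s]), []).append(s)
    rows = [
        {
            "patient": patient,
            "n_samples": len(samples),
            "proportion": sum(s in in_target for s in samples) / len(samples),
        }
        for patient, samples in per_patient.items()
        if samples
    ]
    df = (
        pd.DataFrame(rows)
        .sort_values(["proportion", "patient"], ascending=[False, True])
        .set_index("patient")
    )
    if labels is not None:
        lab = pd.Series({p: labels[p] for p in df.index})
        k = int((lab == positive_label).sum())
        predicted = pd.Series(False, index=df.index)
        predicted.iloc[:k] = True
        df["label"] = lab
        df["predicted"] = predicted
        df.attrs["accuracy"] = float(
            (predicted == (lab == positive_label)).mean()
        )
    return df


def cluster_median_scores(
    clusters: Sequence[MetabolicCluster], combined: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster median of the combined (binary x continuous) task score.

    Returns a task-by-cluster matrix; ``df.attrs["nonzero_tasks"]``
    lists tasks with a nonzero median in at least one cluster.
    """
    data = {
        c.label: combined[c.members].median(axis=1) for c in clusters if c.members
    }
    df = pd.DataFrame(data, index=combined.index)
    nonzero = df.index[(df.fillna(0.0) != 0.0).any(axis=1)]
    df.attrs["nonzero_tasks"] = list(nonzero)
    return df
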