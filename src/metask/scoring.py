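"""Task activity scoring from a gene-by-sample expression matrix.

The pipeline, per sample:

1.  **Gene activity score.**  Each gene g gets a platform-free score
    ``5 * ln(1 + x_gs / t_g)`` where ``x_gs`` is its expression in
    sample s and ``t_g`` a per-gene threshold.  A gene exactly at its
    threshold scores ``5*ln(2) ~ 3.4657``; a silent gene scores 0.
    Thresholds come from local percentile clamping: the gene's mean
    expression, clamped to the 25th/75th percentiles of the overall
    expression distribution (or a single global percentile).
2.  **Reaction activity level (RAL).**  Each reaction's GPR rule is
    evaluated over gene scores with min (complex) / max (isozyme)
    propagation; the propagated leaf is the reaction's *determinant*
    gene and its score the RAL.
3.  **Gene significance.**  ``S(g) = 1 / #reactions whose determinant
    is g`` in that sample, over the union of reactions appearing in any
    task's essential set — promiscuous determinants are down-weighted.
4.  **Metabolic task score.**  ``MT(task) = mean over the task's
    reactions of RAL * S(determinant)``; the binary call is active when
    the plain mean RAL strictly exceeds ``5*ln(2)``, and the combined
    score is ``binary * continuous``.

MT scores are comparable across samples, not across tasks: a task whose
genes are constitutively low-expressed scores low everywhere, so only
relative variation is meaningful.  The result object carries this
contract in its documentation rather than enforcing it.

:class:`TaskActivityModel` wraps the pipeline statsmodels-style:
construct from data, ``fit()`` returns a :class:`TaskActivityResult`
with the score matrices, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gpr import evaluate_gpr
from .model_core import MetabolicModel, TaskEssentialSet

__all__ = [
    "BINARY_THRESHOLD",
    "ExpressionDataset",
    "ReactionActivity",
    "TaskScoreResult",
    "TaskActivityModel",
    "TaskActivityResult",
    "compute_thresholds",
    "gene_activity_scores",
    "reaction_activity",
    "gene_significance",
    "metabolic_task_scores",
]

#: Score of a gene exactly at its expression threshold; also the strict
#: cutoff on the mean RAL for calling a task active.
BINARY_THRESHOLD = 5.0 * math.log(2.0)


@dataclass
class ExpressionDataset:
    """A non-negative gene-by-sample expression matrix.

    Units are free (counts, TPM, microarray intensity) as long as the
    whole dataset comes from one platform; all downstream quantities are
    ratios to per-gene thresholds and are invariant to global rescaling.
    """

    values: pd.DataFrame  # genes x samples

    def __post_init__(self) -> None:
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix must be numeric")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, sep: Optional[str] = None) -> "ExpressionDataset":
        """Read a matrix whose first column is the gene id."""
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionDataset":
        return cls(df.copy())


def compute_thresholds(
    data: ExpressionDataset,
    mode: str = "local",
    lower_pct: float = 25.0,
    upper_pct: float = 75.0,
    distribution: str = "gene_means",
    global_pct: float = 75.0,
) -> pd.Series:
    """Per-gene expression thresholds.

    ``local`` mode clamps each gene's mean expression to lower/upper
    percentile bounds of the overall expression distribution —
    ``distribution`` selects whether the percentiles are taken over the
    per-gene means (default) or over all gene-by-sample entries.
    ``global`` mode assigns every gene the single ``global_pct``
    percentile of the overall distribution.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("require 0 <= lower_pct < upper_pct <= 100")
    if distribution not in ("gene_means", "all_values"):
        raise ValueError("distribution must be 'gene_means' or 'all_values'")
    means = data.values.mean(axis=1)
    pool = (
        means.to_numpy() if distribution == "gene_means"
        else data.values.to_numpy().ravel()
    )
    if mode == "local" and len(data.samples) < 2:
        warnings.warn("local thresholding needs >=2 samples; falling back to global")
        mode = "global"
    if mode == "global":
        thr = float(np.percentile(pool, global_pct))
        return pd.Series(thr, index=data.values.index, name="threshold")
    if mode != "local":
        raise ValueError("mode must be 'local' or 'global'")
    lower = float(np.percentile(pool, lower_pct))
    upper = float(np.percentile(pool, upper_pct))
    return means.clip(lower, upper).rename("threshold")


def gene_activity_scores(
    data: ExpressionDataset, thresholds: pd.Series
) -> pd.DataFrame:
    """Gene score matrix ``5 * ln(1 + expression / threshold)``."""
    thr = thresholds.reindex(data.values.index)
    if thr.isna().any():
        raise ValueError(
            f"thresholds missing for genes: {list(thr.index[thr.isna()])[:5]}"
        )
    if (thr <= 0).any():
        raise ValueError("thresholds must be strictly positive")
    ratio = data.values.div(thr, axis=0)
    return 5.0 * np.log1p(ratio)


@dataclass
class ReactionActivity:
    """Per-reaction, per-sample GPR evaluation results.

    ``ral`` holds the activity level (NaN where undefined), ``determinant``
    the propagated gene id (None where undefined), ``defined`` whether
    the reaction's GPR could be evaluated for that sample.
    """

    ral: pd.DataFrame
    determinant: pd.DataFrame
    defined: pd.DataFrame
    reaction_tasks: dict[str, list[str]] = field(default_factory=dict)


def reaction_activity(
    scores: pd.DataFrame,
    essential_sets: Sequence[TaskEssentialSet],
    model: MetabolicModel,
    missing: str = "drop",
) -> ReactionActivity:
    """Evaluate GPRs of every reaction appearing in any essential set.

    Reactions shared by several tasks are evaluated once per sample.
    Reactions without a GPR (or whose genes are all unmeasured under the
    ``drop`` policy) are undefined, not zero.
    """
    reaction_tasks: dict[str, list[str]] = {}
    for es in essential_sets:
        for rxn_id in es.reactions:
            reaction_tasks.setdefault(rxn_id, []).append(es.task_id)
    rxn_ids = sorted(reaction_tasks)
    samples = list(scores.columns)
    ral = pd.DataFrame(np.nan, index=rxn_ids, columns=samples)
    det = pd.DataFrame(None, index=rxn_ids, columns=samples, dtype=object)
    defined = pd.DataFrame(False, index=rxn_ids, columns=samples)
    measured = set(scores.index)
    no_gpr_logged = False
    from .gpr import gpr_genes

    for rxn_id in rxn_ids:
        rule = model.reaction(rxn_id).gpr
        if rule is None:
            if not no_gpr_logged:
                warnings.warn(
                    f"reaction {rxn_id!r} (and possibly others) has no GPR; "
                    "its activity is undefined"
                )
                no_gpr_logged = True
            continue
        rule_genes = gpr_genes(rule)
        for sample in samples:
            col = scores[sample]
            gene_scores = {g: col[g] for g in rule_genes if g in measured}
            ev = evaluate_gpr(rule, gene_scores, missing=missing)
            if ev.defined:
                ral.at[rxn_id, sample] = ev.value
                det.at[rxn_id, sample] = ev.determinant
                defined.at[rxn_id, sample] = True
    return ReactionActivity(ral, det, defined, reaction_tasks)


def gene_significance(activity: ReactionActivity) -> pd.DataFrame:
    """Per-sample gene significance S = 1 / determinant count.

    The count runs over the unique reactions in the union of all
    task-essential sets (the metabolism the task map covers), separately
    for each sample because determinants shift with expression.  Genes
    never selected as determinant are NaN.
    """
    genes = sorted(
        {
            g
            for col in activity.determinant.columns
            for g in activity.determinant[col].dropna().unique()
        }
    )
    S = pd.DataFrame(np.nan, index=genes, columns=activity.determinant.columns)
    for sample in activity.determinant.columns:
        counts = activity.determinant[sample].dropna().value_counts()
        S.loc[counts.index, sample] = 1.0 / counts
    return S


@dataclass
class TaskScoreResult:
    """Task-by-sample activity: continuous, binary, combined, coverage.

    ``combined = score * binary`` (the continuous value where active,
    zero where inactive).  ``coverage`` is the fraction of a task's
    reactions with a defined RAL; tasks under ``min_coverage`` carry NaN
    scores.  Scores compare across samples within one task only.
    """

    score: pd.DataFrame
    binary: pd.DataFrame
    combined: pd.DataFrame
    coverage: pd.DataFrame

    @property
    def tasks(self) -> list[str]:
        return list(self.score.index)

    @property
    def samples(self) -> list[str]:
        return list(self.score.columns)


def metabolic_task_scores(
    activity: ReactionActivity,
    significance: pd.DataFrame,
    essential_sets: Sequence[TaskEssentialSet],
    binary_threshold: float = BINARY_THRESHOLD,
    min_coverage: float = 0.0,
    denominator: str = "defined",
) -> TaskScoreResult:
    """Continuous and binary task scores from RALs and gene significance.

    ``denominator="defined"`` (default) averages over the reactions with
    a defined RAL; ``"all"`` divides by the task's full reaction count,
    which biases scores downward when reactions are unmeasured.
    """
    if denominator not in ("defined", "all"):
        raise ValueError("denominator must be 'defined' or 'all'")
    samples = list(activity.ral.columns)
    tasks = [es.task_id for es in essential_sets]
    score = pd.DataFrame(np.nan, index=tasks, columns=samples)
    binary = pd.DataFrame(False, index=tasks, columns=samples)
    coverage = pd.DataFrame(0.0, index=tasks, columns=samples)
    for es in essential_sets:
        if not es.feasible or not es.reactions:
            continue
        rals = activity.ral.loc[es.reactions]
        dets = activity.determinant.loc[es.reactions]
        n_total = len(es.reactions)
        for sample in samples:
            r = rals[sample]
            mask = r.notna()
            n_def = int(mask.sum())
            coverage.at[es.task_id, sample] = n_def / n_total
            if n_def == 0 or n_def / n_total < min_coverage:
                continue
            d = dets[sample][mask]
            s_vals = significance[sample].reindex(d.to_numpy()).to_numpy()
            weighted = r[mask].to_numpy() * s_vals
            denom = n_def if denominator == "defined" else n_total
            score.at[es.task_id, sample] = weighted.sum() / denom
            binary.at[es.task_id, sample] = bool(
                r[mask].mean() > binary_threshold
            )
    combined = score.where(binary, 0.0).where(score.notna(), np.nan)
    return TaskScoreResult(score, binary, combined, coverage)


# ---------------------------------------------------------------------------
# statsmodels-style surface


class TaskActivityModel:
    """Metabolic-task activity model over an expression dataset.

    Parameters
    ----------
    expression:
        :class:`ExpressionDataset` (or a gene-by-sample DataFrame).
    essential_sets:
        Task essential sets from :func:`metask.task_extraction.build_task_gene_map`
        or loaded from the JSON artifact.
    model:
        The metabolic model supplying GPR rules for the set reactions.
    threshold_mode, lower_pct, upper_pct, distribution, global_pct:
        See :func:`compute_thresholds`.
    binary_threshold:
        Strict cutoff on the mean RAL for the binary call; default
        ``5*ln(2)``, the score of a gene exactly at its threshold.
    min_coverage:
        Minimum fraction of task reactions with defined RAL for a score
        to be reported.
    missing:
        Policy for unmeasured genes inside GPRs (``"drop"`` or ``"zero"``).
    """

    def __init__(
        self,
        expression: ExpressionDataset | pd.DataFrame,
        essential_sets: Sequence[TaskEssentialSet],
        model: MetabolicModel,
        threshold_mode: str = "local",
        lower_pct: float = 25.0,
        upper_pct: float = 75.0,
        distribution: str = "gene_means",
        global_pct: float = 75.0,
        binary_threshold: float = BINARY_THRESHOLD,
        min_coverage: float = 0.0,
        denominator: str = "defined",
        missing: str = "drop",
    ):
        if isinstance(expression, pd.DataFrame):
            expression = ExpressionDataset.from_dataframe(expression)
        self.expression = expression
        self.essential_sets = list(essential_sets)
        self.model = model
        self.threshold_mode = threshold_mode
        self.lower_pct = lower_pct
        self.upper_pct = upper_pct
        self.distribution = distribution
        self.global_pct = global_pct
        self.binary_threshold = binary_threshold
        self.min_coverage = min_coverage
        self.denominator = denominator
        self.missing = missing

    @classmethod
    def from_files(
        cls,
        expression_path: str | Path,
        sets_path: str | Path,
        model_path: str | Path,
        **kwargs,
    ) -> "TaskActivityModel":
        from .model_core import read_model, read_task_essential_sets

        return cls(
            ExpressionDataset.from_tsv(expression_path),
            read_task_essential_sets(sets_path),
            read_model(model_path),
            **kwargs,
        )

    def fit(self) -> "TaskActivityResult":
        """Run thresholding, GPR mapping and task scoring."""
        thresholds = compute_thresholds(
            self.expression,
            mode=self.threshold_mode,
            lower_pct=self.lower_pct,
            upper_pct=self.upper_pct,
            distribution=self.distribution,
            global_pct=self.global_pct,
        )
        scores = gene_activity_scores(self.expression, thresholds)
        activity = reaction_activity(
            scores, self.essential_sets, self.model, missing=self.missing
        )
        significance = gene_significance(activity)
        result = metabolic_task_scores(
            activity,
            significance,
            self.essential_sets,
            binary_threshold=self.binary_threshold,
            min_coverage=self.min_coverage,
            denominator=self.denominator,
        )
        return TaskActivityResult(
            model=self,
            thresholds=thresholds,
            gene_scores=scores,
            reaction_activity=activity,
            significance=significance,
            scores=result,
        )


@dataclass
class TaskActivityResult:
    """Fitted task-activity results with diagnostics.

    Attributes
    ----------
    scores:
        :class:`TaskScoreResult` — continuous/binary/combined matrices.
    thresholds, gene_scores, reaction_activity, significance:
        Intermediate quantities for audit.
    """

    model: TaskActivityModel
    thresholds: pd.Series
    gene_scores: pd.DataFrame
    reaction_activity: ReactionActivity
    significance: pd.DataFrame
    scores: TaskScoreResult

    @property
    def score(self) -> pd.DataFrame:
        return self.scores.score

    @property
    def binary(self) -> pd.DataFrame:
        return self.scores.binary

    @property
    def combined(self) -> pd.DataFrame:
        return self.scores.combined

    @property
    def coverage(self) -> pd.DataFrame:
        return self.scores.coverage

    def summary(self) -> str:
        """Per-task summary table: mean score, active fraction, coverage."""
        rows = []
        for task in self.scores.tasks:
            s = self.scores.score.loc[task]
            b = self.scores.binary.loc[task]
            c = self.scores.coverage.loc[task]
            rows.append(
                {
                    "task": task,
                    "mean_score": s.mean(),
                    "active_fraction": float(b.mean()),
                    "mean_coverage": float(c.mean()),
                }
            )
        df = pd.DataFrame(rows).set_index("task")
        header = (
            "Metabolic task activity\n"
            f"  samples: {len(self.scores.samples)}  tasks: {len(self.scores.tasks)}\n"
            f"  thresholding: {self.model.threshold_mode} "
            f"({self.model.lower_pct:g}/{self.model.upper_pct:g} pct), "
            f"binary cutoff {self.model.binary_threshold:.4f}\n"
            "  note: scores compare across samples within a task, not across tasks\n"
        )
        with pd.option_context("display.float_format", "{:.4f}".format):
            return header + df.to_string()

    def to_csv(self, out_dir: str | Path, detail: bool = False) -> None:
        """Write score.csv, score_binary.csv, coverage.csv (and detail JSONL)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.scores.score.to_csv(out / "score.csv")
        self.scores.binary.astype(int).to_csv(out / "score_binary.csv")
        self.scores.coverage.to_csv(out / "coverage.csv")
        if detail:
            self._write_detail(out / "detail.jsonl")

    def _write_detail(self, path: Path) -> None:
        import json

        act = self.reaction_activity
        with open(path, "w") as fh:
            for es in self.model.essential_sets:
                if not es.feasible:
                    continue
                for sample in self.scores.samples:
                    records = []
                    for rxn in es.reactions:
                        det = act.determinant.at[rxn, sample]
                        records.append(
                            {
                                "reaction": rxn,
                                "ral": None
                                if pd.isna(act.ral.at[rxn, sample])
                                else float(act.ral.at[rxn, sample]),
                                "determinant": det,
                                "S": None
                                if det is None
                                else float(self.significance.at[det, sample]),
                            }
                        )
                    fh.write(
                        json.dumps(
                            {
                                "task": es.task_id,
                                "sample": sample,
                                "coverage": float(
                                    self.scores.coverage.at[es.task_id, sample]
                                ),
                                "reactions": records,
                            },
                            sort_keys=True,
                        )
                        + "\n"
                    )
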