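"""Gene scores, reaction activity levels, significance and task scores."""

import math

import numpy as np
import pandas as pd
import pytest

from metask.gpr import parse_gpr
from metask.model_core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    TaskEssentialSet,
)
from metask.scoring import (
    BINARY_THRESHOLD,
    ExpressionDataset,
    TaskActivityModel,
    compute_thresholds,
    gene_activity_scores,
    gene_significance,
    metabolic_task_scores,
    reaction_activity,
)


def _dataset(values: dict, samples=None) -> ExpressionDataset:
    df = pd.DataFrame(values).T
    if samples is not None:
        df.columns = samples
    return ExpressionDataset(df.astype(float))


def test_expression_must_be_non_negative():
    with pytest.raises(ValueError, match="non-negative"):
        _dataset({"g1": [1.0, -0.5]})


def test_local_thresholds_clamp_gene_means():
    """Gene means (1, 5, 10, 50, 100) with percentile bounds landing on
    (5, 50) clamp to (5, 5, 10, 50, 50) — boundary genes inclusive."""
    data = _dataset(
        {
            "g1": [1, 1],
            "g2": [5, 5],
            "g3": [10, 10],
            "g4": [50, 50],
            "g5": [100, 100],
        }
    )
    thr = compute_thresholds(data, mode="local", lower_pct=25, upper_pct=75)
    assert thr.tolist() == [5.0, 5.0, 10.0, 50.0, 50.0]


def test_local_threshold_default_percentiles_are_quartiles():
    import inspect

    sig = inspect.signature(compute_thresholds)
    assert sig.parameters["lower_pct"].default == 25.0
    assert sig.parameters["upper_pct"].default == 75.0


def test_global_threshold_single_value_for_all_genes():
    data = _dataset({"g1": [1, 3], "g2": [10, 30], "g3": [100, 300]})
    thr = compute_thresholds(data, mode="global", global_pct=50)
    assert thr.nunique() == 1


def test_single_sample_falls_back_to_global():
    data = _dataset({"g1": [1.0], "g2": [10.0]})
    with pytest.warns(UserWarning, match="falling back to global"):
        thr = compute_thresholds(data, mode="local")
    assert thr.nunique() == 1


@pytest.mark.parametrize(
    "expr_over_thr, expected",
    [
        (1.0, 5 * math.log(2)),   # at the threshold: the binary cutoff
        (0.0, 0.0),               # silent gene
        (3.0, 5 * math.log(4)),   # three-fold over threshold
    ],
)
def test_gene_score_closed_form(expr_over_thr, expected):
    data = _dataset({"g": [2.0 * expr_over_thr, 2.0 * expr_over_thr]})
    thr = pd.Series({"g": 2.0})
    scores = gene_activity_scores(data, thr)
    assert scores.iloc[0, 0] == pytest.approx(expected, rel=1e-12)


def test_binary_cutoff_constant_value():
    assert BINARY_THRESHOLD == pytest.approx(3.465735902799726, rel=1e-12)


def _scoring_model():
    """R0 (gene h), R1 and R2 (both gene g): two tasks sharing nothing."""
    mets = [Metabolite(m, "c") for m in ("A", "B", "C", "D")]
    rxns = [
        Reaction("R0", {"A": -1.0, "B": 1.0}, 0, 1000, gpr=parse_gpr("h")),
        Reaction("R1", {"B": -1.0, "C": 1.0}, 0, 1000, gpr=parse_gpr("g")),
        Reaction("R2", {"C": -1.0, "D": 1.0}, 0, 1000, gpr=parse_gpr("g")),
        Reaction("RN", {"A": -1.0, "D": 1.0}, 0, 1000),  # no GPR
    ]
    model = MetabolicModel("scoring", mets, rxns)
    sets = [
        TaskEssentialSet("T1", True, ["R0"], frozenset({"h"}), {"R0": 1.0}),
        TaskEssentialSet("T2", True, ["R1", "R2"], frozenset({"g"}), {"R1": 1.0, "R2": 1.0}),
    ]
    return model, sets


def test_reaction_activity_max_semantics_and_dedup():
    mets = [Metabolite(m, "c") for m in ("A", "B")]
    rxns = [Reaction("R", {"A": -1.0, "B": 1.0}, 0, 1000, gpr=parse_gpr("A or B"))]
    model = MetabolicModel("m", mets, rxns)
    sets = [
        TaskEssentialSet("T1", True, ["R"], frozenset({"A", "B"}), {"R": 1.0}),
        TaskEssentialSet("T2", True, ["R"], frozenset({"A", "B"}), {"R": 1.0}),
    ]
    scores = pd.DataFrame({"s1": [2.0, 5.0]}, index=["A", "B"])
    act = reaction_activity(scores, sets, model)
    assert list(act.ral.index) == ["R"]  # shared reaction evaluated once
    assert act.ral.at["R", "s1"] == 5.0
    assert act.determinant.at["R", "s1"] == "B"
    assert act.reaction_tasks["R"] == ["T1", "T2"]


def test_reaction_with_all_genes_unmeasured_is_undefined():
    model, sets = _scoring_model()
    scores = pd.DataFrame({"s1": [4.0]}, index=["g"])  # h unmeasured
    act = reaction_activity(scores, sets, model)
    assert not act.defined.at["R0", "s1"]
    assert np.isnan(act.ral.at["R0", "s1"])
    assert act.defined.at["R1", "s1"]


def test_gene_significance_counts_determinants_per_sample():
    model, sets = _scoring_model()
    # s1: g determines R1+R2 (S=1/2), h determines R0 (S=1)
    scores = pd.DataFrame({"s1": [4.0, 4.0], "s2": [4.0, 4.0]}, index=["g", "h"])
    act = reaction_activity(scores, sets, model)
    S = gene_significance(act)
    assert S.at["g", "s1"] == 0.5
    assert S.at["h", "s1"] == 1.0


def test_significance_varies_across_samples():
    """A gene's determinant count follows expression, so S is per sample."""
    mets = [Metabolite(m, "c") for m in ("A", "B", "C")]
    rxns = [
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0, 1000, gpr=parse_gpr("x or y")),
        Reaction("R2", {"B": -1.0, "C": 1.0}, 0, 1000, gpr=parse_gpr("x")),
    ]
    model = MetabolicModel("m", mets, rxns)
    sets = [TaskEssentialSet("T", True, ["R1", "R2"], frozenset({"x", "y"}), {"R1": 1.0, "R2": 1.0})]
    scores = pd.DataFrame({"s1": [5.0, 1.0], "s2": [1.0, 5.0]}, index=["x", "y"])
    act = reaction_activity(scores, sets, model)
    S = gene_significance(act)
    assert S.at["x", "s1"] == 0.5  # x determines both reactions in s1
    assert S.at["x", "s2"] == 1.0  # only R2 in s2 (y wins R1)


def test_task_scores_hand_computed():
    """1-reaction task with RAL 4 and S=1 scores 4; 2-reaction task with a
    shared determinant (S=1/2) and RALs (4,4) scores (4/2+4/2)/2 = 2;
    both are active since mean RAL 4 > 5 ln 2."""
    model, sets = _scoring_model()
    scores = pd.DataFrame({"s1": [4.0, 4.0]}, index=["g", "h"])
    act = reaction_activity(scores, sets, model)
    S = gene_significance(act)
    result = metabolic_task_scores(act, S, sets)
    assert result.score.at["T1", "s1"] == pytest.approx(4.0)
    assert result.score.at["T2", "s1"] == pytest.approx(2.0)
    assert bool(result.binary.at["T1", "s1"]) and bool(result.binary.at["T2", "s1"])
    assert result.combined.at["T2", "s1"] == pytest.approx(2.0)


def test_all_determinants_exactly_at_threshold_called_inactive():
    """Strict binary rule: mean RAL equal to 5 ln 2 is not active."""
    model, sets = _scoring_model()
    at_thr = 5 * math.log(2)
    scores = pd.DataFrame({"s1": [at_thr, at_thr]}, index=["g", "h"])
    act = reaction_activity(scores, sets, model)
    result = metabolic_task_scores(act, gene_significance(act), sets)
    assert not result.binary.to_numpy().any()


def test_combined_is_zero_when_inactive():
    model, sets = _scoring_model()
    scores = pd.DataFrame({"s1": [1.0, 1.0]}, index=["g", "h"])
    act = reaction_activity(scores, sets, model)
    result = metabolic_task_scores(act, gene_significance(act), sets)
    assert not result.binary.at["T1", "s1"]
    assert result.combined.at["T1", "s1"] == 0.0
    assert result.score.at["T1", "s1"] > 0


def test_min_coverage_marks_scores_undefined():
    model, sets = _scoring_model()
    sets = sets + [
        TaskEssentialSet("T3", True, ["R0", "RN"], frozenset({"h"}), {"R0": 1.0, "RN": 1.0})
    ]
    scores = pd.DataFrame({"s1": [4.0, 4.0]}, index=["g", "h"])
    with pytest.warns(UserWarning, match="no GPR"):
        act = reaction_activity(scores, sets, model)
    result = metabolic_task_scores(act, gene_significance(act), sets, min_coverage=1.0)
    assert result.coverage.at["T3", "s1"] == 0.5
    assert np.isnan(result.score.at["T3", "s1"])
    # with the default min_coverage the defined half is averaged
    result0 = metabolic_task_scores(act, gene_significance(act), sets)
    assert result0.score.at["T3", "s1"] == pytest.approx(4.0)


def test_literal_denominator_divides_by_all_reactions():
    model, sets = _scoring_model()
    sets = [TaskEssentialSet("T3", True, ["R0", "RN"], frozenset({"h"}), {"R0": 1.0, "RN": 1.0})]
    scores = pd.DataFrame({"s1": [4.0]}, index=["h"])
    with pytest.warns(UserWarning, match="no GPR"):
        act = reaction_activity(scores, sets, model)
    res = metabolic_task_scores(act, gene_significance(act), sets, denominator="all")
    assert res.score.at["T3", "s1"] == pytest.approx(2.0)  # 4*1 / 2 reactions


def test_scale_invariance_of_whole_pipeline(nested_fixture):
    """Multiplying the expression matrix by any c > 0 leaves every score
    and binary call unchanged (thresholds scale with the data)."""
    _, model, tasks, truth_sets, data, _ = nested_fixture
    sets = [
        TaskEssentialSet(
            t.id,
            True,
            sorted(truth_sets[t.id]),
            frozenset().union(*(model.reaction(r).genes for r in truth_sets[t.id])),
            {r: 1.0 for r in truth_sets[t.id]},
        )
        for t in tasks
    ]
    base = TaskActivityModel(data, sets, model).fit()
    for c in (0.1, 7.0, 1000.0):
        scaled = ExpressionDataset(data.values * c)
        res = TaskActivityModel(scaled, sets, model).fit()
        assert np.allclose(res.score.to_numpy(), base.score.to_numpy(), rtol=1e-9)
        assert res.binary.equals(base.binary)


def test_score_boundedness_under_capped_expression():
    """With expression at most k times its threshold, every task score is
    at most 5 log(1+k)."""
    rng = np.random.default_rng(5)
    model, sets = _scoring_model()
    k = 3.0
    data = ExpressionDataset(
        pd.DataFrame(
            rng.uniform(0.5, 2.0, size=(2, 10)), index=["g", "h"],
            columns=[f"s{i}" for i in range(10)],
        )
    )
    thr = compute_thresholds(data)
    capped = ExpressionDataset(data.values.clip(upper=thr * k, axis=0))
    scores = gene_activity_scores(capped, thr)
    act = reaction_activity(scores, sets, model)
    res = metabolic_task_scores(act, gene_significance(act), sets)
    assert np.nanmax(res.score.to_numpy()) <= 5 * math.log(1 + k) + 1e-9


def test_result_summary_and_csv_output(nested_fixture, tmp_path):
    _, model, tasks, truth_sets, data, _ = nested_fixture
    sets = [
        TaskEssentialSet(
            t.id,
            True,
            sorted(truth_sets[t.id]),
            frozenset().union(*(model.reaction(r).genes for r in truth_sets[t.id])),
            {r: 1.0 for r in truth_sets[t.id]},
        )
        for t in tasks
    ]
    res = TaskActivityModel(data, sets, model).fit()
    text = res.summary()
    assert "active_fraction" in text and "T1" in text
    res.to_csv(tmp_path)
    out = pd.read_csv(tmp_path / "score.csv", index_col=0)
    assert out.shape == res.score.shape
    binary = pd.read_csv(tmp_path / "score_binary.csv", index_col=0)
    assert set(np.unique(binary.to_numpy())) <= {0, 1}
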