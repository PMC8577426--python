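# Methods

## Model and task formalism

A genome-scale metabolic model is a stoichiometric matrix S
(metabolites × reactions) with flux bounds l ≤ v ≤ u and a GPR rule per
reaction. A metabolic task declares substrate metabolites with maximum
uptake magnitudes and product metabolites with required minimum
production rates. Task inputs are stated as non-negative magnitudes —
quantities, not signed exchange fluxes — and converted internally: the
task environment adds an uptake column (+1 for the substrate, bounds
[lb, ub]) and a demand column (−1 for the product, lower-bounded by the
required production), while every model boundary reaction (recognized
as a single-metabolite reaction) is closed. Feasibility is a plain LP
feasibility question over S·v = 0 under those bounds.

Task metabolite ids are matched to the model namespace by exact id,
`id_c`/`id[c]` compartment spellings, a compartment-suffix-stripped
match, and an optional user alias map, in that order — model dialects
disagree on suffix conventions more often than on base ids.

## Essential-set extraction (pFBA)

Among feasible flux vectors the extraction minimizes Σ|v| over the
model's own reactions (task boundary columns are not penalized), with
each reversible reaction split into an irreversible pair — the standard
exact L1 encoding. The essential set is the reactions with |net flux| >
`flux_tolerance` (default 1e−6, the solver noise floor in the model's
flux units). Because the closed environment admits no side routes, the
L1 optimum traces the economical route for the task; for well-posed
task collections it is unique, but LP optima can degenerate, so a
second LP fixes the total-flux budget at the optimum (+1e−9 relative
slack) and re-minimizes with weights 1 + δ·rank(reaction id), δ = 1e−7,
ranking reactions lexicographically. This one-LP perturbation realizes
the same canonical intent as sequential lexicographic minimization at a
fraction of the cost and makes repeated extractions byte-identical.
Both LPs use scipy's HiGHS interior/simplex via `linprog`; infeasible
tasks return a typed infeasible result rather than raising, and batch
extraction collects per-task failures without aborting.

The task's gene set is every gene appearing syntactically in the
support reactions' GPRs — genes that *may* contribute — not only
determinant-reachable ones.

## GPR evaluation

Rules are parsed with AND binding tighter than OR (the convention of
constraint-based tooling; source rules relying on precedence are
accepted but ambiguous ones should be parenthesized upstream), and
evaluated numerically with min over AND, max over OR. Determinant ties
break toward the lexicographically smallest gene id: determinism
matters because significance counts determinants. Genes absent from the
data are dropped from their parent operator (unmeasured ≠ inactive); a
rule whose genes are all unmeasured is *undefined*, not zero. A
`missing="zero"` switch provides the alternative reading, under which
an unmeasured complex subunit zeroes its AND node.

## Thresholds and scores

Local thresholding clamps each gene's mean expression to the
`lower_pct`/`upper_pct` percentiles (defaults 25/75) of the overall
expression distribution. "Overall distribution" is ambiguous between
the per-gene means and the full gene×sample pool; the default is the
per-gene means (`distribution="gene_means"`), with `"all_values"` as a
switch. Global mode assigns one `global_pct` percentile (default 75) to
every gene. With fewer than two samples, local mode falls back to
global with a warning.

The gene score is 5·ln(1 + x/t) with the natural logarithm: the binary
cutoff 5·ln 2 is exactly the score of a gene at its threshold, so the
binary rule is base-free, but the continuous scale must be pinned and
natural log is the convention of the thresholding family this follows.
The binary rule is strict (mean RAL > 5·ln 2): a sample with every
determinant exactly at threshold is inactive.

Two deliberate readings where the procedure is underdetermined:

- **Significance scope and timing.** S(g) is computed per sample (the
  determinant of a reaction shifts with expression) over the union of
  unique reactions across all task essential sets — the metabolism the
  task map covers. Whole-model counting would require scoring
  reactions outside every task.
- **Score denominator.** The mean divides by the number of task
  reactions with a *defined* RAL (and reports coverage), because the
  literal task-size denominator silently drives scores toward zero on
  sparse data; `denominator="all"` restores the literal rule, and
  `min_coverage` marks under-measured tasks as undefined (NaN) instead
  of extrapolating.

Consequences worth knowing: all quantities are ratios to thresholds, so
the whole pipeline is invariant under global rescaling of the
expression matrix, and scores compare across samples within a task —
never across tasks, since tasks differ in their genes' baseline
expression.

## Downstream statistics

*Group similarity.* The observed statistic is the mean Euclidean
distance over all unordered within-group pairs of score columns (a
centroid variant would be possible but the pairwise mean is the natural
reading). The null draws `n_random` (default 10,000) uniformly random
same-size subsets from the pool of all entities in considered groups
(groups need ≥ 3 members), and the empirical p is the proportion of
null distances strictly below the observed — an exact permutation p
with no +1 correction; `plus_one=True` gives the conservative
(c+1)/(N+1) variant.

*Binary-combination clustering.* Samples are grouped by their exact
binary signature over the selected tasks (those active in strictly more
than a `fraction` of samples, default 0.5). Labels M1, M2, … follow
descending binary signature order (all-active first), so labelling is
deterministic. The cluster universe is 2^k; only realized signatures
are returned.

*Trait enrichment.* Per (cluster, trait level) a 2×2 table of
in/out-cluster × level/other is tested one-tailed for
over-representation (`scipy.stats.fisher_exact`, `alternative=
"greater"`, i.e. the hypergeometric upper tail). Samples without a
trait value are excluded pairwise; single-level traits are skipped.

*Patient aggregation.* Patients are ranked by the fraction of their
samples in target clusters; with binary labels, the top-k patients
(k = label prevalence) are called positive and the resulting accuracy
reported.

## Synthetic data generator

`make_toy_model` builds disjoint linear pathways (input exchange →
L conversion steps → product exchange), one task per pathway, GPRs of
selectable complexity (single gene, isozyme pair, two-gene complex, or
nested `(a and b) or c`), and optionally a strictly longer decoy bypass
per pathway so parsimonious extraction must discriminate routes. The
known minimal route per task is returned for oracle comparisons.

`make_expression` draws a log-normal baseline (scale 10, `noise_sd`
0.1 on the ln scale) and plants binary task activity: each task is
active in a sample with probability 0.5, scaling *all* genes of its
route by `activity_effect` (default 4×) when active and by its
reciprocal when inactive — planting every route gene keeps AND-based
rules responsive and the ground truth unambiguous. Defaults use 200
samples for recovery checks. The generator emulates none of the hard
features of real data — no dropout, batch effects, platform biases or
correlated pathways — so recovery results certify the pipeline's
internal correctness, not performance on real tissue or single-cell
data.

The packaged `data/curated_tasks_synthetic.csv` is a deterministic
synthetic instance of the canonical task-table layout (195 tasks over
the seven metabolic systems: energy, nucleotide, carbohydrates, amino
acid, lipid, vitamin & cofactor, glycan); it exercises the schema,
reader and counting logic and is not a biological resource.

## Numerical choices and limitations

- LP tolerances: flux support cutoff 1e−6; steady-state residual
  asserted below 1e−6 in tests; budget slack 1e−9 relative.
- Percentile computation uses numpy's default linear interpolation;
  threshold clamping is boundary-inclusive.
- Degenerate inputs: empty expression matrices, non-numeric or negative
  values, duplicate gene ids, tasks without a required output, and
  models with dangling references are rejected with typed errors.
- Problem sizes: oracle suites use toy models (≤ 12 internal reactions,
  exhaustive subset search), 1,000 random GPR trees, the full sweep of
  2×2 tables with margins ≤ 30, and 200-sample recovery runs — sizes at
  which the independent oracles are exact and fast.
- Not covered: thermodynamic/loopless constraints, growth-objective
  FBA, negative-control ("should fail") task semantics, proteomics or
  chromatin-accessibility inputs, expression normalization or batch
  correction (upstream responsibilities), and isoenzyme-specific
  activity weighting.
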