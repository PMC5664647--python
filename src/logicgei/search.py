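"""Logic-regression model fitting by simulated annealing.

A logic model is a small set of Boolean trees entering a regression
linearly: logit(P(case)) = b0 + sum_j b_j T_j(x) for the case-control
endpoint, or an exponential survival model log(rate) = b0 + sum_j b_j
T_j(x) for the survival endpoint (cases only).  Model fit is scored by
deviance (-2 log-likelihood); tree space is searched by simulated
annealing over the standard move set; model size (number of trees and
total leaves) is chosen by stratified cross-validation.

Step 1 builds one gene-specific tree (GST) per gene from the gene's
indicator columns; Step 2 runs the same machinery over the GST columns
to build pathway trees used downstream as adjustment covariates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .glm import GlmFit, fit_binomial, fit_exponential
from .trees import LogicTree, propose_move, random_leaf_tree
from .io_encoding import IndicatorMatrix

log = logging.getLogger(__name__)

__all__ = [
    "AnnealSchedule",
    "LogicModel",
    "CVSelection",
    "GST",
    "score_logit",
    "score_exponential",
    "anneal",
    "cv_select",
    "build_gst",
    "build_pathway_trees",
    "DEFAULT_GRID",
]

#: model-size grid: (n_trees, max_total_leaves)
DEFAULT_GRID: list[tuple[int, int]] = [
    (t, l) for t in (1, 2) for l in range(1, 9) if l >= t
]


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule for the annealer.

    ``start_temperature=None`` calibrates the start so that roughly 90%
    of initial uphill moves are accepted.
    """

    start_temperature: float | None = None
    cooling: float = 0.999
    n_iterations: int = 25_000
    n_restarts: int = 10

    def __post_init__(self):
        if self.start_temperature is not None and self.start_temperature <= 0:
            raise ValueError("start_temperature must be positive")
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling must be in (0, 1)")
        if self.n_iterations < 0 or self.n_restarts < 1:
            raise ValueError("bad iteration/restart counts")


@dataclass
class LogicModel:
    trees: list[LogicTree]
    coefficients: np.ndarray  # intercept first
    link: str  # "logit" | "exponential_survival"
    score: float  # deviance / -2 loglik
    separated: bool = False

    def evaluate_trees(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([t.evaluate(X) for t in self.trees])


@dataclass
class CVSelection:
    grid: list[tuple[int, int]]
    folds: int
    mean_scores: dict[tuple[int, int], float]
    chosen: tuple[int, int]


@dataclass
class GST:
    """Gene-specific tree: the best single tree summarising one gene."""

    gene: str
    tree: LogicTree
    complement: LogicTree
    coefficient: float
    prevalence: float
    column_names: list[str] = field(default_factory=list)
    degenerate: bool = False
    cv: CVSelection | None = None

    def indicator(self, X_gene: np.ndarray) -> np.ndarray:
        return self.tree.evaluate(X_gene)

    def to_text(self) -> str:
        return self.tree.to_text(self.column_names or None)

    def complement_text(self) -> str:
        return self.complement.to_text(self.column_names or None)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _pattern_aggregate(Z: np.ndarray):
    """Collapse binary tree columns to unique patterns with row weights.

    Returns (patterns k x p, group index per row) so a GLM over n rows is
    fit on at most 2**p pattern rows.
    """
    if Z.shape[1] == 0:
        return np.zeros((1, 0)), np.zeros(Z.shape[0], dtype=np.intp)
    code = Z @ (1 << np.arange(Z.shape[1]))
    uniq, inv = np.unique(code, return_inverse=True)
    patterns = ((uniq[:, None] >> np.arange(Z.shape[1])) & 1).astype(float)
    return patterns, inv


def score_logit(trees: list[LogicTree], y: np.ndarray, X) -> tuple[float, GlmFit]:
    """Deviance of the logistic logic model at its MLE.

    Rows are aggregated over unique tree-value patterns, so the fit cost
    is independent of subject count once the trees are evaluated.
    """
    values = X.values if isinstance(X, IndicatorMatrix) else np.asarray(X)
    y = np.asarray(y, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one subject of each outcome class")
    Z = (
        np.column_stack([t.evaluate(values) for t in trees])
        if trees
        else np.zeros((len(y), 0), dtype=np.uint8)
    )
    patterns, inv = _pattern_aggregate(Z)
    k = np.bincount(inv, weights=y, minlength=len(patterns))
    n = np.bincount(inv, minlength=len(patterns)).astype(float)
    design = np.column_stack([np.ones(len(patterns)), patterns])
    fit = fit_binomial(design, k, n)
    return fit.deviance, fit


def score_exponential(
    trees: list[LogicTree], time: np.ndarray, event: np.ndarray, X
) -> tuple[float, GlmFit]:
    """-2 log-likelihood of the exponential survival logic model."""
    values = X.values if isinstance(X, IndicatorMatrix) else np.asarray(X)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if event.sum() == 0:
        raise ValueError("all-censored data: no exponential MLE")
    Z = (
        np.column_stack([t.evaluate(values) for t in trees])
        if trees
        else np.zeros((len(time), 0), dtype=np.uint8)
    )
    patterns, inv = _pattern_aggregate(Z)
    d = np.bincount(inv, weights=event, minlength=len(patterns))
    t = np.bincount(inv, weights=time, minlength=len(patterns))
    design = np.column_stack([np.ones(len(patterns)), patterns])
    fit = fit_exponential(design, d, t)
    return fit.deviance, fit


@dataclass
class _Outcome:
    """Bound outcome + link, exposing score(trees) and held-out deviance."""

    link: str
    y: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None

    def score(self, trees, values) -> tuple[float, GlmFit]:
        if self.link == "logit":
            return score_logit(trees, self.y, values)
        return score_exponential(trees, self.time, self.event, values)

    def subset(self, idx) -> "_Outcome":
        if self.link == "logit":
            return _Outcome("logit", y=self.y[idx])
        return _Outcome(self.link, time=self.time[idx], event=self.event[idx])

    def strata_labels(self) -> np.ndarray:
        return self.y if self.link == "logit" else self.event

    def validation_deviance(self, trees, beta, values) -> float:
        Z = (
            np.column_stack([t.evaluate(values) for t in trees])
            if trees
            else np.zeros((len(self.strata_labels()), 0))
        )
        eta = beta[0] + Z @ beta[1:]
        if self.link == "logit":
            log1p = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
            return float(-2.0 * (self.y @ eta - log1p.sum()))
        return float(-2.0 * (self.event @ eta - (np.exp(eta) * self.time).sum()))


def make_outcome(link: str, *, y=None, time=None, event=None) -> _Outcome:
    if link == "logit":
        return _Outcome("logit", y=np.asarray(y, dtype=float))
    if link == "exponential_survival":
        return _Outcome(
            link, time=np.asarray(time, dtype=float), event=np.asarray(event, dtype=float)
        )
    raise ValueError(f"unknown link {link!r}")


# ---------------------------------------------------------------------------
# Annealing
# ---------------------------------------------------------------------------


def _estimate_start_temperature(score_fn, state, values, n_columns, max_leaves, rng):
    """Start temperature giving ~90% acceptance of initial uphill moves."""
    base, _ = score_fn(state, values)
    deltas = []
    for _ in range(50):
        i = int(rng.integers(len(state)))
        prop = propose_move(state[i], n_columns, rng, max_leaves=max_leaves)
        if prop is None:
            continue
        cand = list(state)
        cand[i] = prop[0]
        s, _ = score_fn(cand, values)
        if s > base:
            deltas.append(s - base)
    if not deltas:
        return 1.0
    return float(np.mean(deltas) / math.log(1.0 / 0.9))


def anneal(
    X,
    outcome: _Outcome,
    size: tuple[int, int],
    schedule: AnnealSchedule,
    rng: np.random.Generator,
) -> LogicModel:
    """Simulated-annealing search for the best-scoring logic model.

    ``size`` is (n_trees, max_total_leaves).  Metropolis acceptance on
    the deviance with geometric cooling; the best model visited across
    all restarts is returned.  Deterministic given the generator state.
    """
    values = X.values if isinstance(X, IndicatorMatrix) else np.asarray(X)
    n_trees, max_total_leaves = size
    if n_trees < 1 or max_total_leaves < n_trees:
        raise ValueError("size must allow at least one leaf per tree")
    n_columns = values.shape[1]

    def score_fn(trees, vals):
        return outcome.score(trees, vals)

    best_score = math.inf
    best_trees: list[LogicTree] | None = None
    best_fit: GlmFit | None = None

    for _ in range(schedule.n_restarts):
        state = [random_leaf_tree(n_columns, rng) for _ in range(n_trees)]
        cur_score, cur_fit = score_fn(state, values)
        if cur_score < best_score:
            best_score, best_trees, best_fit = cur_score, list(state), cur_fit
        T = schedule.start_temperature
        if T is None:
            T = _estimate_start_temperature(
                score_fn, state, values, n_columns, max_total_leaves, rng
            )
        for _ in range(schedule.n_iterations):
            i = int(rng.integers(n_trees))
            other_leaves = sum(t.n_leaves for j, t in enumerate(state) if j != i)
            prop = propose_move(
                state[i], n_columns, rng, max_leaves=max_total_leaves - other_leaves
            )
            if prop is not None:
                cand = list(state)
                cand[i] = prop[0]
                cand_score, cand_fit = score_fn(cand, values)
                delta = cand_score - cur_score
                if delta <= 0 or (T > 0 and rng.random() < math.exp(-delta / T)):
                    state, cur_score, cur_fit = cand, cand_score, cand_fit
                    if cur_score < best_score:
                        best_score, best_trees, best_fit = cur_score, list(state), cur_fit
            T *= schedule.cooling
    assert best_trees is not None and best_fit is not None
    return LogicModel(
        trees=[t.canonical() for t in best_trees],
        coefficients=best_fit.beta.copy(),
        link=outcome.link,
        score=best_score,
        separated=best_fit.separated,
    )


# ---------------------------------------------------------------------------
# Cross-validation size selection
# ---------------------------------------------------------------------------


def _stratified_folds(labels: np.ndarray, folds: int, rng: np.random.Generator):
    """Fold assignment stratified by a binary label, from a seeded shuffle."""
    assign = np.empty(len(labels), dtype=int)
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        idx = idx[rng.permutation(len(idx))]
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def cv_select(
    X,
    outcome: _Outcome,
    grid: list[tuple[int, int]],
    folds: int,
    schedule: AnnealSchedule,
    rng: np.random.Generator,
) -> CVSelection:
    """Choose model size by stratified K-fold validation deviance.

    Stratification is by outcome class (logit) or event indicator
    (survival); the chosen size minimises mean validation deviance, ties
    resolved toward fewer total leaves then fewer trees.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if not grid:
        raise ValueError("empty size grid")
    values = X.values if isinstance(X, IndicatorMatrix) else np.asarray(X)
    labels = outcome.strata_labels()
    if outcome.link == "logit":
        if min((labels == 1).sum(), (labels == 0).sum()) < folds:
            raise ValueError("a fold would contain a single outcome class")
    elif (labels == 1).sum() < folds:
        raise ValueError("a fold would contain no events")
    assign = _stratified_folds(labels, folds, rng)

    mean_scores: dict[tuple[int, int], float] = {}
    for size in grid:
        scores = []
        for f in range(folds):
            train, valid = assign != f, assign == f
            model = anneal(values[train], outcome.subset(train), size, schedule, rng)
            scores.append(
                outcome.subset(valid).validation_deviance(
                    model.trees, model.coefficients, values[valid]
                )
            )
        mean_scores[size] = float(np.mean(scores))

    chosen = min(grid, key=lambda s: (mean_scores[s], s[1], s[0]))
    return CVSelection(list(grid), folds, mean_scores, chosen)


# ---------------------------------------------------------------------------
# Step 1 / Step 2 builders
# ---------------------------------------------------------------------------


def build_gst(
    gene: str,
    X_gene: np.ndarray,
    outcome: _Outcome,
    schedule: AnnealSchedule,
    rng: np.random.Generator,
    grid: list[tuple[int, int]] | None = None,
    folds: int = 10,
    column_names: list[str] | None = None,
) -> GST:
    """Build the gene-specific tree for one gene.

    Runs CV size selection then a full-data annealing fit restricted to
    the gene's indicator columns; the single best tree (largest
    |coefficient| if the selected model has two) becomes the GST,
    returned with its De Morgan complement, coefficient and prevalence.
    Monomorphic genes are flagged degenerate and excluded downstream.
    """
    X_gene = np.asarray(X_gene)
    if X_gene.shape[1] == 0 or np.all(X_gene == X_gene[0:1, :]):
        dummy = LogicTree.from_json('{"col": 0, "neg": false}')
        return GST(gene, dummy, dummy.complement(), 0.0, 0.0, degenerate=True,
                   column_names=list(column_names or []))
    # drop constant columns from the grid's reach implicitly: search works anyway
    grid = grid if grid is not None else DEFAULT_GRID
    grid = [s for s in grid if s[1] <= 2 * X_gene.shape[1]] or [grid[0]]
    cv = (
        cv_select(X_gene, outcome, grid, folds, schedule, rng)
        if len(grid) > 1
        else CVSelection(grid, folds, {grid[0]: math.nan}, grid[0])
    )
    model = anneal(X_gene, outcome, cv.chosen, schedule, rng)
    coefs = model.coefficients[1:]
    best = int(np.argmax(np.abs(coefs)))
    if len(model.trees) > 1:
        log.info("gene %s: CV chose %d trees; keeping tree with |coef| %.3f",
                 gene, len(model.trees), abs(coefs[best]))
    tree = model.trees[best]
    ind = tree.evaluate(X_gene)
    prev = float(ind.mean())
    if prev in (0.0, 1.0):  # tautology/contradiction tree: no information
        return GST(gene, tree, tree.complement().canonical(), 0.0, prev,
                   column_names=list(column_names or []), degenerate=True, cv=cv)
    return GST(
        gene=gene,
        tree=tree,
        complement=tree.complement().canonical(),
        coefficient=float(coefs[best]),
        prevalence=prev,
        column_names=list(column_names or []),
        cv=cv,
    )


def build_gsts(
    indicators: IndicatorMatrix,
    outcome: _Outcome,
    schedule: AnnealSchedule,
    rng_for_gene,
    grid: list[tuple[int, int]] | None = None,
    folds: int = 10,
    genes: list[str] | None = None,
) -> dict[str, GST]:
    """Step 1 over every gene; ``rng_for_gene(gene)`` supplies a stream."""
    out: dict[str, GST] = {}
    gene_order = genes or list(dict.fromkeys(indicators.gene_of_snp.values()))
    for gene in gene_order:
        X_gene, cols = indicators.gene_slice(gene)
        names = [f"{rs}:{kind}" for rs, kind in cols]
        out[gene] = build_gst(
            gene, X_gene, outcome, schedule, rng_for_gene(gene),
            grid=grid, folds=folds, column_names=names,
        )
    return out


def build_pathway_trees(
    gst_matrix: np.ndarray,
    gst_names: list[str],
    outcome: _Outcome,
    schedule: AnnealSchedule,
    rng: np.random.Generator,
    grid: list[tuple[int, int]] | None = None,
    folds: int = 10,
) -> LogicModel:
    """Step 2: logic regression whose leaves are GST indicator columns."""
    gst_matrix = np.asarray(gst_matrix)
    if gst_matrix.shape[1] < 2:
        raise ValueError("need at least 2 non-degenerate GSTs for pathway trees")
    grid = grid if grid is not None else DEFAULT_GRID
    cv = (
        cv_select(gst_matrix, outcome, grid, folds, schedule, rng)
        if len(grid) > 1
        else CVSelection(grid, folds, {grid[0]: math.nan}, grid[0])
    )
    model = anneal(gst_matrix, outcome, cv.chosen, schedule, rng)
    return model


def gst_matrix(
    gsts: dict[str, GST], indicators: IndicatorMatrix
) -> tuple[np.ndarray, list[str]]:
    """Stack non-degenerate GST indicator columns (subjects x genes)."""
    cols, names = [], []
    for gene, gst in gsts.items():
        if gst.degenerate:
            continue
        X_gene, _ = indicators.gene_slice(gene)
        cols.append(gst.indicator(X_gene))
        names.append(gene)
    if not cols:
        return np.zeros((len(indicators.subject_ids), 0), dtype=np.uint8), []
    return np.column_stack(cols), names
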