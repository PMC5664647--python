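"""Step 3: adjusted gene-environment interaction models and permutation test.

Each candidate interaction crosses one gene-specific tree (GST) with one
non-reference level of an environmental exposure.  Risk models are
logistic regressions over all subjects; survival models are Cox
proportional-hazards regressions over cases only, with the baseline
hazard stratified by SEER stage.  Every model keeps the interaction
hierarchy (GST and exposure main effects are never dropped) and adjusts
for age, sex, race, study center and the Step-2 pathway trees.

Sub-pathway interaction sets are reduced by backward selection (drop the
single least significant interaction until all remaining have p <= the
threshold); the survivors from all sub-pathways are then tested jointly
in one full-pathway model.  The multiple-testing correction permutes the
0/1 GST columns and the three exposure columns across subjects and
repeats the whole of Step 3, comparing the observed count of significant
interactions with its permutation distribution.

A GST and its De Morgan complement parameterise the same interaction
test once the main effects are present (complement = 1 - GST), so each
(gene, exposure, level) pair is fitted once and the reported orientation
is chosen to give an interaction odds/hazard ratio above 1, matching the
convention of reporting complementary trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import fit_logistic
from .io_encoding import EXPOSURE_LEVELS, RACE_LEVELS, STAGE_LEVELS

log = logging.getLogger(__name__)

__all__ = [
    "Term",
    "GEITerm",
    "GEIFit",
    "Step3Data",
    "Step3Result",
    "PermutationSummary",
    "SingularDesignError",
    "fit_risk_model",
    "fit_survival_model",
    "backward_select_subpathway",
    "joint_final_model",
    "run_step3",
    "permutation_test",
    "all_candidate_terms",
]

Z975 = stats.norm.ppf(0.975)


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient; message names offending columns."""


@dataclass(frozen=True, order=True)
class Term:
    gene: str
    exposure: str
    level: str

    @property
    def name(self) -> str:
        return f"{self.gene}:{self.exposure}={self.level}"


@dataclass
class GEITerm:
    term: Term
    estimate: float  # log-OR / log-HR of the interaction, GST orientation
    se: float
    p: float
    flipped: bool = False  # True when reported via the complement GST
    separated: bool = False

    @property
    def reported_estimate(self) -> float:
        return -self.estimate if self.flipped else self.estimate

    @property
    def ratio(self) -> float:
        """OR_INT / HR_INT in the reported orientation."""
        return float(np.exp(self.reported_estimate))

    @property
    def ci95(self) -> tuple[float, float]:
        e = self.reported_estimate
        return (float(np.exp(e - Z975 * self.se)), float(np.exp(e + Z975 * self.se)))


@dataclass
class GEIFit:
    endpoint: str  # "risk" | "survival"
    terms: dict[Term, GEITerm]
    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    n_obs: int
    separated: bool = False
    flags: list[str] = field(default_factory=list)

    def stratum_gene_ratio(self, term: Term) -> float:
        """Gene OR/HR within the exposed stratum: exp(beta_GST + beta_INT)."""
        return float(np.exp(self.params[f"gst_{term.gene}"] + self.params[term.name]))

    def significant(self, threshold: float = 0.05) -> list[Term]:
        return sorted(t for t, gt in self.terms.items() if gt.p <= threshold)


@dataclass
class PermutationSummary:
    n_permutations: int
    observed_count: int
    counts: list[int]
    seed: int | None = None

    @property
    def empirical_p(self) -> float:
        c = np.asarray(self.counts)
        return float((c >= self.observed_count).sum() / len(c))


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def _exposure_dummies(exposures: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for name, levels in EXPOSURE_LEVELS.items():
        for lv in levels[1:]:
            cols[f"{name}={lv}"] = (exposures[name] == lv).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=exposures.index)


def _covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    cols = {"age": covariates["age"].to_numpy(dtype=float)}
    cols["sex_male"] = (covariates["sex"] == "male").to_numpy(dtype=float)
    for lv in RACE_LEVELS[1:]:
        cols[f"race_{lv}"] = (covariates["race"] == lv).to_numpy(dtype=float)
    cols["center_utah"] = (covariates["center"] == "utah").to_numpy(dtype=float)
    return pd.DataFrame(cols, index=covariates.index)


def build_design(
    genes: list[str],
    gst_cols: dict[str, np.ndarray],
    exposures: pd.DataFrame,
    covariates: pd.DataFrame | None,
    pathway_cols: np.ndarray | None,
    terms: list[Term],
) -> pd.DataFrame:
    """Model matrix with hierarchy: mains for every gene and exposure level,
    adjustment covariates, pathway trees, then one product column per term."""
    n = len(exposures)
    parts: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    for g in genes:
        parts[f"gst_{g}"] = np.asarray(gst_cols[g], dtype=float)
    expo = _exposure_dummies(exposures)
    for c in expo.columns:
        parts[c] = expo[c].to_numpy()
    if covariates is not None:
        cov = _covariate_design(covariates)
        for c in cov.columns:
            parts[c] = cov[c].to_numpy()
    if pathway_cols is not None:
        pw = np.atleast_2d(np.asarray(pathway_cols, dtype=float))
        if pw.shape[0] != n:
            pw = pw.T
        # a pathway tree collinear with the main-effect design (e.g. a
        # single-leaf tree duplicating a GST) is a redundant adjustment:
        # drop it rather than poisoning every downstream fit
        base = np.column_stack(list(parts.values()))
        base_rank = np.linalg.matrix_rank(base)
        for j in range(pw.shape[1]):
            trial = np.column_stack([base, pw[:, j]])
            if np.linalg.matrix_rank(trial) > base_rank:
                parts[f"pathway_tree_{j}"] = pw[:, j]
                base, base_rank = trial, base_rank + 1
            else:
                log.info("dropping pathway tree %d: collinear with main effects", j)
    for t in terms:
        if t.gene not in gst_cols:
            raise KeyError(f"term {t.name} references gene without a GST column")
        parts[t.name] = parts[f"gst_{t.gene}"] * expo[f"{t.exposure}={t.level}"].to_numpy()
    return pd.DataFrame(parts, index=exposures.index)


def _check_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal set of offending columns
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                bad.append(design.columns[j])
            else:
                keep.append(j)
        raise SingularDesignError(
            f"singular design; collinear columns: {bad}"
        )


# ---------------------------------------------------------------------------
# Risk (logistic) endpoint
# ---------------------------------------------------------------------------


def fit_risk_model(
    genes: list[str],
    gst_cols: dict[str, np.ndarray],
    exposures: pd.DataFrame,
    covariates: pd.DataFrame | None,
    pathway_cols: np.ndarray | None,
    y: np.ndarray,
    terms: list[Term],
) -> GEIFit:
    """Adjusted logistic GEI model over all subjects.

    Reports, per interaction term, OR_INT = exp(coefficient) with Wald
    95% CI and p, plus the stratum-specific gene OR exp(b_GST + b_INT).
    Separation is flagged per term rather than silently reported.
    """
    design = build_design(genes, gst_cols, exposures, covariates, pathway_cols, terms)
    y = np.asarray(y, dtype=float)
    n_params = design.shape[1]
    if len(y) < 10 * n_params:
        log.warning("only %d rows for %d parameters", len(y), n_params)
    _check_rank(design)
    fit = fit_logistic(design.to_numpy(), y)
    params = pd.Series(fit.beta, index=design.columns)
    se = pd.Series(fit.se, index=design.columns)
    z = params / se
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=design.columns)
    gei_terms = {}
    for t in terms:
        est, s, p = float(params[t.name]), float(se[t.name]), float(pvals[t.name])
        sep = fit.separated and abs(est) > 10
        gei_terms[t] = GEITerm(t, est, s, p, flipped=est < 0, separated=sep)
    return GEIFit("risk", gei_terms, params, se, pvals, len(y), fit.separated)


# ---------------------------------------------------------------------------
# Survival (stratified Cox) endpoint
# ---------------------------------------------------------------------------


def fit_survival_model(
    genes: list[str],
    gst_cols: dict[str, np.ndarray],
    exposures: pd.DataFrame,
    covariates: pd.DataFrame | None,
    pathway_cols: np.ndarray | None,
    time: np.ndarray,
    event: np.ndarray,
    stage: pd.Series | np.ndarray,
    terms: list[Term],
) -> GEIFit:
    """Stage-stratified Cox GEI model over cases (Efron tie handling).

    Strata without events are dropped (they contribute nothing to the
    partial likelihood); monotone-likelihood terms are flagged via the
    same separation sentinel as the logistic endpoint.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    design = build_design(genes, gst_cols, exposures, covariates, pathway_cols, terms)
    design = design.drop(columns="intercept")  # absorbed by baseline hazard
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events in survival data")
    stage = pd.Series(np.asarray(stage, dtype=object), index=design.index, name="stage")

    df = design.copy()
    df["duration"] = time
    df["event"] = event
    df["stage"] = stage.astype(str).to_numpy()
    # drop eventless strata explicitly
    ev_by_stratum = df.groupby("stage")["event"].sum()
    keep = df["stage"].map(ev_by_stratum) > 0
    if not keep.all():
        log.info("dropping %d subjects in eventless strata", int((~keep).sum()))
        df = df[keep]
    _check_rank(df.drop(columns=["duration", "event", "stage"]).assign(_one=1.0))

    cph = CoxPHFitter()
    flags: list[str] = []
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            cph.fit(df, duration_col="duration", event_col="event", strata=["stage"])
    except ConvergenceError as err:
        raise SingularDesignError(f"Cox model did not converge: {err}") from err
    params = cph.params_.copy()
    se = cph.standard_errors_.copy()
    pvals = cph.summary["p"].copy()
    separated = bool(np.any(np.abs(params) > 15))
    gei_terms = {}
    for t in terms:
        est, s, p = float(params[t.name]), float(se[t.name]), float(pvals[t.name])
        sep = abs(est) > 10 and separated
        gei_terms[t] = GEITerm(t, est, s, p, flipped=est < 0, separated=sep)
    return GEIFit("survival", gei_terms, params, se, pvals, len(df), separated, flags)


# ---------------------------------------------------------------------------
# Backward selection / joint model / permutation
# ---------------------------------------------------------------------------


def all_candidate_terms(genes: list[str]) -> list[Term]:
    """Every (gene, exposure, non-reference level) combination."""
    return [
        Term(g, e, lv)
        for g in genes
        for e, levels in EXPOSURE_LEVELS.items()
        for lv in levels[1:]
    ]


def _viable_terms(terms, gst_cols, exposures) -> list[Term]:
    """Drop terms whose product column cannot be estimated (no variation
    or exactly duplicating a main effect)."""
    expo = _exposure_dummies(exposures)
    out = []
    for t in terms:
        g = np.asarray(gst_cols[t.gene], dtype=float)
        e = expo[f"{t.exposure}={t.level}"].to_numpy()
        prod = g * e
        if prod.sum() == 0 or np.array_equal(prod, g) or np.array_equal(prod, e):
            log.info("dropping inestimable candidate term %s", t.name)
            continue
        out.append(t)
    return out


def backward_select_subpathway(
    fit_fn,
    candidates: list[Term],
    threshold: float = 0.05,
    prevalence: dict[Term, float] | None = None,
) -> tuple[list[Term], GEIFit | None]:
    """Backward selection over a sub-pathway's interaction terms.

    Refits and removes the single highest-p interaction (ties broken by
    smaller |estimate|, then term name) until every remaining term has
    p <= threshold.  Main effects and adjustments are never dropped.
    If the initial model is unfittable, terms are dropped one at a time
    (lowest interaction-column prevalence first) until it fits.
    """
    current = sorted(candidates)
    fit = None
    while current:
        try:
            fit = fit_fn(current)
        except (SingularDesignError, np.linalg.LinAlgError) as err:
            if prevalence:
                dropped = min(current, key=lambda t: (prevalence.get(t, 0.0), t.name))
            else:
                dropped = current[-1]
            log.warning("unfittable model (%s); dropping %s", err, dropped.name)
            current = [t for t in current if t != dropped]
            fit = None
            continue
        worst = max(
            fit.terms.values(),
            key=lambda gt: (gt.p, -abs(gt.estimate), gt.term.name),
        )
        if worst.p <= threshold:
            return current, fit
        current = [t for t in current if t != worst.term]
    return [], fit


def joint_final_model(
    fit_fn,
    retained: list[Term],
    threshold: float = 0.05,
) -> tuple[GEIFit | None, list[Term]]:
    """Joint full-pathway test of all sub-pathway survivors.

    Returns the joint fit and the final significant set (p <= threshold).
    An empty survivor set yields (None, [])."""
    retained = sorted(set(retained))
    if not retained:
        return None, []
    fit = fit_fn(retained)
    return fit, fit.significant(threshold)


@dataclass
class Step3Data:
    """Everything Step 3 needs, endpoint-agnostic."""

    gst_cols: dict[str, np.ndarray]  # gene -> 0/1 indicator over subjects
    exposures: pd.DataFrame
    covariates: pd.DataFrame | None
    pathway_cols: np.ndarray | None
    subpathways: dict[str, list[str]]
    y: np.ndarray | None = None  # risk endpoint
    time: np.ndarray | None = None  # survival endpoint (cases only)
    event: np.ndarray | None = None
    stage: pd.Series | None = None
    threshold: float = 0.05

    def genes(self) -> list[str]:
        return list(self.gst_cols)

    def make_fit_fn(self, endpoint: str, genes: list[str]):
        if endpoint == "risk":
            return lambda terms: fit_risk_model(
                genes, self.gst_cols, self.exposures, self.covariates,
                self.pathway_cols, self.y, terms,
            )
        if endpoint == "survival":
            return lambda terms: fit_survival_model(
                genes, self.gst_cols, self.exposures, self.covariates,
                self.pathway_cols, self.time, self.event, self.stage, terms,
            )
        raise ValueError(f"unknown endpoint {endpoint!r}")


@dataclass
class Step3Result:
    endpoint: str
    retained_by_subpathway: dict[str, list[Term]]
    joint_fit: GEIFit | None
    significant: list[Term]

    @property
    def count(self) -> int:
        return len(self.significant)


def run_step3(data: Step3Data, endpoint: str) -> Step3Result:
    """Sub-pathway backward selection followed by the joint pathway model."""
    retained_by_sp: dict[str, list[Term]] = {}
    for sp, sp_genes in data.subpathways.items():
        sp_genes = [g for g in sp_genes if g in data.gst_cols]
        if not sp_genes:
            retained_by_sp[sp] = []
            continue
        candidates = _viable_terms(
            all_candidate_terms(sp_genes), data.gst_cols, data.exposures
        )
        expo = _exposure_dummies(data.exposures)
        prevalence = {
            t: float(
                (
                    np.asarray(data.gst_cols[t.gene], dtype=float)
                    * expo[f"{t.exposure}={t.level}"].to_numpy()
                ).mean()
            )
            for t in candidates
        }
        fit_fn = data.make_fit_fn(endpoint, sp_genes)
        retained, _ = backward_select_subpathway(
            fit_fn, candidates, data.threshold, prevalence
        )
        retained_by_sp[sp] = retained
    survivors = sorted({t for ts in retained_by_sp.values() for t in ts})
    joint_genes = sorted({t.gene for t in survivors}) or data.genes()[:1]
    joint_fn = data.make_fit_fn(endpoint, joint_genes)
    joint_fit, significant = joint_final_model(joint_fn, survivors, data.threshold)
    return Step3Result(endpoint, retained_by_sp, joint_fit, significant)


def permutation_test(
    data: Step3Data,
    endpoint: str,
    n_permutations: int,
    rng: np.random.Generator,
    observed_count: int | None = None,
) -> PermutationSummary:
    """Permutation-based multiple-testing correction for Step 3.

    Each run independently permutes every GST 0/1 column and each of the
    three exposure columns across subjects (outcome, covariates and
    pathway trees stay fixed) — preserving every marginal prevalence
    exactly while destroying any association — and repeats the whole of
    Step 3.  The empirical p is the fraction of runs whose count of
    significant interactions reaches the observed count.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if observed_count is None:
        observed_count = run_step3(data, endpoint).count
    n = len(data.exposures)
    counts: list[int] = []
    # one independent stream per permutation index: results are identical
    # however the runs are scheduled or distributed
    streams = rng.spawn(n_permutations)
    for b, rng_b in enumerate(streams):
        gst_perm = {
            g: np.asarray(col)[rng_b.permutation(n)] for g, col in data.gst_cols.items()
        }
        expo_perm = pd.DataFrame(
            {
                name: data.exposures[name].to_numpy()[rng_b.permutation(n)]
                for name in EXPOSURE_LEVELS
            },
            index=data.exposures.index,
        )
        for name in EXPOSURE_LEVELS:
            expo_perm[name] = pd.Categorical(
                expo_perm[name], categories=list(EXPOSURE_LEVELS[name])
            )
        perm_data = Step3Data(
            gst_cols=gst_perm,
            exposures=expo_perm,
            covariates=data.covariates,
            pathway_cols=data.pathway_cols,
            subpathways=data.subpathways,
            y=data.y,
            time=data.time,
            event=data.event,
            stage=data.stage,
            threshold=data.threshold,
        )
        try:
            counts.append(run_step3(perm_data, endpoint).count)
        except (SingularDesignError, ValueError) as err:
            log.warning("permutation %d unfittable (%s); recording count 0", b, err)
            counts.append(0)
    return PermutationSummary(n_permutations, observed_count, counts)
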