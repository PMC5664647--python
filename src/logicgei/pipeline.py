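"""End-to-end orchestration: simulate -> encode -> GSTs -> pathway -> GEI -> permute.

Runs the three analysis steps for one or both endpoints from a single
config with hierarchical seeding (master seed -> independent per-stage,
per-gene and per-permutation streams, so e.g. adding permutations never
changes the GST search) and writes TSV/JSON artifacts plus a manifest.
Re-running an identical config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gei as gei_mod
from . import search as search_mod
from .gei import PermutationSummary, Step3Data, Step3Result, Term
from .io_encoding import (
    EXPOSURE_LEVELS,
    PathwayConfig,
    default_pathway_config,
    derive_exposures,
    descriptive_table,
    encode_genotypes,
    load_pathway_config,
    read_genotypes_tsv,
    read_genotypes_vcf,
    read_phenotypes,
)
from .search import GST, AnnealSchedule, LogicModel, build_gsts, gst_matrix, make_outcome
from .trees import LogicTree

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "PipelineState", "run_pipeline", "render_tree_genotypes"]

# fixed stream constants for hierarchical seeding
_STREAM_GST = 11
_STREAM_PATHWAY = 12
_STREAM_PERMUTE = 13


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class RunConfig:
    genotypes: str | None = None
    phenotypes: str | None = None
    pathway: str | None = None  # None -> packaged angiogenesis pathway
    out: str = "run_out"
    endpoints: tuple[str, ...] = ("risk", "survival")
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    cv_grid: list[tuple[int, int]] | None = None
    cv_folds: int = 10
    threshold: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    simulate: bool = False  # generate inputs instead of reading files

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0 (0 disables)")
        for e in self.endpoints:
            if e not in ("risk", "survival"):
                raise ValueError(f"unknown endpoint {e!r}")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sched = raw.pop("schedule", None)
        cfg = cls(**raw)
        if sched:
            cfg.schedule = AnnealSchedule(**sched)
        return cfg


@dataclass
class PipelineState:
    config: RunConfig
    pathway_config: PathwayConfig | None = None
    genotypes: object = None
    phenotypes: pd.DataFrame | None = None
    exposures: pd.DataFrame | None = None
    indicators: object = None
    gsts: dict[str, dict[str, GST]] = field(default_factory=dict)  # endpoint -> gene -> GST
    pathway_trees: dict[str, LogicModel] = field(default_factory=dict)
    step3: dict[str, Step3Result] = field(default_factory=dict)
    permutation: dict[str, PermutationSummary] = field(default_factory=dict)
    artifacts: dict[str, Path] = field(default_factory=dict)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def _stable_gene_id(gene: str) -> int:
    return int.from_bytes(hashlib.sha256(gene.encode()).digest()[:4], "big")


def _write(path: Path, text: str) -> Path:
    """Write via a .partial temp name; rename only once complete."""
    tmp = path.with_suffix(path.suffix + ".partial")
    tmp.write_text(text)
    tmp.rename(path)
    return path


# ---------------------------------------------------------------------------
# Genotype-label rendering (published-table style leaf labels)
# ---------------------------------------------------------------------------


def _leaf_genotypes(kind: str, neg: bool, minor: str, major: str) -> str:
    # heterozygote written minor-then-major; homozygous-minor listed first
    mm, mM, MM = minor + minor, minor + major, major + major
    sets = {
        ("dom", False): [mm, mM],
        ("dom", True): [MM],
        ("rec", False): [mm],
        ("rec", True): [mM, MM],
    }
    return " or ".join(sets[(kind, neg)])


def render_tree_genotypes(
    tree: LogicTree, columns: list[tuple[str, str]], alleles: dict[str, dict[str, str]]
) -> str:
    """Render a tree with genotype labels, e.g. ``rs470215 (TT or TC)``."""
    from .trees import Leaf

    def fmt(node):
        if isinstance(node, Leaf):
            rs, kind = columns[node.col]
            al = alleles.get(rs)
            if al and "minor" in al and "major" in al:
                return f"{rs} ({_leaf_genotypes(kind, node.neg, al['minor'], al['major'])})"
            suffix = "^c" if node.neg else ""
            return f"{rs}:{kind}{suffix}"
        return f"({fmt(node.left)} {node.op.upper()} {fmt(node.right)})"

    return fmt(tree.root)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_load(state: PipelineState, outdir: Path) -> None:
    cfg = state.config
    pconf = load_pathway_config(cfg.pathway) if cfg.pathway else default_pathway_config()
    state.pathway_config = pconf
    if cfg.simulate:
        from .synthetic import study_design, simulate_cohort, write_cohort

        design = study_design(pconf, seed=cfg.seed)
        geno, pheno, expo = simulate_cohort(design)
        write_cohort(outdir / "simulated", design, geno, pheno, expo)
        state.genotypes, state.phenotypes, state.exposures = geno, pheno, expo
        return
    if not cfg.genotypes or not cfg.phenotypes:
        raise PipelineError("load: genotype and phenotype paths required unless simulate=True")
    gpath = Path(cfg.genotypes)
    if gpath.suffix in (".vcf", ".gz", ".bcf"):
        state.genotypes = read_genotypes_vcf(gpath, pconf)
    else:
        state.genotypes = read_genotypes_tsv(gpath, pconf)
    pheno = read_phenotypes(cfg.phenotypes)
    if {"smoking", "alcohol", "protein"} <= set(pheno.columns):
        expo = pheno[["smoking", "alcohol", "protein"]].copy()
        for name, levels in EXPOSURE_LEVELS.items():
            expo[name] = pd.Categorical(expo[name], categories=list(levels))
    else:
        expo = derive_exposures(pheno)
    state.phenotypes = pheno
    state.exposures = expo
    # align subject order
    ids = state.genotypes.subject_ids
    state.phenotypes = pheno.loc[ids]
    state.exposures = expo.loc[ids]


def _stage_encode(state: PipelineState, outdir: Path) -> None:
    state.indicators = encode_genotypes(state.genotypes)


def _stage_descriptives(state: PipelineState, outdir: Path) -> None:
    tab = descriptive_table(state.phenotypes, state.exposures)
    state.artifacts["descriptives"] = _write(
        outdir / "descriptives.tsv", tab.to_csv(sep="\t", index=False)
    )


def _endpoint_outcome(state: PipelineState, endpoint: str):
    pheno = state.phenotypes
    if endpoint == "risk":
        mask = np.ones(len(pheno), dtype=bool)
        outcome = make_outcome("logit", y=pheno["case"].to_numpy())
        return outcome, mask
    cases = (pheno["case"] == 1).to_numpy()
    time = pheno.loc[cases, "survival_months"].to_numpy(dtype=float)
    event = pheno.loc[cases, "event"].to_numpy(dtype=float)
    return make_outcome("exponential_survival", time=time, event=event), cases


def _subset_indicators(state: PipelineState, mask: np.ndarray):
    from .io_encoding import IndicatorMatrix

    ind = state.indicators
    if mask.all():
        return ind
    ids = [s for s, m in zip(ind.subject_ids, mask) if m]
    return IndicatorMatrix(ind.values[mask], ind.columns, ids, ind.gene_of_snp)


def _stage_gst(state: PipelineState, outdir: Path) -> None:
    cfg = state.config
    for endpoint in cfg.endpoints:
        outcome, mask = _endpoint_outcome(state, endpoint)
        ind = _subset_indicators(state, mask)
        ep_id = 0 if endpoint == "risk" else 1
        gsts = build_gsts(
            ind,
            outcome,
            cfg.schedule,
            lambda gene: _rng(cfg.seed, _STREAM_GST, ep_id, _stable_gene_id(gene)),
            grid=cfg.cv_grid,
            folds=cfg.cv_folds,
        )
        state.gsts[endpoint] = gsts
        rows = []
        alleles = state.pathway_config.alleles if state.pathway_config else {}
        case_mask = (state.phenotypes.loc[mask, "case"] == 1).to_numpy()
        for gene, gst in gsts.items():
            cols = [tuple(n.rsplit(":", 1)) for n in gst.column_names]
            if gst.degenerate:
                prev_cases = prev_controls = float("nan")
            else:
                X_gene, _ = ind.gene_slice(gene)
                carrier = gst.indicator(X_gene).astype(bool)
                prev_cases = float(carrier[case_mask].mean()) if case_mask.any() else float("nan")
                prev_controls = (
                    float(carrier[~case_mask].mean()) if (~case_mask).any() else float("nan")
                )
            rows.append(
                {
                    "gene": gene,
                    "tree": gst.to_text(),
                    "tree_genotypes": (
                        render_tree_genotypes(gst.tree, cols, alleles)
                        if not gst.degenerate else ""
                    ),
                    "complement": gst.complement_text(),
                    "coefficient": round(gst.coefficient, 4),
                    "prevalence_cases": round(prev_cases, 4),
                    "prevalence_controls": round(prev_controls, 4),
                    "degenerate": gst.degenerate,
                    "cv_size": "" if gst.cv is None else f"{gst.cv.chosen}",
                }
            )
        state.artifacts[f"gst_{endpoint}"] = _write(
            outdir / f"gst_{endpoint}.tsv",
            pd.DataFrame(rows).to_csv(sep="\t", index=False),
        )


def _stage_pathway(state: PipelineState, outdir: Path) -> None:
    cfg = state.config
    for endpoint in cfg.endpoints:
        outcome, mask = _endpoint_outcome(state, endpoint)
        ind = _subset_indicators(state, mask)
        M, names = gst_matrix(state.gsts[endpoint], ind)
        if M.shape[1] < 2:
            raise PipelineError(f"pathway[{endpoint}]: fewer than 2 non-degenerate GSTs")
        ep_id = 0 if endpoint == "risk" else 1
        model = search_mod.build_pathway_trees(
            M, names, outcome, cfg.schedule,
            _rng(cfg.seed, _STREAM_PATHWAY, ep_id),
            grid=cfg.cv_grid, folds=cfg.cv_folds,
        )
        state.pathway_trees[endpoint] = model
        payload = {
            "endpoint": endpoint,
            "gst_order": names,
            "trees": [t.to_text(names) for t in model.trees],
            "trees_json": [t.to_json() for t in model.trees],
            "coefficients": [round(float(c), 6) for c in model.coefficients],
            "score": round(float(model.score), 6),
        }
        state.artifacts[f"pathway_{endpoint}"] = _write(
            outdir / f"pathway_{endpoint}.json", json.dumps(payload, indent=2)
        )


def _step3_data(state: PipelineState, endpoint: str) -> Step3Data:
    pheno = state.phenotypes
    _, mask = _endpoint_outcome(state, endpoint)
    ind = _subset_indicators(state, mask)
    gst_cols_full, names = gst_matrix(state.gsts[endpoint], ind)
    gst_cols = {g: gst_cols_full[:, j] for j, g in enumerate(names)}
    pw_model = state.pathway_trees.get(endpoint)
    pathway_cols = (
        pw_model.evaluate_trees(gst_cols_full).astype(float) if pw_model else None
    )
    covariates = pheno.loc[mask, ["age", "sex", "race", "center"]]
    exposures = state.exposures.loc[mask]
    subpathways = (
        state.pathway_config.subpathways
        if state.pathway_config and state.pathway_config.subpathways
        else {"all": list(names)}
    )
    kw: dict = {}
    if endpoint == "risk":
        kw["y"] = pheno["case"].to_numpy()
    else:
        kw["time"] = pheno.loc[mask, "survival_months"].to_numpy(dtype=float)
        kw["event"] = pheno.loc[mask, "event"].to_numpy(dtype=int)
        kw["stage"] = pheno.loc[mask, "stage"]
    return Step3Data(
        gst_cols=gst_cols,
        exposures=exposures,
        covariates=covariates,
        pathway_cols=pathway_cols,
        subpathways=subpathways,
        threshold=state.config.threshold,
        **kw,
    )


def _gei_table(state: PipelineState, endpoint: str, result: Step3Result) -> pd.DataFrame:
    rows = []
    ratio_name = "OR_INT" if endpoint == "risk" else "HR_INT"
    fit = result.joint_fit
    alleles = state.pathway_config.alleles if state.pathway_config else {}
    chrom = state.pathway_config.chromosome if state.pathway_config else {}
    for term in sorted(fit.terms) if fit else []:
        gt = fit.terms[term]
        gst = state.gsts[endpoint][term.gene]
        tree = gst.complement if gt.flipped else gst.tree
        cols = [tuple(n.rsplit(":", 1)) for n in gst.column_names]
        lo, hi = gt.ci95
        rows.append(
            {
                "gst": render_tree_genotypes(tree, cols, alleles),
                "gene": term.gene,
                "chromosome": chrom.get(term.gene, ""),
                "exposure": term.exposure,
                "level": term.level,
                ratio_name: round(gt.ratio, 2),
                "ci_low": round(lo, 2),
                "ci_high": round(hi, 2),
                "p": round(gt.p, 4),
                "stratum_gene_ratio": round(
                    fit.stratum_gene_ratio(term) if not gt.flipped else
                    float(np.exp(-fit.params[f"gst_{term.gene}"] - fit.params[term.name])),
                    2,
                ),
                "significant": gt.p <= state.config.threshold,
                "separated": gt.separated,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gst", "gene", "chromosome", "exposure", "level", ratio_name,
            "ci_low", "ci_high", "p", "stratum_gene_ratio", "significant", "separated",
        ],
    )


def _stage_gei(state: PipelineState, outdir: Path) -> None:
    for endpoint in state.config.endpoints:
        data = _step3_data(state, endpoint)
        result = gei_mod.run_step3(data, endpoint)
        state.step3[endpoint] = result
        tab = _gei_table(state, endpoint, result)
        state.artifacts[f"gei_{endpoint}"] = _write(
            outdir / f"gei_{endpoint}.tsv", tab.to_csv(sep="\t", index=False)
        )


def _stage_permute(state: PipelineState, outdir: Path) -> None:
    cfg = state.config
    if cfg.n_permutations == 0:
        return
    for endpoint in cfg.endpoints:
        data = _step3_data(state, endpoint)
        ep_id = 0 if endpoint == "risk" else 1
        summary = gei_mod.permutation_test(
            data,
            endpoint,
            cfg.n_permutations,
            _rng(cfg.seed, _STREAM_PERMUTE, ep_id),
            observed_count=state.step3[endpoint].count,
        )
        summary.seed = cfg.seed
        state.permutation[endpoint] = summary
        payload = {
            "endpoint": endpoint,
            "observed_count": summary.observed_count,
            "n_permutations": summary.n_permutations,
            "empirical_p": summary.empirical_p,
            "seed": cfg.seed,
        }
        state.artifacts[f"permutation_{endpoint}"] = _write(
            outdir / f"permutation_{endpoint}.json", json.dumps(payload, indent=2)
        )
        state.artifacts[f"permutation_counts_{endpoint}"] = _write(
            outdir / f"permutation_counts_{endpoint}.tsv",
            "run\tcount\n" + "\n".join(f"{i}\t{c}" for i, c in enumerate(summary.counts)) + "\n",
        )


_STAGES = [
    ("load", _stage_load),
    ("encode", _stage_encode),
    ("descriptives", _stage_descriptives),
    ("gst", _stage_gst),
    ("pathway", _stage_pathway),
    ("gei", _stage_gei),
    ("permute", _stage_permute),
]


def run_pipeline(config: RunConfig, upto: str = "permute") -> PipelineState:
    """Run the pipeline through stage ``upto``; returns the full state.

    Artifacts (TSV/JSON) and a manifest are written under ``config.out``.
    Identical configs yield byte-identical artifacts.
    """
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    state = PipelineState(config=config)
    stage_names = [s for s, _ in _STAGES]
    if upto not in stage_names:
        raise ValueError(f"unknown stage {upto!r}; one of {stage_names}")
    for name, fn in _STAGES:
        try:
            fn(state, outdir)
        except PipelineError:
            raise
        except Exception as err:  # noqa: BLE001 - stage-named diagnostics
            raise PipelineError(f"{name}: {err}") from err
        if name == upto:
            break
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages_run": stage_names[: stage_names.index(upto) + 1],
        "artifacts": {k: str(v) for k, v in sorted(state.artifacts.items())},
        "significant_counts": {e: r.count for e, r in state.step3.items()},
        "permutation_p": {e: s.empirical_p for e, s in state.permutation.items()},
    }
    _write(outdir / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return state
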