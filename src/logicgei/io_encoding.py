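"""Input handling: genotypes, phenotypes, pathway configuration, exposures.

Genotypes arrive as minor-allele counts (0/1/2, missing allowed) from a
VCF or a subjects x rsIDs TSV; each SNP is re-coded as a pair of binary
indicators (dominant: at least one minor allele; recessive: two minor
alleles), which are the leaf predicates of all logic trees.  The three
environmental exposures of the study design — pack-years of cigarette
smoking, long-term alcohol consumption, and the animal/vegetable protein
intake ratio — are derived from raw questionnaire-style variables and
dichotomised/trichotomised at the study cut-offs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "InputError",
    "GenotypeMatrix",
    "IndicatorMatrix",
    "PathwayConfig",
    "MISSING",
    "SMOKING_LEVELS",
    "ALCOHOL_LEVELS",
    "PROTEIN_LEVELS",
    "STAGE_LEVELS",
    "EXPOSURE_LEVELS",
    "encode_genotypes",
    "decode_indicators",
    "derive_smoking",
    "derive_alcohol",
    "derive_protein",
    "derive_exposures",
    "descriptive_table",
    "read_genotypes_tsv",
    "read_genotypes_vcf",
    "read_phenotypes",
    "load_pathway_config",
    "default_pathway_config",
]

MISSING = -1  # missing-genotype sentinel in count matrices

SMOKING_LEVELS = ("never", "lt20py", "ge20py")
ALCOHOL_LEVELS = ("non_moderate", "heavy")
PROTEIN_LEVELS = ("low", "high")
STAGE_LEVELS = ("in_situ", "local", "regional", "distant", "unknown")
RACE_LEVELS = ("white", "hispanic", "african_american")

#: exposure name -> ordered levels, reference level first
EXPOSURE_LEVELS = {
    "smoking": SMOKING_LEVELS,
    "alcohol": ALCOHOL_LEVELS,
    "protein": PROTEIN_LEVELS,
}

ALCOHOL_CUTOFF = {"male": 20.0, "female": 10.0}  # grams/week
PACK_YEAR_CUTOFF = 20.0
PROTEIN_RATIO_CUTOFF = 1.5
MIN_LIFETIME_CIGS = 100


class ConfigError(ValueError):
    """Pathway configuration inconsistent with the data."""


class InputError(ValueError):
    """Malformed subject-level input."""


# ---------------------------------------------------------------------------
# Pathway configuration
# ---------------------------------------------------------------------------


@dataclass
class PathwayConfig:
    """Gene -> SNP and sub-pathway -> gene mapping, plus display metadata."""

    genes: dict[str, list[str]]
    subpathways: dict[str, list[str]]
    alleles: dict[str, dict[str, str]] = field(default_factory=dict)
    chromosome: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seen: dict[str, str] = {}
        for gene, snps in self.genes.items():
            for s in snps:
                if s in seen:
                    raise ConfigError(f"SNP {s} listed under both {seen[s]} and {gene}")
                seen[s] = gene
        for sp, members in self.subpathways.items():
            for g in members:
                if g not in self.genes:
                    raise ConfigError(f"sub-pathway {sp} names unknown gene {g}")
        self._gene_of_snp = seen

    @property
    def gene_of_snp(self) -> dict[str, str]:
        return dict(self._gene_of_snp)

    @property
    def snp_ids(self) -> list[str]:
        return [s for snps in self.genes.values() for s in snps]

    @property
    def n_snps(self) -> int:
        return len(self._gene_of_snp)


def load_pathway_config(path: str | Path) -> PathwayConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PathwayConfig(
        genes={g: list(v) for g, v in raw["genes"].items()},
        subpathways={k: list(v) for k, v in raw.get("subpathways", {}).items()},
        alleles=raw.get("alleles", {}),
        chromosome=raw.get("chromosome", {}),
    )


def default_pathway_config() -> PathwayConfig:
    """The packaged angiogenesis pathway (34 genes, 257 SNPs, 9 sub-pathways)."""
    from importlib.resources import files

    return load_pathway_config(files("logicgei").joinpath("data/angiogenesis_pathway.yaml"))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele counts with a SNP -> gene map."""

    subject_ids: list[str]
    snp_ids: list[str]
    gene_of_snp: dict[str, str]
    counts: np.ndarray  # int8, values {0,1,2,MISSING}

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int8)
        n, p = self.counts.shape
        if n != len(self.subject_ids) or p != len(self.snp_ids):
            raise InputError("count matrix dimensions do not match ID lists")
        for s in self.snp_ids:
            if s not in self.gene_of_snp:
                raise ConfigError(f"SNP {s} has no gene assignment in the pathway config")
        bad = ~np.isin(self.counts, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InputError(
                f"genotype count {self.counts[i, j]} for subject "
                f"{self.subject_ids[i]} / {self.snp_ids[j]} not in {{0,1,2,missing}}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def snps_of_gene(self, gene: str) -> list[str]:
        return [s for s in self.snp_ids if self.gene_of_snp[s] == gene]

    def genes(self) -> list[str]:
        out: list[str] = []
        for s in self.snp_ids:
            g = self.gene_of_snp[s]
            if g not in out:
                out.append(g)
        return out

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=self.subject_ids, columns=self.snp_ids)
        df = df.replace(MISSING, pd.NA)
        df.to_csv(path, sep="\t", index_label="subject_id", na_rep="NA")


@dataclass
class IndicatorMatrix:
    """Two binary columns per SNP: dominant (count >= 1) and recessive (count == 2)."""

    values: np.ndarray  # subjects x (2 * SNPs), uint8
    columns: list[tuple[str, str]]  # (rsID, "dom" | "rec")
    subject_ids: list[str]
    gene_of_snp: dict[str, str]

    @property
    def column_names(self) -> list[str]:
        return [f"{rs}:{kind}" for rs, kind in self.columns]

    def gene_slice(self, gene: str) -> tuple[np.ndarray, list[tuple[str, str]]]:
        idx = [i for i, (rs, _) in enumerate(self.columns) if self.gene_of_snp[rs] == gene]
        return self.values[:, idx], [self.columns[i] for i in idx]


def encode_genotypes(g: GenotypeMatrix) -> IndicatorMatrix:
    """Dominant/recessive indicator recoding of a genotype matrix.

    Missing counts evaluate both indicators to 0 (the leaf predicate is
    false), keeping Boolean tree evaluation total.
    """
    c = g.counts
    dom = (c >= 1) & (c != MISSING)
    rec = c == 2
    values = np.empty((c.shape[0], 2 * c.shape[1]), dtype=np.uint8)
    values[:, 0::2] = dom
    values[:, 1::2] = rec
    columns = [(rs, kind) for rs in g.snp_ids for kind in ("dom", "rec")]
    return IndicatorMatrix(values, columns, list(g.subject_ids), dict(g.gene_of_snp))


def decode_indicators(ind: IndicatorMatrix) -> np.ndarray:
    """Inverse of :func:`encode_genotypes` on non-missing entries."""
    dom = ind.values[:, 0::2].astype(np.int8)
    rec = ind.values[:, 1::2].astype(np.int8)
    return dom + rec


def read_genotypes_tsv(path: str | Path, config: PathwayConfig) -> GenotypeMatrix:
    """Read a subjects x rsIDs TSV of minor-allele counts (NA = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for rs in df.columns:
        if rs not in config.gene_of_snp:
            raise ConfigError(f"SNP {rs} in genotype file absent from pathway config")
    vals = df.to_numpy(dtype=object)
    counts = np.full(vals.shape, MISSING, dtype=np.int8)
    mask = pd.notna(df).to_numpy()
    numeric = pd.to_numeric(df.stack(), errors="coerce")
    if numeric.isna().any() and mask.any():
        nonint = df.stack()[numeric.isna()]
        raise InputError(f"non-numeric genotype count: {nonint.iloc[0]!r}")
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.any(mask & (arr != np.round(arr))):
        raise InputError("non-integer genotype count in TSV")
    counts[mask] = arr[mask].astype(np.int8)
    return GenotypeMatrix(
        [str(s) for s in df.index], list(df.columns), config.gene_of_snp, counts
    )


def read_genotypes_vcf(path: str | Path, config: PathwayConfig) -> GenotypeMatrix:
    """Read genotypes from a VCF; variant IDs must be rsIDs in the config.

    ALT is taken as the minor allele unless the config's ``alleles`` block
    declares otherwise (``minor_is_ref: true``), so leaf labels stay
    stable regardless of sample frequencies.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        rs = var.ID
        if rs is None or rs not in config.gene_of_snp:
            raise ConfigError(f"VCF variant {rs!r} absent from pathway config")
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types)
        counts = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        if config.alleles.get(rs, {}).get("minor_is_ref"):
            nonmiss = counts != MISSING
            counts[nonmiss] = 2 - counts[nonmiss]
        snp_ids.append(rs)
        rows.append(counts.astype(np.int8))
    return GenotypeMatrix(
        subject_ids, snp_ids, config.gene_of_snp, np.column_stack(rows)
    )


# ---------------------------------------------------------------------------
# Exposure derivation
# ---------------------------------------------------------------------------


def derive_smoking(cigs_per_day: float, years_smoked: float, lifetime_cigs: float) -> str:
    """Smoking category from pack-years.

    Never-smokers are those with fewer than 100 lifetime cigarettes; for
    smokers, pack-years = cigarettes/day x years / 20, cut at 20.
    """
    if min(cigs_per_day, years_smoked, lifetime_cigs) < 0:
        raise InputError("negative smoking input")
    if lifetime_cigs < MIN_LIFETIME_CIGS:
        return "never"
    pack_years = cigs_per_day * years_smoked / 20.0
    return "ge20py" if pack_years >= PACK_YEAR_CUTOFF else "lt20py"


def derive_alcohol(grams_per_week_10y: float, grams_per_week_20y: float, sex: str) -> str:
    """Long-term alcohol category with sex-specific cut-offs.

    Heavy if the mean of the consumption reported 10 and 20 years prior
    strictly exceeds 20 g/week (men) or 10 g/week (women).
    """
    if sex not in ALCOHOL_CUTOFF:
        raise InputError(f"unknown sex level {sex!r}")
    if min(grams_per_week_10y, grams_per_week_20y) < 0:
        raise InputError("negative alcohol consumption")
    long_term = 0.5 * (grams_per_week_10y + grams_per_week_20y)
    return "heavy" if long_term > ALCOHOL_CUTOFF[sex] else "non_moderate"


def derive_protein(animal_g: float, vegetable_g: float) -> str:
    """Animal/vegetable protein ratio dichotomised at a strict 1.5."""
    if animal_g < 0 or vegetable_g < 0:
        raise InputError("negative protein intake")
    if vegetable_g == 0:
        warnings.warn(
            "zero vegetable protein: ratio unbounded, assigning 'high'", stacklevel=2
        )
        return "high"
    return "high" if animal_g / vegetable_g > PROTEIN_RATIO_CUTOFF else "low"


def derive_exposures(pheno: pd.DataFrame) -> pd.DataFrame:
    """Derive the three exposure categories for every subject.

    Expects columns: cigs_per_day, years_smoked, lifetime_cigs,
    alcohol_g_wk_10y, alcohol_g_wk_20y, sex, animal_protein_g,
    vegetable_protein_g.  Returns a DataFrame with categorical columns
    smoking / alcohol / protein indexed like ``pheno``.
    """
    smoking = [
        derive_smoking(r.cigs_per_day, r.years_smoked, r.lifetime_cigs)
        for r in pheno.itertuples()
    ]
    alcohol = [
        derive_alcohol(r.alcohol_g_wk_10y, r.alcohol_g_wk_20y, r.sex)
        for r in pheno.itertuples()
    ]
    protein = [
        derive_protein(r.animal_protein_g, r.vegetable_protein_g)
        for r in pheno.itertuples()
    ]
    return pd.DataFrame(
        {
            "smoking": pd.Categorical(smoking, categories=SMOKING_LEVELS),
            "alcohol": pd.Categorical(alcohol, categories=ALCOHOL_LEVELS),
            "protein": pd.Categorical(protein, categories=PROTEIN_LEVELS),
        },
        index=pheno.index,
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype/exposure TSV (declared column names, NA allowed)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"age", "sex", "race", "center", "case"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"phenotype file missing columns: {sorted(missing)}")
    if "stage" in df.columns:
        controls = df.loc[df["case"] == 0, "stage"]
        if controls.notna().any():
            raise InputError("survival/stage fields present for controls")
    return df


# ---------------------------------------------------------------------------
# Descriptive table
# ---------------------------------------------------------------------------


def _chi2_p(table: np.ndarray) -> float:
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def descriptive_table(
    pheno: pd.DataFrame,
    exposures: pd.DataFrame | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Case/control descriptive summary with chi-square and t-test p-values.

    Per categorical variable: counts and within-group percentages (one
    decimal) by case status plus a Pearson chi-square p (no continuity
    correction); age is summarised as mean (SD) with a two-sample t-test.
    """
    df = pheno.copy()
    if exposures is not None:
        overlap = [c for c in exposures.columns if c in df.columns]
        df = df.drop(columns=overlap).join(exposures)
    case = df["case"].astype(int)
    if case.sum() == 0 or (1 - case).sum() == 0:
        raise InputError("descriptive table needs at least one case and one control")

    if categorical is None:
        categorical = [
            c
            for c in ("sex", "race", "center", "smoking", "alcohol", "protein")
            if c in df.columns
        ]

    rows = []
    n_cases = int(case.sum())
    n_controls = int((1 - case).sum())

    if "age" in df.columns:
        a_case = df.loc[case == 1, "age"].dropna()
        a_ctrl = df.loc[case == 0, "age"].dropna()
        _, p = stats.ttest_ind(a_case, a_ctrl, equal_var=True)
        rows.append(
            {
                "variable": "age",
                "level": "mean (SD)",
                "cases_n": round(float(a_case.mean()), 1),
                "cases_pct": round(float(a_case.std(ddof=1)), 1),
                "controls_n": round(float(a_ctrl.mean()), 1),
                "controls_pct": round(float(a_ctrl.std(ddof=1)), 1),
                "p": float(p),
            }
        )

    for var in categorical:
        col = df[var]
        levels = (
            list(col.cat.categories) if hasattr(col, "cat") else sorted(col.dropna().unique())
        )
        tab = np.array(
            [
                [int(((col == lv) & (case == 1)).sum()) for lv in levels],
                [int(((col == lv) & (case == 0)).sum()) for lv in levels],
            ]
        )
        p = _chi2_p(tab.T)
        for j, lv in enumerate(levels):
            rows.append(
                {
                    "variable": var,
                    "level": str(lv),
                    "cases_n": int(tab[0, j]),
                    "cases_pct": round(100.0 * tab[0, j] / n_cases, 1),
                    "controls_n": int(tab[1, j]),
                    "controls_pct": round(100.0 * tab[1, j] / n_controls, 1),
                    "p": float(p) if j == len(levels) - 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
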