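import numpy as np
import pytest

import logicgei as lg
from logicgei.search import AnnealSchedule


@pytest.fixture(scope="session")
def fast_schedule():
    """Reduced annealing budget for test-scale searches."""
    return AnnealSchedule(n_iterations=300, n_restarts=2)


def small_design(n_genes=3, snps_per_gene=2, seed=0, **kwargs):
    genes = [
        lg.GeneDesign(
            f"G{i}",
            [f"rsG{i}_{j}" for j in range(snps_per_gene)],
            [0.3 + 0.05 * j for j in range(snps_per_gene)],
        )
        for i in range(n_genes)
    ]
    return lg.SimulationDesign(genes=genes, seed=seed, **kwargs)


@pytest.fixture
def null_cohort():
    """Small cohort with no planted effects."""
    design = small_design(n_genes=2, n_cases=150, n_controls=200, seed=11)
    geno, pheno, expo = lg.simulate_case_control(design)
    return design, geno, pheno, expo


@pytest.fixture
def planted_cohort():
    """Study-scale cohort with one planted smoking interaction (OR_INT = 2)."""
    tree = lg.LogicTree(lg.Leaf(0))  # dominant indicator of the gene's first SNP
    eff = lg.PlantedEffect(
        "G1", tree, "smoking", "ge20py",
        log_or=np.log(2.0), main_log_or=np.log(1.4),
    )
    design = small_design(
        n_genes=4, n_cases=747, n_controls=956, seed=21, planted_effects=[eff]
    )
    geno, pheno, expo = lg.simulate_case_control(design)
    return design, geno, pheno, expo


def random_tree(rng, n_columns, max_leaves=4):
    """Random logic tree via random moves from a random leaf."""
    t = lg.LogicTree(lg.Leaf(int(rng.integers(n_columns)), bool(rng.integers(2))))
    for _ in range(int(rng.integers(0, 6))):
        prop = lg.propose_move(t, n_columns, rng, max_leaves=max_leaves)
        if prop is not None:
            t = prop[0]
    return t
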