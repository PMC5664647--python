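"""Survival endpoint: stage-stratified Cox GEI model on simulated cases.

Simulates case survival with a planted GST x high-protein hazard ratio,
then fits the stratified Cox interaction model (Efron ties, baseline
hazard per SEER stage) and prints HR_INT with its Wald CI.
"""

import numpy as np

import logicgei as lg
from logicgei.gei import Term, fit_survival_model

plant = lg.LogicTree(lg.Leaf(0))
effect = lg.PlantedEffect("KDRlike", plant, "protein", "high", log_hr=np.log(2.4))
design = lg.SimulationDesign(
    n_cases=747, n_controls=956,
    genes=[lg.GeneDesign("KDRlike", ["rsK1", "rsK2"], [0.3, 0.4])],
    planted_effects=[effect], seed=14,
)
geno, pheno, expo = lg.simulate_cohort(design)
cases = pheno[pheno["case"] == 1]
ind = lg.encode_genotypes(geno)
mask = (pheno["case"] == 1).to_numpy()
Xg, _ = ind.gene_slice("KDRlike")
gst_col = plant.evaluate(Xg)[mask].astype(float)

term = Term("KDRlike", "protein", "high")
fit = fit_survival_model(
    ["KDRlike"], {"KDRlike": gst_col}, expo[pheno["case"] == 1],
    cases[["age", "sex", "race", "center"]], None,
    cases["survival_months"].to_numpy(), cases["event"].to_numpy(),
    cases["stage"], [term],
)
gt = fit.terms[term]
lo, hi = gt.ci95
print(f"cases: {len(cases)}, events: {int(cases['event'].sum())}, "
      f"stage strata: {cases['stage'].nunique()}")
print(f"HR_INT for carrier x high animal/vegetable protein: "
      f"{gt.ratio:.2f} (95% CI {lo:.2f}, {hi:.2f}), p = {gt.p:.4f}")
print(f"carrier HR within the high-protein stratum: {fit.stratum_gene_ratio(term):.2f}")

# HR_INT estimates the ratio of the carrier hazard ratio between protein
# strata; the planted value is 2.4, so the CI should cover it.
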