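"""Validate breeding values forward in time.

The last two batches are masked, the model is solved on the earlier records
only, and validation animals are scored by (i) theoretical accuracy
R = sqrt(1 - PEV/((1+F) sigma^2)) and (ii) the correlation between the
combined breeding value (own DBV + pen mates' SBVs) and the fixed-effect-
corrected phenotype.
"""

import numpy as np

import sgeblup as sg

dataset = sg.simulate_social_phenotypes(sg.SimulationConfig(
    n_founders=80, n_generations=2, litter_size_range=(3, 6),
    group_size_range=(5, 5), n_markers=800, genotyped_fraction=0.4,
    n_batches=5, seed=3, architecture="marker",
))
ped = dataset.pedigree
ph = dataset.phenotypes
spec = sg.SocialModelSpec()

periods = np.sort(ph.period.unique())
train = ph[~ph.period.isin(periods[-2:])]
print(f"{len(train)} training records, {len(ph) - len(train)} validation records")

for label, kernel in {
    "PED_social": sg.GeneticKernel.from_pedigree(ped),
    "ssGBLUP(omega=0.6)": sg.GeneticKernel.single_step(
        ped,
        A22 := sg.build_A22(ped, ids := dataset.genotypes.index.to_numpy()),
        sg.blend_G(sg.build_G(sg.impute_mean(
            dataset.genotypes.to_numpy(dtype=float))), A22),
        ids, tau=1.0, omega=0.6,
    ),
}.items():
    design_tr = sg.build_design(train, ped, spec)
    fit = sg.fit_reml(design_tr, kernel, spec, tol=1e-5, max_iter=40)
    corr, _ = sg.forward_validation(ph, ped, kernel, fit.components, spec)
    res = sg.evaluate_model(train, ped, kernel, fit.components, spec, label)
    val = res.per_animal[res.per_animal.animal.isin(
        ph.loc[ph.period.isin(periods[-2:]), "animal"])]
    print(f"{label:20s} DBV acc {val.R_D.mean():.2f} ({val.R_D.std():.2f})  "
          f"cor(CBV, y_c) = {corr:.2f}")
print("\nHigher theoretical accuracy for the single-step model reflects the")
print("genomic information on validation animals that have no phenotype yet.")
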