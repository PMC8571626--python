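"""Which design factors structure the community, and which taxa respond?

Runs a sequential multi-factor PERMANOVA on the Bray–Curtis matrix of a
simulated study, then an IndVal.g indicator analysis of treatment-vs-control
samples directly after the pulse.
"""

from microstab import (SimulationConfig, bray_curtis, indval, permanova,
                       simulate_study, to_relative)

study = simulate_study(SimulationConfig(
    n_features_per_niche=250, niches=("endo", "epi"), effect_size=2.5,
    responsive_fraction=0.15, depth_mean=8000, seed=4))
rel = to_relative(study.counts_table)

res = permanova(bray_curtis(rel), study.metadata,
                terms=["niche", "timepoint", "treatment"], n_perm=199, seed=0)
print(res.table.round(4).to_string())
print("\nR2 = fraction of distance-matrix variation explained by each factor"
      "\n(sequential); p from 199 free label permutations.\n")

meta = study.metadata
samples = (meta.samples_where(niche="endo", treatment="control", timepoint="T1")
           + meta.samples_where(niche="endo", treatment="nutrient", timepoint="T1"))
groups = [meta.frame.loc[s, "treatment"] for s in samples]
hits = indval(rel.select_samples(samples), groups, n_perm=199, seed=0)
top = hits.sort_values("stat", ascending=False).head(5)
print(top.round(3).to_string(index=False))
print("\nstat = sqrt(specificity × fidelity) for the feature's best group;"
      "\ntruly pulse-responsive taxa surface with stat near 1 and small p.")
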