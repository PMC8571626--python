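"""Simulate a pulse-perturbation mesocosm study and profile its stability.

Generates a two-niche factorial design (control + three treatments, three
timepoints, three replicates), then computes the resistance/resilience
profile from the observed counts and compares it with the latent ground
truth the generator carries.
"""

from dataclasses import replace

from microstab import SimulationConfig, simulate_study, stability_profile

cfg = SimulationConfig(n_features_per_niche=300, niches=("endo", "epi"),
                       effect_size=2.5, recovery=0.8, depth_mean=10_000,
                       seed=20)
study = simulate_study(cfg)
print(f"simulated {study.counts_table.n_features} features × "
      f"{study.counts_table.n_samples} samples")

est = stability_profile(study.counts_table, study.metadata)
merged = est.merge(study.truth, on=["niche", "treatment"],
                   suffixes=("_est", "_true"))
cols = ["niche", "treatment", "RS_est", "RS_true", "RL_est", "RL_true"]
print(merged[cols].round(3).to_string(index=False))
print("\nRS near 1 = community barely displaced by the pulse; RL near 1 = the"
      "\ndisplacement closed during recovery.  Estimates from noisy counts"
      "\ntrack the latent truth within sampling error.")
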