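"""AUC resolvability profiles over the IPTG stimulus series.

The AUC between single-cell distributions at adjacent stimulus levels is the
probability a random cell from the higher level reads above one from the
lower level (ties count half): 0.5 means the method cannot resolve the step,
1.0 means perfect resolution in the expected direction.
"""

from brass import Construct, SimulationConfig, auc_profile, simulate_experiment

config = SimulationConfig(cells_flow=2000, cells_microscopy=300, seed=1)
tables = simulate_experiment(config)
levels = config.stimulus_series

for label in ("Kn flow protein", "HCR flow rna_fluorescence"):
    series = {t.sample.iptg_umol_per_l: t for t in tables
              if t.method.label == label
              and t.sample.construct is Construct.INDUCIBLE
              and t.sample.replicate == 1}
    prof = auc_profile(series, levels)
    pairs = ", ".join(f"{a:.2f}" for a in prof.auc_adjacent)
    print(f"{label:30s} AUC profile: [{pairs}]  average {prof.average_auc:.3f}")

print("\nProfiles peak near the middle of the stimulus range, where the")
print("dose-response is steepest; the average AUC summarizes overall")
print("resolvability for ranking methods.")
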