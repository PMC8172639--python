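"""Attribute performance differences to single measurement steps.

Pairs of methods that differ in exactly one step (preparation, detection or
measurand) are compared cell-by-cell on their AUC profiles with a two-sided
sign test, and Hill-parameter bias across all methods is tested with
Friedman tests blocked by replicate (and the other way around).
"""

from brass import CANONICAL_METHODS, PipelineConfig, SimulationConfig, attribution_pairs, run_pipeline

for step, name in (("M", "measurand"), ("D", "detection"), ("P", "preparation")):
    pairs = attribution_pairs(CANONICAL_METHODS, step)
    print(f"{len(pairs)} method pairs differ only in {name}")

config = PipelineConfig(
    simulation=SimulationConfig(cells_flow=1500, cells_microscopy=300, seed=3),
    seed=3, n_boot=200,
)
results = run_pipeline(config)

print("\nPairwise resolvability (sign tests on matched AUC cells):")
for _, row in results.pairwise[results.pairwise.differing_step == "D"].iterrows():
    print(f"  {row.method_a}  vs  {row.method_b}: "
          f"{row.n_a_higher}-{row.n_b_higher} (p={row.p_two_sided:.3g})")

print("\nFriedman bias tests on Hill parameters (RPU-normalized):")
sub = results.friedman.query("normalization == 'rpu'")
for _, row in sub.iterrows():
    print(f"  {row.parameter:10s} primary={row.primary_factor:9s} "
          f"p={row.p_value:.3g}")
print("\nA small replicate-primary p for K_1/2 reflects the planted")
print("replicate-level stimulus-potency shift; it moves the curve along the")
print("x-axis without changing cooperativity or normalized amplitude.")
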