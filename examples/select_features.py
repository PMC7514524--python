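"""Two-stage feature selection on the simulated benchmark.

Generates a 10-feature categorical dataset whose outcome depends on five
features (one of which has an exact redundant copy), runs the screening
and greedy-selection stages, and scores the result against the exact
ground-truth model.
"""

from casmi import SimConfig, build_true_joint, generate_benchmark, irr, select_features

table = generate_benchmark(SimConfig(n=800, seed=7))
print(f"dataset: n={table.n}, features={table.feature_names}\n")

result = select_features(table, alpha=0.10, u=1.0)
print(f"stage-1 survivors: {result.survivors}")
print("greedy selection (CASMI score of the growing joint feature):")
for name, score in zip(result.selected, result.trajectory):
    print(f"  + {name:4s} -> {score:.4f}")
print(f"automatic stop after c={result.c} features\n")

model = build_true_joint()
report = irr(model, result.selected)
print(f"information recovery ratio: {report.irr:.4f}")
print(
    f"  (the selected joint feature carries {report.mi_selected:.3f} of the\n"
    f"   {report.mi_relevant:.3f} nats of outcome information in the full\n"
    "   relevant set; weakly informative features are deliberately left out\n"
    "   at this sample size because their estimated coverage is too low)"
)
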