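"""Bootstrap node stability with the dual-threshold classification.

Each iteration resamples texts with replacement, rebuilds the network
(count >= 1, lift > 1) and records which nodes keep at least one edge.
Nodes are core (appearance >= 95%), exploratory (>= 60%) or excluded.
"""

import distortnet as dn

corpus = dn.generate(dn.study_config(n_texts=20_000, seed=42))
report = dn.bootstrap_stability(corpus, k=1_000, seed=42)

print(f"bootstrap iterations: {report.k_iterations}")
print(f"density 95% CI: [{report.density_ci[0]:.3f}, {report.density_ci[1]:.3f}] "
      f"(point {report.density_point:.3f})")
print(f"clustering 95% CI: [{report.clustering_ci[0]:.3f}, "
      f"{report.clustering_ci[1]:.3f}]")
for cls in ("core", "exploratory", "excluded"):
    labs = [l for l, c in report.node_class.items() if c == cls]
    print(f"{cls:>12} ({len(labs)}):")
    for lab in sorted(labs, key=lambda l: -report.appearance[l]):
        print(f"    {lab:<28} {100 * report.appearance[lab]:5.1f}%")

# Core nodes retain an edge in nearly every resample — their network
# position is not an artifact of which texts happened to be sampled.
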