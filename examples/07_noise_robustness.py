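"""Sweep misclassification noise and classify stability regimes.

At each error rate (0-50%), a fraction of positive labels is made
erroneous (half deletions, half additions), the network is rebuilt, and
hub preservation is measured as the Jaccard similarity of the top-5 hubs
against the clean reference.
"""

import distortnet as dn

corpus = dn.generate(dn.study_config(n_texts=20_000, seed=42))
sweep = dn.noise_sweep(corpus, replicates=50, seed=42)

print(f"{'noise':>6} {'hub J':>7} {'density':>8} {'clustering':>11} regime")
for i, eps in enumerate(sweep.levels):
    print(f"{100 * eps:5.0f}% {sweep.mean_hub_jaccard[i]:7.3f} "
          f"{sweep.mean_density[i]:8.3f} {sweep.mean_clustering[i]:11.3f} "
          f"{sweep.regimes[i]}")

# Hub Jaccard of 1 at 0% noise falls monotonically toward random-hub
# levels; density *rises* with noise because uniformly added false
# positives create spurious co-occurrences — rising density with falling
# hub stability is diagnostic of noise-induced rather than genuine
# structure.
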