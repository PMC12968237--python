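# distortnet

Co-occurrence network analysis for multi-label annotations of cognitive
distortions — the systematic thinking biases of cognitive-behavioural
therapy (catastrophizing, all-or-nothing thinking, personalization, …).
Given a binary text × label incidence matrix in which each text may carry
several of 18 distortion labels, the package answers three questions that
recur in computational mental-health research:

1. **Which pairs of distortions co-occur beyond chance?** Association
   mining with lift and chi-square tests under Bonferroni correction.
2. **Do stable three-way bundles exist?** A multiplicative triadic
   statistic with a percentile significance rule.
3. **Is the resulting network organised around hubs, and is that
   organisation real?** Topology and centrality metrics, bootstrap node
   stability, split-half/stratified QAP reliability, and robustness to
   simulated annotation error.

Because corpora of this kind are rarely shareable, the package ships a
synthetic-corpus generator that emulates the statistical structure such a
corpus exhibits (skewed per-text label counts, heterogeneous prevalences,
planted co-occurrence bundles), so every procedure can be validated on
data whose ground truth is known.

## The statistics

For labels *i*, *j* with text counts *N_i*, *N_j* in a corpus of *N*
texts, and *O* texts containing both:

```
E = N_i · N_j / N            expected co-occurrence under independence
lift = O / E                 association strength (lift > 1: attraction)
```

Each pair gets a Pearson chi-square test on its 2×2 table; the family-wise
level is α/C(18,2) = 0.05/153 ≈ 3.27·10⁻⁴. Network edges are pairs with
lift > 1, count ≥ 1 and (for the headline network) a significant
chi-square.

Three-way combinations are scored with the **Integrated Significance
Metric**:

```
ISM = f_rel · P_avg · OER
```

where `f_rel = count/N` is the triple's relative frequency, `P_avg` the
mean of the three conditionals P(i | j∧k), P(j | i∧k), P(k | i∧j), and
`OER = count / (N·π_i·π_j·π_k)` the observed-to-expected ratio under
independence. The product is high only when frequency, conditional
cohesion and enrichment are elevated simultaneously; the significance rule
is the 99th percentile of all C(18,3) = 816 ISM values.

Stability machinery: bootstrap resampling of texts (a node is *stable* in
proportion to the resamples in which it keeps ≥ 1 filtered edge; core
≥ 95%, exploratory ≥ 60%, excluded below), QAP permutation correlation
between split-half or cross-stratum networks (node relabelling null,
respecting dyadic dependence), and a noise sweep that corrupts a fraction
ε of the positive labels (half deletions, half additions) and tracks the
Jaccard overlap of the top-5 hubs against the clean network.

## Worked example

```python
import distortnet as dn

corpus = dn.generate(dn.study_config(n_texts=50_000, seed=42))
cfg = dn.AssociationConfig()
pairs = dn.pair_stats(corpus, cfg)
print(pairs.sort_values("lift", ascending=False).head(1)
      [["label_i", "label_j", "observed", "lift"]])
```

```
                 label_i          label_j  observed     lift
5  All-or-Nothing Thinking  Catastrophizing      1751  1.94
```

The planted dominant pair tops the lift ranking: 1,751 of 50,000 texts
carry both labels, 1.94× the count expected if the two labels were
independent. Continuing (`examples/04_network_metrics.py`,
`examples/07_noise_robustness.py`):

```
network: 11 nodes, 12 edges
top hub: All-or-Nothing Thinking  degree=4  weighted=6.02

 noise   hub J  density  regime
    0%   1.000    0.111  stable
   25%   0.651    0.139  degrading
   50%   0.264    0.177  collapse
```

Hub overlap decays monotonically with annotation error while density
*rises* — uniformly added false positives manufacture spurious edges — the
signature that distinguishes noise-induced from genuine structure.

The `examples/` directory holds one short script per capability
(simulation, pairs, triads, network metrics, bootstrap, QAP, noise sweep,
full pipeline); each prints the numbers it computes and a line on what
they mean. A thin CLI mirrors the same stages:

```bash
distortnet simulate --out corpus.csv --n-texts 50000 --seed 42
distortnet pairs --in corpus.csv --out pairs.csv
distortnet run --config pipeline.yaml
```

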