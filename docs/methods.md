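# Methods

## Data model

The unit of analysis is a text (e.g., a user comment) annotated with a
subset of 18 cognitive-distortion labels. All analyses operate on the
binary incidence matrix `X` (texts × labels); optional metadata carry a
text id, a character length (texts shorter than 200 characters are
excluded by the corpus filter — the boundary is inclusive, a 200-character
text is kept) and a group/thread id used for stratified reliability.
Texts with no label are dropped before analysis.

## Pairwise associations

For each unordered pair the observed co-occurrence `O` is the number of
texts containing both labels; the expectation under independence is
`E = N_i N_j / N` and lift is `O/E`. Lift is reported as missing (never
infinite) when `E = 0`; such pairs never pass any filter. Significance
uses Pearson's chi-square on the 2×2 table (1 df, no continuity
correction by default — at the corpus sizes involved the Yates correction
is immaterial, and it remains available via `AssociationConfig`), with
upper-tail p-values and Bonferroni correction at `alpha / C(D,2)`; the
exact quotient 0.05/153 is used rather than its rounded decimal.

Two filter profiles exist on purpose:

* **headline** — lift > 1 (strict), count ≥ 1, corrected p below level;
  used for the published network, and also for split-half/stratified QAP
  (see Reliability below);
* **resampling** — lift > 1, count ≥ 1 only; used inside bootstrap and
  noise reconstructions, whose aim is to probe the raw co-occurrence
  structure rather than a significance-vetted summary of it.

## Triadic statistic (ISM)

`ISM = f_rel × P_avg × OER` per label triple.

* `f_rel = count / N`. The alternative denominator — total triadic
  instances, Σ_t C(k_t, 3) — is available behind
  `f_rel_denominator="triad_instances"`; the per-text denominator is the
  default because it keeps the triple's "percentage" interpretable as a
  fraction of texts.
* `P_avg` is the mean of the three fully-conditioned probabilities
  P(i | j∧k), P(j | i∧k), P(k | i∧j) (triple count over the pair count of
  the conditioning pair). This is the only reading that treats the three
  members symmetrically. A conditional with zero denominator contributes
  0.
* `OER = count / (N π_i π_j π_k)` with plug-in marginal proportions — the
  pairwise expectation logic lifted to three labels.
* A zero-count triple has all components, and hence ISM, reported as 0.

Significant triads are those at or above the empirical percentile cutoff
(default 99th, linear interpolation over the full vector of 816 values;
ties at the cutoff are retained). With 816 values a strict 99th-percentile
rule yields ~9 triads; an explicit-cutoff mode (`cutoff=`) exists because
percentile conventions differ across software and published thresholds
are often stated as a cutoff value.

## Network construction and metrics

One node per label (isolates dropped by default; a keep-isolates mode
exists), one edge per surviving pair, weight = lift, with observed count
and p-value as edge attributes. The graph is simple; duplicate pairs or
self-loops in the input are contract violations and raise.

* density `|E| / C(|V|, 2)`;
* clustering: the headline value is the **average local clustering
  coefficient** (unweighted); global transitivity is reported alongside
  because publications rarely say which convention they use;
* betweenness: normalised shortest-path betweenness with edge distance
  `1/lift`, so stronger associations are shorter paths. With uniform
  weights this reduces exactly to unweighted betweenness (tested);
* degree assortativity (Pearson over edge endpoints). On degree-regular
  graphs the coefficient is undefined and reported as `None`, never NaN;
* hubs: top-k by degree, ties broken by weighted degree (sum of incident
  lifts) descending, then label lexicographically — a deterministic total
  order.

Resampling hot loops use a vectorised density/clustering computation on
boolean adjacency matrices; it is tested for exact agreement with the
networkx path and with a triangle-enumeration oracle.

## Bootstrap stability

`k` iterations (default 10,000; scalable) resample N texts with
replacement, realised as multinomial row weights — distributionally
identical to row resampling and reducing each iteration to one weighted
cross-product. The network is rebuilt under the resampling filter; a node
*appears* iff it retains at least one edge (an isolated node has no
interpretable network position). Appearance proportions feed the dual
rule: core ≥ 0.95, exploratory ≥ 0.60, excluded otherwise (both
boundaries inclusive). Density and average clustering CIs are simple
percentile bootstrap (2.5/97.5). The percentile bootstrap does not
guarantee that the full-data point estimate falls inside its own CI;
violations are possible for threshold statistics (edge counts jump
discretely as lifts cross 1) and are surfaced as a warning rather than
hidden.

## Reliability (QAP)

Split-half: a seeded uniform permutation splits the corpus into halves of
⌊N/2⌋ and ⌈N/2⌉; one network per half is built on the **full 18-label
node set** so adjacency matrices stay conformable even when a label loses
all edges in one half. The QAP statistic is the Pearson correlation of the
off-diagonal upper triangles (lift-weighted by default; binary available);
the null applies the same random node relabelling to rows and columns of
one matrix; the p-value is add-one permutation-inclusive and two-sided on
|r|, so p ≥ 1/(n_perm + 1) always.

Split-half and stratified QAP default to the **headline** filter. The
reasoning: reliability should compare the networks the headline criteria
would report, and without the significance requirement the adjacency is
dominated by borderline lift ≈ 1 edges whose membership flips between
halves by sampling noise alone — on the synthetic corpus the lift-weighted
correlation is ~0.75–0.88 without the significance filter and ~0.98–1.0
with it, with the planted structure identical in both halves throughout.
The two-criterion filter can be passed explicitly.

Stratified reliability partitions texts into high- and low-activity
strata by group size (median, Pareto top-20%, or top-quartile rules) and
correlates the two stratum networks the same way.

## Noise robustness

A noise level ε makes a fraction ε of the positive cells erroneous:
`round(ε·L·f)` uniformly chosen positives are cleared (false negatives)
and `round(ε·L·(1−f))` uniformly chosen negatives are set (false
positives), with `f = 0.5` by default so the positive-cell count is
preserved to ±1 and prevalence effects do not confound structural
randomisation. ε is capped at 0.5: beyond that, a majority of positive
labels would be erroneous and the notion of a perturbed version of the
same annotation process stops being meaningful.

The sweep (11 levels 0–50% in 5% steps × 50 replicates by default)
rebuilds the network per replicate under the resampling filter and
summarises density, average clustering and the hub Jaccard against the
clean reference. Both the reference and the noisy networks use the same
filter by default — this is what makes hub Jaccard exactly 1 at ε = 0, a
useful self-check; an asymmetric variant (significance-filtered
reference) is available via `reference_cfg`. Density and clustering are
computed over the full fixed node set (isolates kept): the sweep compares
one node universe across levels, so density movements reflect edge
creation rather than node-set churn (noise tends to connect previously
isolated rare labels, which under an isolate-dropping convention would
*dilute* density and mask the false-positive-driven rise).

Regime labels per level from mean hub Jaccard J: stable (J ≥ 0.95),
degrading (0.60 ≤ J < 0.95), collapse (J < 0.60). Only the 0.60 boundary
is an established hub-preservation threshold; 0.95 operationalises
"essentially unchanged". Replicate seeds derive as
`seed + 1000·level_index + replicate_index`, so any single design cell is
reproducible in isolation.

## Synthetic corpus generator

The generator is the package's test-bed: it produces corpora with the
marginal structure the analysis assumes and with known planted effects.

Per text: draw a label count `k` from a configurable distribution; with
probability equal to the total bundle weight, seed the text from one
planted bundle (bundles are mutually exclusive per text; all members
included, `k` raised to the bundle size if needed); fill remaining slots
by prevalence-weighted sampling without replacement (Plackett–Luce
successive sampling, vectorised with the Gumbel top-k device). Lengths
are lognormal (median 435 characters, clipped to [200, 8307]); optional
group ids follow a symmetric Dirichlet-multinomial so thread sizes are
realistically heterogeneous.

The default study-emulation configuration targets: mean 1.78 labels per
text; count buckets 82.3% (1–2), 12.7% (3), 5.0% (4+), with the 4+ tail a
truncated geometric over 4–8; top prevalence ≈ 15.5% with the two next
labels at 14.2% and 11.4% and a mild geometric decay over the rest
(because the marginals must sum to the mean, the profile is necessarily
flat-ish); a dominant planted pair at lift ≈ 1.96 backed by a dominant
triad and a halo of weaker bundles (lifts ≈ 1.25–1.45) forming a clear
5-hub hierarchy. Two corrections make the realised statistics match the
targets rather than drift: prevalence weights are the marginal targets
minus each label's total bundle mass, and the drawn count distribution is
solved so that the *realised* buckets and mean (after bundle-induced
count raising) equal the targets in expectation. Halo bundles pair each
hub with mid/low-prevalence partners deliberately: forcing extra
co-occurrence between two already-prevalent labels requires large bundle
mass, and a large total bundle mass induces spurious mixing co-occurrence
among unplanted labels that blurs the planted structure.

Two structural facts about the sampler matter for nulls:

* with a fixed count distribution the slot-filling induces slight
  *negative* pairwise dependence (for the study counts, baseline lift
  ≈ 0.81·D/(D−1)·E[k(k−1)]/E[k]² below 1), so a "no-bundles" corpus is
  not an independence null;
* with flat weights and `k ~ Binomial(D, p)` the procedure is *exactly*
  iid Bernoulli(p) per label. `independent_config()` builds this true
  independence null, used for the type-I-error and exchangeability
  checks.

Rare, excluded-class distortions are modelled as single-label texts
(`add_rare_label_rows`): a rare label that co-occurs even once forms a
high-lift edge (lift ≈ 1/π of its partner) and would be retained by the
count/lift filter, so genuine exclusion corresponds to labels appearing
in isolation — consistent with excluded nodes being those with no
significant connections.

What the generator does **not** emulate: correlated annotator error (noise
is independent by design), temporal or per-author structure, any
dependence between text length and labels, and the full joint
distribution of real labels (only the marginal summaries above are
targeted). Passing tests therefore demonstrate correctness and
recoverability of the machinery under the stated structure, not fidelity
of any particular real corpus.

## Problem sizes and numerical choices

Validation suites run at: parameter recovery n = 100,000; bootstrap
recovery n = 20,000 with k = 1,000; type-I control 200 replicates of
n = 50,000; QAP null calibration 200 pairs × 199 permutations; split-half
reliability n = 249,414 (the study-scale corpus); noise sweep n = 20,000
with the full 11 × 50 design. These sizes give the stochastic checks
comfortable margins at small Monte-Carlo cost.

Percentiles use linear interpolation; all randomness flows from explicit
integer seeds through `numpy.random.default_rng`; equality tolerances in
oracle tests are 1e-9 to 1e-12 (exact arithmetic paths). Degenerate
inputs have defined outputs throughout: empty filters warn rather than
fail, zero-variance QAP inputs report a missing correlation, zero-margin
chi-square tables report chi² = 0, p = 1.

## Known limitations

* Lift is a ratio estimator; for very rare pairs it is noisy and
  systematically favours rare-label pairs in rankings. The count filter
  only partially mitigates this.
* The bootstrap treats texts as exchangeable; any real dependence
  (threads, authors) makes the CIs anti-conservative. Stratified QAP
  probes, but does not correct for, group structure.
* The ISM has no analytic null distribution; the percentile rule is a
  relative-enrichment convention, not a significance test.
* The noise model is independent and prevalence-preserving; systematic
  annotator biases (confusing specific label pairs) would degrade the
  network differently.
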