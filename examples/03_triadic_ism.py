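"""Score all 816 three-way label combinations with the Integrated
Significance Metric and select the top percentile.

ISM = f_rel x P_avg x OER: relative frequency, mean conditional
probability of each member given the other two, and the observed/expected
ratio under independence. High ISM requires all three to be elevated at
once.
"""

import distortnet as dn

corpus = dn.generate(dn.study_config(n_texts=50_000, seed=42))
triads = dn.triad_stats(corpus)
thr = dn.threshold_triads(triads, percentile=99)

print(f"triples scored: {len(triads)}; 99th-percentile ISM cutoff: "
      f"{thr.cutoff_value:.4f}; significant: {thr.n_significant}")
for row in thr.significant.head(5).to_dict("records"):
    members = " + ".join((row["label_i"], row["label_j"], row["label_k"]))
    print(f"  #{row['rank']} ISM={row['ism']:.4f} count={row['count']} "
          f"({row['percentage']:.1f}%) O/E={row['oer']:.1f}  {members}")

# The planted triad should head the ranking: a bundle of three distortions
# that genuinely co-activate scores far above chance-level triples.
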