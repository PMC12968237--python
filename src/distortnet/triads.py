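"""Triadic enrichment via the Integrated Significance Metric (ISM).

For every unordered label triple (816 triples for 18 labels) the ISM is the
product of three components, each of which must be elevated for the metric
to be large:

    ISM = f_rel * P_avg * OER

* ``f_rel`` — relative frequency: the triple's co-occurrence count divided
  by the number of texts (an alternative denominator, the total number of
  triadic instances  sum_t C(k_t, 3), is available via
  ``f_rel_denominator="triad_instances"``);
* ``P_avg`` — the mean of the three conditional probabilities
  P(i | j and k), P(j | i and k), P(k | i and j), each the triple count
  divided by the corresponding pair count (a conditional with zero
  denominator contributes 0);
* ``OER`` — observed-to-expected ratio under label independence, with the
  expectation ``N * pi_i * pi_j * pi_k`` built from marginal proportions.

Triples with zero count have ISM = 0 with all components reported as 0.
Significant triads are selected by an empirical percentile cutoff over the
full ISM vector (99th percentile by default, linear interpolation, ties at
the cutoff retained) or by an explicit cutoff value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .corpus import LabelMatrix

TRIAD_COLUMNS = (
    "label_i", "label_j", "label_k", "count",
    "f_rel", "p_avg", "oer", "ism", "percentage",
)


def triad_counts(m: LabelMatrix) -> pd.DataFrame:
    """Co-occurrence counts for all C(D, 3) triples."""
    if m.n_labels < 3:
        raise ValueError("need at least 3 labels for triadic analysis")
    X = m.incidence.astype(np.int64)
    D = m.n_labels
    labels = np.asarray(m.taxonomy.labels)
    rows_i, rows_j, rows_k, counts = [], [], [], []
    for i, j in combinations(range(D), 2):
        if j == D - 1:
            continue
        both = X[:, i] * X[:, j]
        cnt = both @ X[:, j + 1:]
        ks = np.arange(j + 1, D)
        rows_i.append(np.full(ks.size, i))
        rows_j.append(np.full(ks.size, j))
        rows_k.append(ks)
        counts.append(cnt)
    ii = np.concatenate(rows_i)
    jj = np.concatenate(rows_j)
    kk = np.concatenate(rows_k)
    return pd.DataFrame(
        {
            "label_i": labels[ii],
            "label_j": labels[jj],
            "label_k": labels[kk],
            "_i": ii,
            "_j": jj,
            "_k": kk,
            "count": np.concatenate(counts),
        }
    )


def triad_stats(
    m: LabelMatrix, f_rel_denominator: str = "texts"
) -> pd.DataFrame:
    """Full triad table with f_rel, P_avg, OER and ISM for every triple."""
    if f_rel_denominator not in ("texts", "triad_instances"):
        raise ValueError("f_rel_denominator must be 'texts' or 'triad_instances'")
    out = triad_counts(m)
    X = m.incidence.astype(np.int64)
    n = m.n_texts
    pair = X.T @ X
    marg = np.diag(pair)
    pi = marg / n

    ii = out["_i"].to_numpy()
    jj = out["_j"].to_numpy()
    kk = out["_k"].to_numpy()
    cnt = out["count"].to_numpy().astype(float)

    if f_rel_denominator == "texts":
        denom = float(n)
    else:
        k_per_text = m.labels_per_text
        denom = float(
            (k_per_text * (k_per_text - 1) * (k_per_text - 2) // 6).sum()
        )
    f_rel = cnt / denom if denom > 0 else np.zeros_like(cnt)

    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.zeros((cnt.size, 3))
        for col, (a, b) in enumerate(((jj, kk), (ii, kk), (ii, jj))):
            pc = pair[a, b].astype(float)
            cond[:, col] = np.where(pc > 0, cnt / pc, 0.0)
        p_avg = cond.mean(axis=1)
        expected = n * pi[ii] * pi[jj] * pi[kk]
        oer = np.where(expected > 0, cnt / expected, 0.0)

    zero = cnt == 0
    f_rel[zero] = 0.0
    p_avg[zero] = 0.0
    oer[zero] = 0.0
    out["f_rel"] = f_rel
    out["p_avg"] = p_avg
    out["oer"] = oer
    out["ism"] = f_rel * p_avg * oer
    out["percentage"] = 100.0 * cnt / n
    return out.drop(columns=["_i", "_j", "_k"])


@dataclass(frozen=True)
class TriadThreshold:
    """Result of percentile (or explicit-cutoff) triad selection."""

    percentile: float | None
    cutoff_value: float
    significant: pd.DataFrame  # ranked descending by ISM

    @property
    def n_significant(self) -> int:
        return len(self.significant)


def threshold_triads(
    stats: pd.DataFrame,
    percentile: float = 99.0,
    cutoff: float | None = None,
) -> TriadThreshold:
    """Select significant triads by ISM percentile or explicit cutoff.

    The percentile cutoff is the linearly interpolated empirical percentile
    of the full ISM vector; triads with ISM >= cutoff are retained (ties
    kept) and ranked descending.
    """
    ism = stats["ism"].to_numpy()
    if cutoff is None:
        if not 0.0 < percentile < 100.0:
            raise ValueError("percentile must lie in (0, 100)")
        cutoff_value = float(np.percentile(ism, percentile))
        used_pct: float | None = percentile
    else:
        cutoff_value = float(cutoff)
        used_pct = None
    sig = stats[stats["ism"] >= cutoff_value].copy()
    sig = sig.sort_values(
        ["ism", "count", "label_i", "label_j", "label_k"],
        ascending=[False, False, True, True, True],
    ).reset_index(drop=True)
    sig.insert(0, "rank", np.arange(1, len(sig) + 1))
    return TriadThreshold(percentile=used_pct, cutoff_value=cutoff_value, significant=sig)


def ranked_triads(stats: pd.DataFrame) -> pd.DataFrame:
    """All triads ranked descending by ISM (deterministic tie-breaks)."""
    out = stats.sort_values(
        ["ism", "count", "label_i", "label_j", "label_k"],
        ascending=[False, False, True, True, True],
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
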