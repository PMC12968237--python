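"""Split-half and stratified reliability via QAP permutation correlation.

Edges of a network share nodes, so adjacency cells are not independent and
an ordinary correlation test between two networks overstates significance.
The quadratic assignment procedure (QAP) respects this dyadic dependence:
the observed statistic is the Pearson correlation between the two
matrices' off-diagonal upper triangles, and the null distribution is built
by applying the *same* random node relabelling to the rows and columns of
one matrix and recomputing the correlation. The p-value is add-one
permutation-inclusive, two-sided on |r|:

    p = (1 + #{|r_perm| >= |r_obs|}) / (n_permutations + 1)

Split-half reliability randomly halves the corpus, builds one network per
half on the full taxonomy node set (so matrices stay conformable even when
a label drops out of one half) and correlates them. Stratified reliability
does the same across high- vs low-activity group strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import LabelMatrix
from .network import DistortionNetwork, build_network
from .pairs import AssociationConfig, RESAMPLING_CONFIG, pair_stats, filter_edges
from .taxonomy import DistortionTaxonomy


@dataclass(frozen=True)
class QAPResult:
    """Observed correlation and its QAP permutation p-value."""

    r_observed: float | None
    p_value: float | None
    n_permutations: int
    seed: int
    matrix_convention: str = "lift_weighted"

    def as_dict(self) -> dict:
        return {
            "r_observed": self.r_observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "matrix_convention": self.matrix_convention,
        }


def split_half(m: LabelMatrix, seed: int = 0) -> tuple[LabelMatrix, LabelMatrix]:
    """Uniformly random split into halves of size floor(N/2) and ceil(N/2)."""
    if m.n_texts < 2:
        raise ValueError("need at least 2 texts to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m.n_texts)
    half = m.n_texts // 2
    return m.subset(perm[:half]), m.subset(perm[half:])


def _upper(a: np.ndarray) -> np.ndarray:
    ii, jj = np.triu_indices(a.shape[0], k=1)
    return a[ii, jj]


def qap_correlation(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 5000,
    seed: int = 0,
) -> QAPResult:
    """QAP correlation between two conformable symmetric matrices.

    Degenerate inputs (zero variance in either off-diagonal) yield
    ``r_observed = None`` with no p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and conformable")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    ua, ub = _upper(a), _upper(b)
    if ua.std() == 0 or ub.std() == 0:
        return QAPResult(None, None, n_permutations, seed)
    r_obs = float(np.corrcoef(ua, ub)[0, 1])

    rng = np.random.default_rng(seed)
    n = a.shape[0]
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        ub_perm = _upper(b[np.ix_(perm, perm)])
        sd = ub_perm.std()
        if sd == 0:
            continue  # cannot happen for b with variance, kept for safety
        r_perm = float(np.corrcoef(ua, ub_perm)[0, 1])
        if abs(r_perm) >= abs(r_obs) - 1e-15:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return QAPResult(r_obs, p, n_permutations, seed)


def network_from_matrix(
    m: LabelMatrix, cfg: AssociationConfig | None = None
) -> DistortionNetwork:
    """Pair mining + filtering + graph construction on the full node set.

    Defaults to the headline filter (lift > 1, count >= 1 and the
    Bonferroni significance requirement): reliability compares the
    networks the headline criteria would publish, and the significance
    filter suppresses borderline lift ~1 edges whose inclusion would be
    dominated by sampling noise.
    """
    cfg = cfg or AssociationConfig()
    stats = pair_stats(m, cfg)
    edges = filter_edges(stats, cfg, m.n_labels)
    return build_network(edges, cfg, isolate_policy="keep", taxonomy=m.taxonomy)


def split_half_qap(
    m: LabelMatrix,
    cfg: AssociationConfig | None = None,
    n_permutations: int = 5000,
    seed: int = 0,
    matrix_convention: str = "lift_weighted",
) -> QAPResult:
    """Split-half reliability: QAP correlation of the two half networks."""
    cfg = cfg or AssociationConfig()
    h1, h2 = split_half(m, seed=seed)
    a = _adjacency(network_from_matrix(h1, cfg), m.taxonomy, matrix_convention)
    b = _adjacency(network_from_matrix(h2, cfg), m.taxonomy, matrix_convention)
    res = qap_correlation(a, b, n_permutations=n_permutations, seed=seed)
    return QAPResult(
        res.r_observed, res.p_value, n_permutations, seed, matrix_convention
    )


def _adjacency(
    net: DistortionNetwork, taxonomy: DistortionTaxonomy, convention: str
) -> np.ndarray:
    if convention == "lift_weighted":
        return net.adjacency(taxonomy, weight="lift")
    if convention == "binary":
        return net.adjacency(taxonomy, weight=None)
    raise ValueError("matrix_convention must be 'lift_weighted' or 'binary'")


# -- stratified (cross-group) reliability ----------------------------------

PARTITION_RULES = ("median", "pareto_top20", "top_quartile")


def partition_groups(groups: np.ndarray, rule: str = "median") -> np.ndarray:
    """Boolean mask: True for texts in high-activity groups.

    Group activity is its text count. ``median``: groups at or above the
    median size are high; ``pareto_top20``: the largest 20% of groups;
    ``top_quartile``: the largest 25%.
    """
    if rule not in PARTITION_RULES:
        raise ValueError(f"rule must be one of {PARTITION_RULES}")
    ser = pd.Series(groups)
    sizes = ser.map(ser.value_counts())
    unique_sizes = ser.value_counts()
    if rule == "median":
        cut = float(unique_sizes.median())
    elif rule == "pareto_top20":
        cut = float(unique_sizes.quantile(0.80))
    else:
        cut = float(unique_sizes.quantile(0.75))
    return (sizes >= cut).to_numpy()


def stratified_qap(
    m: LabelMatrix,
    rule: str = "median",
    cfg: AssociationConfig | None = None,
    n_permutations: int = 5000,
    seed: int = 0,
    matrix_convention: str = "lift_weighted",
) -> QAPResult:
    """QAP correlation between high- and low-activity group strata."""
    cfg = cfg or AssociationConfig()
    if m.groups is None:
        raise ValueError("group_id metadata is required for stratified QAP")
    high = partition_groups(m.groups, rule)
    m_high, m_low = m.subset(high), m.subset(~high)
    if m_high.n_texts == 0 or m_low.n_texts == 0:
        raise ValueError("a stratum is empty under this partition rule")
    if m_high.marginals.sum() == 0 or m_low.marginals.sum() == 0:
        raise ValueError("a stratum carries no labels")
    a = _adjacency(network_from_matrix(m_high, cfg), m.taxonomy, matrix_convention)
    b = _adjacency(network_from_matrix(m_low, cfg), m.taxonomy, matrix_convention)
    res = qap_correlation(a, b, n_permutations=n_permutations, seed=seed)
    return QAPResult(
        res.r_observed, res.p_value, n_permutations, seed, matrix_convention
    )
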