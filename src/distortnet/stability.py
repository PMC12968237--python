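"""Bootstrap node stability and metric confidence intervals.

Each bootstrap iteration resamples the texts with replacement (realised as
multinomial row weights, which is distributionally identical and keeps the
inner loop to one weighted cross-product), rebuilds the filtered network
under the resampling filter (count >= 1, lift > 1 by default — no
significance requirement), and records

* which nodes *appear* — a node appears iff it retains at least one
  surviving edge (isolates do not count);
* the density and average clustering of the rebuilt network.

Node stability is the proportion of iterations in which the node appeared.
The dual-threshold rule classifies nodes as ``core`` (>= 0.95),
``exploratory`` (>= 0.60) or ``excluded`` (< 0.60). Confidence intervals
for density and clustering are simple 2.5/97.5 percentile bootstrap
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus import LabelMatrix
from .network import adjacency_metrics
from .pairs import (
    RESAMPLING_CONFIG,
    AssociationConfig,
    chi2_contingency_2x2,
)

CORE_THRESHOLD = 0.95
EXPLORATORY_THRESHOLD = 0.60


@dataclass
class StabilityReport:
    """Bootstrap node-appearance proportions and metric CIs."""

    k_iterations: int
    seed: int
    appearance: dict[str, float]
    node_class: dict[str, str] = field(default_factory=dict)
    density_ci: tuple[float, float] = (0.0, 0.0)
    clustering_ci: tuple[float, float] = (0.0, 0.0)
    density_point: float = 0.0
    clustering_point: float = 0.0

    def as_dict(self) -> dict:
        return {
            "k_iterations": self.k_iterations,
            "seed": self.seed,
            "appearance": self.appearance,
            "node_class": self.node_class,
            "density_ci": list(self.density_ci),
            "clustering_ci": list(self.clustering_ci),
            "density_point": self.density_point,
            "clustering_point": self.clustering_point,
        }


def _edge_mask(
    co: np.ndarray, marg: np.ndarray, n: int, cfg: AssociationConfig
) -> np.ndarray:
    """Boolean (D, D) mask of pairs surviving the filter."""
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.outer(marg, marg) / n
        lift = np.where(expected > 0, co / expected, np.nan)
    mask = (co >= cfg.min_count) & (lift > cfg.lift_threshold)
    if cfg.apply_significance_filter:
        D = co.shape[0]
        ii, jj = np.triu_indices(D, k=1)
        _, p = chi2_contingency_2x2(
            co[ii, jj], marg[ii], marg[jj], n, yates=cfg.yates_correction
        )
        alpha = cfg.corrected_alpha(D)
        sig = np.zeros_like(mask)
        sig[ii, jj] = p < alpha
        sig = sig | sig.T
        mask &= sig
    np.fill_diagonal(mask, False)
    return mask & mask.T


def bootstrap_stability(
    m: LabelMatrix,
    k: int = 10_000,
    cfg: AssociationConfig = RESAMPLING_CONFIG,
    seed: int = 0,
) -> StabilityReport:
    """Bootstrap the corpus and estimate node stability; deterministic per seed."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if m.n_texts == 0:
        raise ValueError("matrix is empty")
    rng = np.random.default_rng(seed)
    X = m.incidence.astype(np.float64)
    n, D = X.shape
    p_uniform = np.full(n, 1.0 / n)

    appear = np.zeros(D, dtype=np.int64)
    densities = np.empty(k)
    clusterings = np.empty(k)
    for it in range(k):
        w = rng.multinomial(n, p_uniform).astype(np.float64)
        co = (X * w[:, None]).T @ X
        marg = w @ X
        mask = _edge_mask(co, marg, n, cfg)
        appear += mask.any(axis=1)
        densities[it], clusterings[it] = adjacency_metrics(mask)

    co0, marg0 = (X.T @ X), X.sum(axis=0)
    mask0 = _edge_mask(co0, marg0, n, cfg)
    d0, c0 = adjacency_metrics(mask0)

    report = StabilityReport(
        k_iterations=k,
        seed=seed,
        appearance={
            lab: float(a / k) for lab, a in zip(m.taxonomy.labels, appear)
        },
        density_ci=(
            float(np.percentile(densities, 2.5)),
            float(np.percentile(densities, 97.5)),
        ),
        clustering_ci=(
            float(np.percentile(clusterings, 2.5)),
            float(np.percentile(clusterings, 97.5)),
        ),
        density_point=d0,
        clustering_point=c0,
    )
    _warn_if_point_outside(report)
    return classify_nodes(report)


def _warn_if_point_outside(report: StabilityReport) -> None:
    lo, hi = report.density_ci
    if not lo <= report.density_point <= hi:
        warnings.warn(
            "full-data density lies outside the percentile bootstrap CI",
            stacklevel=3,
        )
    lo, hi = report.clustering_ci
    if not lo <= report.clustering_point <= hi:
        warnings.warn(
            "full-data clustering lies outside the percentile bootstrap CI",
            stacklevel=3,
        )


def classify_nodes(report: StabilityReport) -> StabilityReport:
    """Apply the dual-threshold rule (core >= 0.95, exploratory >= 0.60)."""
    report.node_class = {
        lab: (
            "core"
            if prop >= CORE_THRESHOLD
            else "exploratory" if prop >= EXPLORATORY_THRESHOLD else "excluded"
        )
        for lab, prop in report.appearance.items()
    }
    return report
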