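"""Noise-injection robustness: sweep misclassification levels, rebuild
networks, and classify stability regimes.

The sweep perturbs the corpus at each error rate (0%-50% in 5% steps by
default), rebuilds the co-occurrence network under the two-criterion
resampling filter (count >= 1, lift > 1), and summarises per level:

* mean and sd of network density and average clustering;
* mean and sd of the hub Jaccard — the Jaccard similarity between the
  top-5 degree hubs of the noisy network and of the reference network.

Stability regimes per level, from the mean hub Jaccard J: ``stable``
(J >= 0.95), ``degrading`` (0.60 <= J < 0.95), ``collapse`` (J < 0.60).
Only the 0.60 boundary is an established threshold (hub preservation); the
0.95 boundary operationalises the "perfectly preserved" narrative band.

Replicate seeds derive from the master seed as
``seed + level_index * 1000 + replicate_index`` so any single cell of the
design can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import LabelMatrix
from .network import adjacency_metrics, degrees_from_adjacency
from .pairs import AssociationConfig, RESAMPLING_CONFIG
from .stability import _edge_mask
from .synthetic import NoiseSpec, inject_noise

DEFAULT_LEVELS: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.501, 0.05), 2))

STABLE_J = 0.95
COLLAPSE_J = 0.60


def jaccard(a: set, b: set) -> float:
    """Jaccard similarity |a & b| / |a | b|; 1.0 when both sets are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class NoiseSweepResult:
    """Per-level summaries of the noise sweep."""

    levels: list[float]
    replicates_per_level: int
    seed: int
    mean_density: list[float] = field(default_factory=list)
    sd_density: list[float] = field(default_factory=list)
    mean_clustering: list[float] = field(default_factory=list)
    sd_clustering: list[float] = field(default_factory=list)
    mean_hub_jaccard: list[float] = field(default_factory=list)
    sd_hub_jaccard: list[float] = field(default_factory=list)
    regimes: list[str] = field(default_factory=list)
    reference_hubs: list[str] = field(default_factory=list)

    @property
    def total_reconstructions(self) -> int:
        return len(self.levels) * self.replicates_per_level

    def as_dict(self) -> dict:
        return {
            "levels": self.levels,
            "replicates_per_level": self.replicates_per_level,
            "seed": self.seed,
            "mean_density": self.mean_density,
            "sd_density": self.sd_density,
            "mean_clustering": self.mean_clustering,
            "sd_clustering": self.sd_clustering,
            "mean_hub_jaccard": self.mean_hub_jaccard,
            "sd_hub_jaccard": self.sd_hub_jaccard,
            "regimes": self.regimes,
            "reference_hubs": self.reference_hubs,
            "total_reconstructions": self.total_reconstructions,
        }


def _hubs_from_mask(
    mask: np.ndarray, lift: np.ndarray, labels: Sequence[str], k: int = 5
) -> list[str]:
    """Top-k hubs by degree from an edge mask; ties by weighted degree, then label."""
    deg = degrees_from_adjacency(mask)
    wdeg = (np.where(mask, lift, 0.0)).sum(axis=1)
    connected = [i for i in range(len(labels)) if deg[i] > 0]
    order = sorted(connected, key=lambda i: (-deg[i], -wdeg[i], labels[i]))
    return [labels[i] for i in order[:k]]


def _network_summary(
    m: LabelMatrix, cfg: AssociationConfig
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """(edge mask, lift matrix, density, clustering) for one matrix.

    Density and clustering are computed on the full taxonomy node set
    (isolates kept): the sweep compares the same node universe at every
    noise level, so density movements reflect edge creation/destruction
    rather than node-set churn.
    """
    X = m.incidence.astype(np.float64)
    n = m.n_texts
    co = X.T @ X
    marg = X.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.outer(marg, marg) / n
        lift = np.where(expected > 0, co / expected, 0.0)
    mask = _edge_mask(co, marg, n, cfg)
    density, clustering = adjacency_metrics(mask, drop_isolates=False)
    return mask, lift, density, clustering


def noise_sweep(
    m: LabelMatrix,
    levels: Sequence[float] = DEFAULT_LEVELS,
    replicates: int = 50,
    cfg: AssociationConfig = RESAMPLING_CONFIG,
    seed: int = 0,
    reference_cfg: AssociationConfig | None = None,
    hub_k: int = 5,
) -> NoiseSweepResult:
    """Run the full noise-injection sweep; deterministic given the seed.

    The reference network (and its top-``hub_k`` hubs) is computed once
    from the clean corpus under ``reference_cfg`` (defaults to the same
    filter as the noisy reconstructions, which guarantees hub Jaccard = 1
    at zero noise).
    """
    if m.n_texts == 0:
        raise ValueError("matrix is empty")
    levels = [float(lv) for lv in levels]
    for lv in levels:
        if not 0.0 <= lv <= 0.5:
            raise ValueError(f"invalid noise level {lv}")
    reference_cfg = reference_cfg or cfg
    labels = list(m.taxonomy.labels)

    ref_mask, ref_lift, _, _ = _network_summary(m, reference_cfg)
    ref_hubs = _hubs_from_mask(ref_mask, ref_lift, labels, k=hub_k)

    result = NoiseSweepResult(
        levels=levels,
        replicates_per_level=replicates,
        seed=seed,
        reference_hubs=ref_hubs,
    )
    for li, eps in enumerate(levels):
        dens = np.empty(replicates)
        clus = np.empty(replicates)
        jac = np.empty(replicates)
        for ri in range(replicates):
            rep_seed = seed + li * 1000 + ri
            noisy = inject_noise(m, NoiseSpec(error_rate=eps, seed=rep_seed))
            mask, lift, d, c = _network_summary(noisy, cfg)
            hubs = _hubs_from_mask(mask, lift, labels, k=hub_k)
            dens[ri], clus[ri] = d, c
            jac[ri] = jaccard(set(hubs), set(ref_hubs))
        result.mean_density.append(float(dens.mean()))
        result.sd_density.append(float(dens.std(ddof=1)) if replicates > 1 else 0.0)
        result.mean_clustering.append(float(clus.mean()))
        result.sd_clustering.append(float(clus.std(ddof=1)) if replicates > 1 else 0.0)
        result.mean_hub_jaccard.append(float(jac.mean()))
        result.sd_hub_jaccard.append(float(jac.std(ddof=1)) if replicates > 1 else 0.0)
    return classify_regimes(result)


def classify_regimes(result: NoiseSweepResult) -> NoiseSweepResult:
    """Label each level stable / degrading / collapse by mean hub Jaccard."""
    result.regimes = [
        "stable" if j >= STABLE_J else "degrading" if j >= COLLAPSE_J else "collapse"
        for j in result.mean_hub_jaccard
    ]
    return result
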