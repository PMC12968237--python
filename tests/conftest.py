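"""Shared fixtures and independent brute-force oracles.

The oracles recompute every statistic by direct per-text enumeration (or
closed form), independent of the vectorised implementation paths they
check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from distortnet import DistortionTaxonomy, LabelMatrix


def letter_taxonomy(d: int) -> DistortionTaxonomy:
    return DistortionTaxonomy(tuple(chr(ord("A") + i) for i in range(d)))


def matrix_from_sets(
    sets: list[set[int]], d: int, lengths=None, groups=None
) -> LabelMatrix:
    """Build a LabelMatrix from per-text label-index sets (labels A, B, ...)."""
    inc = np.zeros((len(sets), d), dtype=np.uint8)
    for t, s in enumerate(sets):
        for i in s:
            inc[t, i] = 1
    return LabelMatrix(
        incidence=inc,
        taxonomy=letter_taxonomy(d),
        lengths=None if lengths is None else np.asarray(lengths),
        groups=None if groups is None else np.asarray(groups),
    )


def random_matrix(rng: np.random.Generator, n: int, d: int, p: float = 0.3) -> LabelMatrix:
    return LabelMatrix(
        incidence=(rng.random((n, d)) < p).astype(np.uint8),
        taxonomy=letter_taxonomy(d),
    )


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def oracle_pair_stats(inc: np.ndarray) -> dict[tuple[int, int], dict]:
    """Per-pair observed/expected/lift by direct per-text enumeration."""
    n, d = inc.shape
    out = {}
    for i, j in combinations(range(d), 2):
        o = sum(1 for t in range(n) if inc[t, i] and inc[t, j])
        ni = int(inc[:, i].sum())
        nj = int(inc[:, j].sum())
        e = ni * nj / n
        out[(i, j)] = {
            "observed": o,
            "expected": e,
            "lift": (o / e) if e > 0 else None,
        }
    return out


def oracle_chi2(o: int, ni: int, nj: int, n: int) -> float:
    """Closed-form Pearson chi-square on the 2x2 table."""
    a, b, c, d_ = o, ni - o, nj - o, n - ni - nj + o
    denom = (a + b) * (c + d_) * (a + c) * (b + d_)
    if denom == 0:
        return 0.0
    return n * (a * d_ - b * c) ** 2 / denom


def oracle_triad_stats(inc: np.ndarray) -> dict[tuple[int, int, int], dict]:
    """Per-triple count/f_rel/p_avg/oer/ism by direct enumeration."""
    n, d = inc.shape
    marg = inc.sum(axis=0)
    out = {}
    for i, j, k in combinations(range(d), 3):
        cnt = sum(
            1 for t in range(n) if inc[t, i] and inc[t, j] and inc[t, k]
        )
        pairs = {
            (j, k): sum(1 for t in range(n) if inc[t, j] and inc[t, k]),
            (i, k): sum(1 for t in range(n) if inc[t, i] and inc[t, k]),
            (i, j): sum(1 for t in range(n) if inc[t, i] and inc[t, j]),
        }
        conds = [cnt / pc if pc > 0 else 0.0 for pc in pairs.values()]
        p_avg = sum(conds) / 3
        exp = n * (marg[i] / n) * (marg[j] / n) * (marg[k] / n)
        oer = cnt / exp if exp > 0 else 0.0
        f_rel = cnt / n
        if cnt == 0:
            f_rel = p_avg = oer = 0.0
        out[(i, j, k)] = {
            "count": cnt,
            "f_rel": f_rel,
            "p_avg": p_avg,
            "oer": oer,
            "ism": f_rel * p_avg * oer,
        }
    return out


def oracle_density_clustering(adj: np.ndarray) -> tuple[float, float]:
    """Density and average local clustering by triangle enumeration."""
    a = np.asarray(adj, dtype=bool)
    nodes = list(range(a.shape[0]))
    n = len(nodes)
    edges = sum(a[i, j] for i in nodes for j in nodes if i < j)
    density = edges / (n * (n - 1) / 2) if n >= 2 else 0.0
    locals_ = []
    for v in nodes:
        nbrs = [u for u in nodes if a[v, u]]
        if len(nbrs) < 2:
            locals_.append(0.0)
            continue
        links = sum(
            1 for x, y in combinations(nbrs, 2) if a[x, y]
        )
        locals_.append(links / (len(nbrs) * (len(nbrs) - 1) / 2))
    return density, float(np.mean(locals_)) if locals_ else 0.0


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same deterministic stream
    return np.random.default_rng(20260927)
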