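"""Pairwise co-occurrence association mining.

For every unordered label pair (153 pairs for the 18-label taxonomy) the
module computes:

* the observed co-occurrence count ``O`` — texts containing both labels;
* the expected count under independence ``E = N_i * N_j / N``;
* the lift ratio ``O / E`` (association strength; lift > 1 means the pair
  co-occurs more often than independence predicts);
* a Pearson chi-square test (1 df, no continuity correction by default) on
  the 2x2 contingency table, with Bonferroni-corrected family-wise alpha
  ``alpha / n_tests`` (0.05 / 153 ~ 3.27e-4 by default).

Network edges are the pairs that survive the configured filter: lift
strictly above the threshold, observed count at least the minimum, and —
when the significance filter is on — corrected p-value below alpha.
Results are carried in a pandas DataFrame with one row per pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import LabelMatrix

#: Columns of the pair-statistics table.
PAIR_COLUMNS = (
    "label_i", "label_j", "n_i", "n_j", "observed",
    "expected", "lift", "chi2", "p_value", "significant",
)


@dataclass(frozen=True)
class AssociationConfig:
    """Filtering and testing configuration for pairwise associations.

    ``n_tests`` defaults to C(D, 2) of the matrix being analysed when left
    ``None``. ``apply_significance_filter`` is on for the headline network
    and off for bootstrap/noise reconstructions, which filter only on count
    and lift.
    """

    alpha: float = 0.05
    n_tests: int | None = None
    lift_threshold: float = 1.0
    min_count: int = 1
    apply_significance_filter: bool = True
    yates_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_tests is not None and self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")

    def corrected_alpha(self, n_labels: int) -> float:
        """Bonferroni-corrected per-test level, alpha / n_tests."""
        n_tests = self.n_tests if self.n_tests is not None else comb(n_labels, 2)
        return self.alpha / n_tests


#: Configuration used by bootstrap and noise reconstructions (count >= 1,
#: lift > 1, no significance requirement).
RESAMPLING_CONFIG = AssociationConfig(apply_significance_filter=False)


def pair_counts(m: LabelMatrix) -> pd.DataFrame:
    """Observed co-occurrence counts and marginals for all C(D, 2) pairs."""
    if m.n_texts == 0:
        raise ValueError("matrix is empty")
    X = m.incidence.astype(np.int64)
    co = X.T @ X
    marg = np.diag(co)
    ii, jj = np.triu_indices(m.n_labels, k=1)
    labels = np.asarray(m.taxonomy.labels)
    return pd.DataFrame(
        {
            "label_i": labels[ii],
            "label_j": labels[jj],
            "n_i": marg[ii],
            "n_j": marg[jj],
            "observed": co[ii, jj],
        }
    )


def expected_and_lift(pairs: pd.DataFrame, n_total: int) -> pd.DataFrame:
    """Add expected counts and lift; lift is NaN (never inf) when E = 0."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    out = pairs.copy()
    expected = out["n_i"] * out["n_j"] / n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        lift = np.where(expected > 0, out["observed"] / expected, np.nan)
    out["expected"] = expected
    out["lift"] = lift
    return out


def chi2_contingency_2x2(
    o: np.ndarray, n_i: np.ndarray, n_j: np.ndarray, n: int,
    yates: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Pearson chi-square on 2x2 tables (1 df).

    Table cells: both = O, only-i = N_i - O, only-j = N_j - O,
    neither = N - N_i - N_j + O. A zero row or column margin yields
    chi2 = 0, p = 1 (no association computable).
    """
    o = np.asarray(o, dtype=float)
    n_i = np.asarray(n_i, dtype=float)
    n_j = np.asarray(n_j, dtype=float)
    a = o
    b = n_i - o
    c = n_j - o
    d = n - n_i - n_j + o
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    diff = np.abs(a * d - b * c)
    if yates:
        diff = np.maximum(diff - n / 2.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * diff**2 / denom, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(denom > 0, p, 1.0)
    return chi2, p


def chi2_test(pairs: pd.DataFrame, n_total: int, yates: bool = False) -> pd.DataFrame:
    """Add Pearson chi-square statistics and upper-tail p-values."""
    out = pairs.copy()
    chi2, p = chi2_contingency_2x2(
        out["observed"].to_numpy(),
        out["n_i"].to_numpy(),
        out["n_j"].to_numpy(),
        n_total,
        yates=yates,
    )
    out["chi2"] = chi2
    out["p_value"] = p
    return out


def pair_stats(m: LabelMatrix, cfg: AssociationConfig | None = None) -> pd.DataFrame:
    """Full pair-statistics table: counts, expected, lift, chi-square, flag."""
    cfg = cfg or AssociationConfig()
    out = pair_counts(m)
    out = expected_and_lift(out, m.n_texts)
    out = chi2_test(out, m.n_texts, yates=cfg.yates_correction)
    return flag_significant(out, cfg, m.n_labels)


def flag_significant(
    pairs: pd.DataFrame, cfg: AssociationConfig, n_labels: int
) -> pd.DataFrame:
    """Set the ``significant`` flag according to the configured filter."""
    out = pairs.copy()
    alpha = cfg.corrected_alpha(n_labels)
    lift = out["lift"].to_numpy()
    ok = (
        ~np.isnan(lift)
        & (lift > cfg.lift_threshold)
        & (out["observed"].to_numpy() >= cfg.min_count)
    )
    if cfg.apply_significance_filter:
        ok &= out["p_value"].to_numpy() < alpha
    out["significant"] = ok
    return out


def filter_edges(
    pairs: pd.DataFrame, cfg: AssociationConfig, n_labels: int
) -> pd.DataFrame:
    """The subset of pairs passing the filter (flags refreshed first)."""
    flagged = flag_significant(pairs, cfg, n_labels)
    return flagged[flagged["significant"]].reset_index(drop=True)


def cooccurrence_counts(m: LabelMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Raw (D, D) co-occurrence matrix and marginal vector (hot-loop API)."""
    X = m.incidence.astype(np.int64)
    co = X.T @ X
    return co, np.diag(co).copy()


def pair_labels(n_labels: int) -> list[tuple[int, int]]:
    """Index pairs in the canonical (upper-triangle) order."""
    return list(combinations(range(n_labels), 2))
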