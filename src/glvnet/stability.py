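"""Cooperation/competition balance and between-group stability comparison.

A community whose fitted interactions are predominantly negative is read
as competitively stabilized; a predominantly positive (cooperative)
community is read as unstable.  The unit of comparison is the ensemble
member: each assembly's fit contributes one pair of sign proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from glvnet.inference import CoefficientEnsemble, ConsensusNetwork


@dataclass
class StabilityProfile:
    """Per-member interaction-sign proportions plus network-level extremes.

    ``proportion_positive[m]`` is the fraction of member m's nonzero
    off-diagonal coefficients that are positive (exact zeros are excluded
    from the denominator and tracked in ``n_zero``).  The extremes are
    taken over the consensus edges' mean strengths and are ``None`` when
    the network has no edge of that sign.
    """

    group: str
    proportion_positive: np.ndarray
    proportion_negative: np.ndarray
    n_zero: np.ndarray
    max_positive_strength: float | None
    min_negative_strength: float | None
    n_edges_positive: int
    n_edges_negative: int

    @property
    def n_members(self) -> int:
        return len(self.proportion_positive)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "member": np.arange(self.n_members),
                "proportion_positive": self.proportion_positive,
                "proportion_negative": self.proportion_negative,
                "n_zero_coefficients": self.n_zero,
            }
        )


def stability_profile(
    ensemble: CoefficientEnsemble,
    network: ConsensusNetwork | None,
    group: str,
) -> StabilityProfile:
    """Summarize one group's ensemble by interaction-sign proportions."""
    a = ensemble.interactions
    n = ensemble.n_taxa
    off = ~np.eye(n, dtype=bool)
    coeffs = a[:, off]  # (M, n*(n-1))
    n_pos = (coeffs > 0).sum(axis=1)
    n_neg = (coeffs < 0).sum(axis=1)
    n_zero = (coeffs == 0).sum(axis=1)
    denom = n_pos + n_neg
    if np.any(denom == 0):
        warnings.warn("ensemble member(s) with all-zero off-diagonal coefficients")
    with np.errstate(invalid="ignore"):
        prop_pos = np.where(denom > 0, n_pos / np.maximum(denom, 1), np.nan)
        prop_neg = np.where(denom > 0, n_neg / np.maximum(denom, 1), np.nan)

    max_pos = min_neg = None
    n_edges_pos = n_edges_neg = 0
    if network is not None and network.n_edges > 0:
        strengths = network.edges["mean_strength"]
        signs = network.edges["sign"]
        pos = strengths[signs > 0]
        neg = strengths[signs < 0]
        n_edges_pos, n_edges_neg = len(pos), len(neg)
        max_pos = float(pos.max()) if len(pos) else None
        min_neg = float(neg.min()) if len(neg) else None
    else:
        warnings.warn(f"group {group!r}: empty network, no strength extremes")

    return StabilityProfile(
        group=group,
        proportion_positive=prop_pos,
        proportion_negative=prop_neg,
        n_zero=n_zero,
        max_positive_strength=max_pos,
        min_negative_strength=min_neg,
        n_edges_positive=n_edges_pos,
        n_edges_negative=n_edges_neg,
    )


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    if pooled.size and np.all(pooled == pooled[0]):
        warnings.warn("all values tied; rank-sum p set to 1")
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        except ValueError:
            warnings.warn("rank-sum test undefined (all ties); p set to 1")
            return 1.0


def compare_stability(
    profile_a: StabilityProfile,
    profile_b: StabilityProfile,
    seed: int | None = None,
) -> dict:
    """Shapiro-Wilk normality checks plus Wilcoxon rank-sum comparison.

    Returns Shapiro p-values per group, two-sided rank-sum p-values for
    the positive and negative proportions, and ``direction``: the group
    label with the stochastically larger proportion of positive
    interactions.  ``seed`` is recorded for provenance (the tests used
    here are deterministic).
    """
    pa = profile_a.proportion_positive[~np.isnan(profile_a.proportion_positive)]
    pb = profile_b.proportion_positive[~np.isnan(profile_b.proportion_positive)]
    na = profile_a.proportion_negative[~np.isnan(profile_a.proportion_negative)]
    nb = profile_b.proportion_negative[~np.isnan(profile_b.proportion_negative)]
    if len(pa) < 3 or len(pb) < 3:
        raise ValueError("each profile needs at least 3 usable members")

    def _shapiro(x: np.ndarray) -> float:
        if np.all(x == x[0]):
            return float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.shapiro(x).pvalue)

    direction = (
        profile_a.group
        if np.median(pa) > np.median(pb)
        else profile_b.group
        if np.median(pb) > np.median(pa)
        else "tie"
    )
    return {
        "group_a": profile_a.group,
        "group_b": profile_b.group,
        "shapiro_p_a": _shapiro(pa),
        "shapiro_p_b": _shapiro(pb),
        "wilcoxon_p_positive": _rank_sum_p(pa, pb),
        "wilcoxon_p_negative": _rank_sum_p(na, nb),
        "direction": direction,
        "median_proportion_positive_a": float(np.median(pa)),
        "median_proportion_positive_b": float(np.median(pb)),
        "seed": seed,
    }
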