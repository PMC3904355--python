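"""Correlation of per-mismatch divergence predictions with risk estimates."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import (
    BindingProfile,
    PeptidePanel,
    affinity_correlation_divergence,
    make_random_panel,
    profile_divergence,
)
from .util import UndefinedResultError

log = logging.getLogger(__name__)

_JOIN_KEY = ["position", "res_a", "res_b"]


@dataclass(frozen=True)
class AssociationResult:
    n: int
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    scatter: pd.DataFrame  # one row per mismatch: divergence, relative risk
    n_dropped: int = 0  # rows lost to undefined risk estimates

    def __post_init__(self) -> None:
        if self.n != len(self.scatter):
            raise ValueError("n must equal the number of scatter rows")


def pearson_with_p(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedResultError("zero variance; Pearson correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman_with_p(x, y) -> tuple[float, float]:
    """Rank correlation (average ranks) with large-sample t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise UndefinedResultError("all-tied vector; Spearman correlation undefined")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def associate(
    risk_table: pd.DataFrame,
    divergence_table: pd.DataFrame,
    rate_mode: str = "adjusted",
) -> AssociationResult:
    """Join risk and divergence tables per mismatch and correlate.

    Inner join on (position, res_a, res_b); rows with undefined (NaN)
    relative risk are dropped with a logged count; at least 3 joined rows
    are required. The divergence variable is ``divergence_total``.
    """
    for col in _JOIN_KEY + ["relative_risk"]:
        if col not in risk_table.columns:
            raise ValueError(f"risk table lacks column {col!r}")
    for col in _JOIN_KEY + ["divergence_total"]:
        if col not in divergence_table.columns:
            raise ValueError(f"divergence table lacks column {col!r}")
    merged = risk_table.merge(divergence_table, on=_JOIN_KEY, how="inner")
    n_before = len(merged)
    merged = merged[np.isfinite(merged["relative_risk"])]
    n_dropped = n_before - len(merged)
    if n_dropped:
        log.info("dropped %d mismatches with undefined relative risk", n_dropped)
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} mismatches shared after join; need at least 3"
        )
    merged = merged.sort_values(_JOIN_KEY).reset_index(drop=True)
    cols = _JOIN_KEY + ["divergence_total", "relative_risk"]
    if "corr_divergence" in merged.columns:
        cols.append("corr_divergence")
    scatter = merged[cols].copy()
    x = scatter["divergence_total"].to_numpy()
    y = scatter["relative_risk"].to_numpy()
    r_p, p_p = pearson_with_p(x, y)
    r_s, p_s = spearman_with_p(x, y)
    return AssociationResult(
        n=len(scatter),
        pearson_r=r_p,
        pearson_p=p_p,
        spearman_r=r_s,
        spearman_p=p_s,
        scatter=scatter,
        n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class MeasureConcordance:
    """Agreement of profile-JSD and affinity-correlation divergences."""

    pearson_r: float
    pearson_p: float
    jsd_totals: np.ndarray
    affinity_divergences: np.ndarray


def compare_divergence_measures(
    profile_pairs: list[tuple[BindingProfile, BindingProfile]],
    panel: PeptidePanel | None = None,
    alpha: float = 0.001,
    panel_seed: int = 0,
    panel_size: int = 10000,
) -> MeasureConcordance:
    """Correlate total JSD with 1 - r(affinity) over a family of pairs.

    Both divergences are computed for every profile pair (on a shared
    random peptide panel for the affinity measure) and their Pearson
    correlation returned. Degenerate variance is flagged, not coerced.
    """
    if len(profile_pairs) < 3:
        raise ValueError("need at least 3 profile pairs")
    if panel is None:
        panel = make_random_panel(panel_size, panel_seed)
    jsd = np.array([profile_divergence(a, b).total for a, b in profile_pairs])
    corr = np.array(
        [affinity_correlation_divergence(a, b, panel, alpha) for a, b in profile_pairs]
    )
    r, p = pearson_with_p(jsd, corr)
    return MeasureConcordance(
        pearson_r=r, pearson_p=p, jsd_totals=jsd, affinity_divergences=corr
    )
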