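"""Differential-abundance marker discovery between two sample groups.

Each feature is compared with a two-sided Mann-Whitney U test (exact for
small tie-free samples, tie-corrected normal approximation otherwise);
p-values are Benjamini-Hochberg adjusted across all tested (non-constant)
features; a feature is called a marker when q < 0.05 and its pseudocounted
fold change passes a 1.2x screen in either direction.  The pseudocount is
half the smallest nonzero abundance in the matrix, keeping the fold change
scale-aware when one group mean is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

Q_THRESHOLD = 0.05
FC_THRESHOLD = 1.2


@dataclass
class MarkerRecord:
    feature_id: str
    mean_a: float
    mean_b: float
    fold_change: float
    u_stat: float
    p: float
    q: float
    enriched_in: str | None


def mwu_test(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample).  Returns (U, p);
    identical constant samples give p = 1."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        return a.size * b.size / 2.0, 1.0
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and tie_free) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_markers(
    abundances: pd.DataFrame,
    groups: pd.Series,
    q_threshold: float = Q_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    use_fc_gate: bool = True,
) -> pd.DataFrame:
    """Per-feature group comparison over a samples x features matrix.

    ``groups`` must take exactly two labels; means/U are oriented with the
    lexicographically first label as group A.  Features that are zero (or
    constant) across all samples are excluded before testing and do not
    count toward the BH denominator.  ``use_fc_gate=False`` calls markers
    on q < ``q_threshold`` alone.
    """
    groups = groups.loc[abundances.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    la, lb = labels
    x = abundances.to_numpy(dtype=float)
    mask_a = (groups == la).to_numpy()
    mask_b = ~mask_a

    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        log.info("excluding %d constant features before testing",
                 int(constant.sum()))
    keep = ~constant
    xa, xb = x[mask_a][:, keep], x[mask_b][:, keep]
    features = abundances.columns[keep]

    res = mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic",
                       axis=0)
    u = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # identical-sample columns can yield nan under the tie correction
    p = np.where(np.isnan(p), 1.0, np.clip(p, 0.0, 1.0))
    q = bh_adjust(p)

    mean_a = xa.mean(axis=0)
    mean_b = xb.mean(axis=0)
    nonzero = x[:, keep][x[:, keep] > 0]
    eps = 0.5 * nonzero.min() if nonzero.size else 1e-12
    fc = (mean_a + eps) / (mean_b + eps)

    fc_pass = ((fc > fc_threshold) | (fc < 1.0 / fc_threshold)
               if use_fc_gate else np.ones_like(fc, dtype=bool))
    is_marker = (q < q_threshold) & fc_pass
    enriched = np.where(is_marker,
                        np.where(mean_a > mean_b, la, lb), "")

    return pd.DataFrame({
        "feature_id": features,
        "mean_a": mean_a, "mean_b": mean_b,
        "fold_change": fc, "u_stat": u,
        "p": p, "q": q,
        "enriched_in": enriched,
    }).reset_index(drop=True)


def markers_only(table: pd.DataFrame) -> pd.DataFrame:
    return table[table["enriched_in"] != ""].reset_index(drop=True)
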