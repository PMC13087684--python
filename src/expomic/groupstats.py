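"""Group-comparison statistics and quartile prevalence-shift analysis.

Mann-Whitney U tests (with BH adjustment across variables), PERMANOVA on
a precomputed dissimilarity matrix, and per-taxon prevalence comparison
between high- and low-exposure quartiles (Fisher's exact test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "PermanovaResult",
    "mann_whitney",
    "permanova",
    "prevalence_shift",
]


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The U statistic reported is for ``group_a``.  An exact p-value is
    computed by enumeration of rank assignments when ``n1 * n2 <= 400``
    and the pooled data are tie-free; otherwise the normal approximation
    with tie correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size * b.size <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PermanovaResult:
    """PERMANOVA on a distance matrix: pseudo-F, R^2 and permutation p."""

    pseudo_f: float
    r2: float
    pvalue: float
    n_permutations: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Total and within-group sums of squares from squared distances.

    Uses the Gower identity: for a set of m points,
    SS = sum_{i<j} d_ij^2 / m.
    """
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total, ss_within


def permanova(
    distance: pd.DataFrame | np.ndarray,
    labels: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate analysis of variance.

    The pseudo-F statistic is built from among/within sums of squares
    computed directly on the distance matrix; the p-value counts
    label permutations with ``F_perm >= F_obs`` using the add-one
    convention ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    D = np.asarray(distance, dtype=float)
    labels = np.asarray(labels)
    n = D.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length must match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    k = groups.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 1):
        raise ValueError("empty group")
    d2 = D ** 2
    ss_total, ss_within = _permanova_ss(d2, labels)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    with np.errstate(divide="ignore"):
        f_obs = (ss_among / df_among) / (ss_within / df_within)
    r2 = ss_among / ss_total
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        sst_p, ssw_p = _permanova_ss(d2, perm)
        with np.errstate(divide="ignore"):
            f_perm = ((sst_p - ssw_p) / df_among) / (ssw_p / df_within)
        if f_perm >= f_obs:
            count_ge += 1
    pvalue = (1 + count_ge) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(pvalue), n_perm)


def prevalence_shift(
    table: pd.DataFrame,
    exposure: pd.Series,
    taxa: Sequence[str] | None = None,
    test: str = "fisher",
) -> pd.DataFrame:
    """Per-taxon prevalence difference between exposure quartiles.

    High = samples strictly above the 75th percentile of ``exposure``;
    low = strictly below the 25th (boundary ties excluded).  Prevalence
    is the fraction of quartile samples with count > 0; the difference
    is reported in percentage points (high - low).  Two-sided Fisher's
    exact test per taxon (``test="chi2"`` switches to the chi-squared
    test), BH adjustment across taxa.
    """
    exposure = exposure.loc[table.index]
    vals = exposure.dropna()
    if vals.size < 8:
        raise ValueError("need >= 8 non-missing exposure values")
    q1, q3 = np.percentile(vals, [25, 75])
    if q1 == q3:
        raise ValueError("degenerate quartiles: exposure nearly constant")
    high_idx = vals.index[vals > q3]
    low_idx = vals.index[vals < q1]
    if len(high_idx) == 0 or len(low_idx) == 0:
        raise ValueError("empty quartile after boundary-tie exclusion")
    logger.info("prevalence quartiles: high n=%d, low n=%d",
                len(high_idx), len(low_idx))
    if taxa is None:
        taxa = list(table.columns)
    rows = []
    for taxon in taxa:
        present_high = int((table.loc[high_idx, taxon] > 0).sum())
        present_low = int((table.loc[low_idx, taxon] > 0).sum())
        n_high, n_low = len(high_idx), len(low_idx)
        prev_high = present_high / n_high
        prev_low = present_low / n_low
        ctab = [[present_high, n_high - present_high],
                [present_low, n_low - present_low]]
        if test == "fisher":
            _, p = stats.fisher_exact(ctab, alternative="two-sided")
        elif test == "chi2":
            p = stats.chi2_contingency(ctab, correction=True)[1]
        else:
            raise ValueError("test must be 'fisher' or 'chi2'")
        rows.append({
            "taxon": taxon,
            "prevalence_high": prev_high,
            "prevalence_low": prev_low,
            "difference_pp": 100.0 * (prev_high - prev_low),
            "pvalue": p,
        })
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["pvalue"].values)
    return out
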