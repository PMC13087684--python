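"""Bivariate exposure -> mediator/outcome association screening.

Each exposure column is regressed against each dependent-variable column
separately (ordinary least squares with heteroskedasticity-consistent
HC1 standard errors, listwise deletion per pair).  P-values are adjusted
by Benjamini-Hochberg within a configurable family (per dependent
variable by default, or globally), and an association counts as
significant only under the dual criterion:

    FDR-adjusted p < 0.05  AND  95% CI for beta excludes 0
    AND adjusted R^2 > 0.005.

The signed effect-size matrix encodes ``sign(beta) * adjusted R^2`` for
significant pairs and 0 elsewhere, ready for heatmap export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "ScreenResults",
    "AssociationScreen",
    "bivariate_ols_robust",
    "bh_fdr",
    "screen",
    "axis_taxa_correlation",
]


@dataclass(frozen=True)
class AssociationResult:
    """Summary of one bivariate exposure-DV regression."""

    x: str
    dv: str
    beta: float
    robust_se: float
    ci_low: float
    ci_high: float
    adj_r2: float
    pvalue: float
    fdr: float = float("nan")
    significant: bool = False
    n: int = 0


def bivariate_ols_robust(
    x, y, cov_type: str = "HC1", alpha: float = 0.05
) -> AssociationResult:
    """OLS of y on x with a sandwich (HC1) covariance estimate.

    Listwise deletion of incomplete pairs; requires >= 3 complete pairs
    and non-constant x.  Returns the slope, robust SE, Wald CI, adjusted
    R^2 and the robust p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant exposure column")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit(cov_type=cov_type)
    beta = fit.params[1]
    se = fit.bse[1]
    lo, hi = fit.conf_int(alpha=alpha)[1]
    adj_r2 = 1.0 - (1.0 - fit.rsquared) * (n - 1) / (n - 2)
    return AssociationResult(
        x="x", dv="y", beta=float(beta), robust_se=float(se),
        ci_low=float(lo), ci_high=float(hi), adj_r2=float(adj_r2),
        pvalue=float(fit.pvalues[1]), n=n,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class ScreenResults:
    """Results container for :class:`AssociationScreen`.

    Attributes
    ----------
    table : DataFrame
        One row per (exposure, DV) pair with beta, robust SE, CI,
        adjusted R^2, raw and FDR p, significance flag and n.
    signed_r2 : DataFrame
        Exposures x DVs matrix of ``sign(beta) * adjR^2`` where the dual
        criterion holds, 0 elsewhere.
    """

    def __init__(self, table: pd.DataFrame, signed_r2: pd.DataFrame,
                 metadata: dict):
        self.table = table
        self.signed_r2 = signed_r2
        self.metadata = metadata

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_pairs(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        md = self.metadata
        lines = [
            "Association screen",
            "==================",
            f"exposures: {md['n_x']}   dependent variables: {md['n_dv']}",
            f"FDR family: {md['fdr_family']}   "
            f"dual criterion: FDR < {md['fdr_cut']} and adjR2 > {md['r2_cut']}",
            f"significant associations: {self.n_significant} "
            f"of {len(self.table)} tested",
        ]
        return "\n".join(lines)


class AssociationScreen:
    """Bivariate robust-SE screen of every exposure against every DV.

    Parameters
    ----------
    exposures : DataFrame
        Participants x exposure columns (numeric; NaN allowed).
    targets : DataFrame
        Participants x dependent-variable columns, index-aligned with
        ``exposures``.
    fdr_family : {"per-dv", "global"}
        Whether BH adjustment pools all exposures against one DV
        (default; one family per index/outcome) or all pairs globally.
    """

    def __init__(
        self,
        exposures: pd.DataFrame,
        targets: pd.DataFrame,
        fdr_family: Literal["per-dv", "global"] = "per-dv",
    ):
        self.exposures = exposures
        self.targets = targets.loc[exposures.index]
        if fdr_family not in ("per-dv", "global"):
            raise ValueError("fdr_family must be 'per-dv' or 'global'")
        self.fdr_family = fdr_family

    def fit(self, fdr_cut: float = 0.05, r2_cut: float = 0.005) -> ScreenResults:
        rows = []
        for dv in self.targets.columns:
            y = self.targets[dv]
            for xname in self.exposures.columns:
                try:
                    res = bivariate_ols_robust(self.exposures[xname], y)
                except ValueError as err:
                    logger.warning("skipping (%s, %s): %s", xname, dv, err)
                    continue
                rows.append({
                    "x": xname, "dv": dv, "beta": res.beta,
                    "robust_se": res.robust_se, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "adj_r2": res.adj_r2,
                    "pvalue": res.pvalue, "n": res.n,
                })
        table = pd.DataFrame(rows)
        if table.empty:
            raise ValueError("no estimable exposure-DV pairs")
        if self.fdr_family == "per-dv":
            table["fdr"] = table.groupby("dv", sort=False)["pvalue"].transform(
                lambda p: bh_fdr(p.values))
        else:
            table["fdr"] = bh_fdr(table["pvalue"].values)
        ci_excl0 = (table["ci_low"] > 0) | (table["ci_high"] < 0)
        table["significant"] = (
            (table["fdr"] < fdr_cut) & ci_excl0 & (table["adj_r2"] > r2_cut)
        )
        signed = pd.DataFrame(
            0.0, index=self.exposures.columns, columns=self.targets.columns)
        for _, r in table[table["significant"]].iterrows():
            signed.loc[r["x"], r["dv"]] = np.sign(r["beta"]) * r["adj_r2"]
        metadata = {
            "n_x": self.exposures.shape[1], "n_dv": self.targets.shape[1],
            "fdr_family": self.fdr_family, "fdr_cut": fdr_cut,
            "r2_cut": r2_cut,
        }
        return ScreenResults(table, signed, metadata)


def screen(
    X: pd.DataFrame,
    DV: pd.DataFrame,
    fdr_cut: float = 0.05,
    r2_cut: float = 0.005,
    fdr_family: Literal["per-dv", "global"] = "per-dv",
) -> ScreenResults:
    """Functional wrapper: ``AssociationScreen(X, DV, fdr_family).fit()``."""
    return AssociationScreen(X, DV, fdr_family=fdr_family).fit(
        fdr_cut=fdr_cut, r2_cut=r2_cut)


def axis_taxa_correlation(
    axis: pd.Series,
    taxa_relabund: pd.DataFrame,
    fdr_cut: float = 0.05,
    r_cut: float = 0.2,
) -> pd.DataFrame:
    """Taxa whose relative abundance tracks an ordination axis.

    Pearson correlation of each taxon with the axis scores, BH-adjusted
    across taxa; retained when FDR < ``fdr_cut`` and ``|r| > r_cut``.
    Zero-variance taxa are skipped with a log message.

    Returns a DataFrame (taxon, r, pvalue, fdr, retained).
    """
    a = np.asarray(axis, dtype=float)
    rows = []
    for taxon in taxa_relabund.columns:
        v = np.asarray(taxa_relabund[taxon], dtype=float)
        if v.size != a.size:
            raise ValueError("axis and taxa lengths differ")
        if np.ptp(v[np.isfinite(v)]) == 0:
            logger.info("skipping zero-variance taxon %s", taxon)
            continue
        keep = np.isfinite(a) & np.isfinite(v)
        r, p = stats.pearsonr(a[keep], v[keep])
        rows.append({"taxon": taxon, "r": r, "pvalue": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(fdr=[], retained=[])
    out["fdr"] = bh_fdr(out["pvalue"].values)
    out["retained"] = (out["fdr"] < fdr_cut) & (out["r"].abs() > r_cut)
    return out
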