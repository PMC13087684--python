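"""Direct and microbiome-mediated (indirect) effects for X -> M -> Y triplets.

The model follows the causal-steps decomposition for a single continuous
mediator M between an exposure X and an outcome Y, adjusting every
regression for a shared covariate set (age and sex by default):

    continuous Y:   Y = c X + e1          (total effect)
                    M = a X + e2          (exposure -> mediator)
                    Y = c' X + b M + e3   (direct + mediator paths)

    binary Y:       path a by linear regression of M on X;
                    c and (c', b) by logistic regression of Y, so those
                    coefficients live on the log-odds scale.

The indirect effect is ab = a * b.  Its 95% CI comes from nonparametric
bootstrap percentiles (continuous outcomes) or from the exact
distribution of the product of two independent normal estimates
(binary outcomes), which is asymmetric in general.  The proportion
mediated is ab/c (signed; may fall outside [0, 1] under inconsistent
mediation).  Each pathway is classified as full, partial, inconsistent
or none:

    ab not significant                          -> none
    ab significant, c' not                      -> full
    both significant, same sign                 -> partial
    both significant, opposite signs            -> inconsistent

Continuous exposures are Z-score standardized on the analysis sample
(after listwise deletion) before fitting, so path coefficients are per
SD of exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "TripletSpec",
    "MediationModel",
    "MediationResults",
    "mediate_continuous",
    "mediate_binary",
    "dist_of_product_ci",
    "classify",
    "proportion_mediated",
    "select_triplets",
]


# ---------------------------------------------------------------------------
# distribution-of-product confidence interval

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def _segments(lo: float, hi: float) -> np.ndarray:
    """Panel boundaries on [lo, hi] (0 < lo < hi), geometrically refined
    towards lo to resolve the CDF transition near x = 0."""
    n_geo = 24
    geo = lo * (hi / lo) ** (np.arange(n_geo + 1) / n_geo)
    return geo


def _panel_quad(f, bounds: np.ndarray) -> float:
    """Gauss-Legendre quadrature of f over consecutive panels, vectorized."""
    a, b = bounds[:-1], bounds[1:]
    mid = 0.5 * (a + b)[:, None]
    half = 0.5 * (b - a)[:, None]
    x = mid + half * _GL_NODES[None, :]
    return float((half * f(x) * _GL_WEIGHTS[None, :]).sum())


def _product_cdf(z: float, a: float, se_a: float, b: float, se_b: float) -> float:
    """P(U * V <= z) for independent U ~ N(a, se_a^2), V ~ N(b, se_b^2).

    Conditioning on U = x: P(V <= z/x) for x > 0 and P(V >= z/x) for
    x < 0, integrated against the density of U by panelled
    Gauss-Legendre quadrature (panels refined towards the x = 0 kink).
    """
    # integration range: support of the U density, clipped away from 0
    span = 10.0 * se_a
    eps = 1e-12 * max(se_a, abs(a), 1.0)

    def pos_part(x):
        return stats.norm.pdf(x, a, se_a) * stats.norm.cdf(z / x, b, se_b)

    def neg_part(x):
        return stats.norm.pdf(x, a, se_a) * stats.norm.sf(z / x, b, se_b)

    total = 0.0
    hi = a + span
    if hi > 0:
        lo = max(eps, a - span)
        total += _panel_quad(pos_part, _segments(lo, hi))
    lo = a - span
    if lo < 0:
        hi_neg = min(-eps, a + span)
        total += _panel_quad(neg_part, -_segments(-hi_neg, -lo)[::-1])
    # mass of U below the clipped-out regions is negligible (10 sigma)
    return total


def dist_of_product_ci(
    a: float, se_a: float, b: float, se_b: float, level: float = 0.95
) -> tuple[float, float]:
    """Asymmetric CI for ab from the distribution of a product of normals.

    Computes the (1 - level)/2 and (1 + level)/2 quantiles of
    ``N(a, se_a^2) * N(b, se_b^2)`` (independent factors) by numerical
    evaluation of the product CDF and root finding.
    """
    for name, val in (("a", a), ("se_a", se_a), ("b", b), ("se_b", se_b)):
        if not np.isfinite(val):
            raise ValueError(f"non-finite input {name}={val}")
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    mean = a * b
    sd = np.sqrt(a * a * se_b * se_b + b * b * se_a * se_a
                 + se_a * se_a * se_b * se_b)
    lo_q, hi_q = (1.0 - level) / 2.0, (1.0 + level) / 2.0

    def quantile(q: float) -> float:
        lo, hi = mean - 20 * sd, mean + 20 * sd
        # widen until the bracket surrounds the quantile
        while _product_cdf(lo, a, se_a, b, se_b) > q:
            lo -= 20 * sd
        while _product_cdf(hi, a, se_a, b, se_b) < q:
            hi += 20 * sd
        return optimize.brentq(
            lambda z: _product_cdf(z, a, se_a, b, se_b) - q,
            lo, hi, xtol=1e-7 * sd, rtol=4e-10)

    return quantile(lo_q), quantile(hi_q)


# ---------------------------------------------------------------------------
# classification and proportion mediated

def classify(
    ab: float,
    ab_ci: tuple[float, float],
    c_prime: float,
    c_prime_p: float,
    alpha: float = 0.05,
) -> str:
    """Classify a mediation pathway.

    ``ab`` is significant when its CI excludes zero; ``c'`` when its
    p-value is below ``alpha``.
    """
    ab_sig = ab_ci[0] > 0 or ab_ci[1] < 0
    cp_sig = c_prime_p < alpha
    if not ab_sig:
        return "none"
    if not cp_sig:
        return "full"
    return "partial" if np.sign(ab) == np.sign(c_prime) else "inconsistent"


def proportion_mediated(ab: float, c: float) -> tuple[float, str]:
    """ab/c with flags: 'undefined' when |c| ~ 0, 'out_of_range' when the
    signed ratio falls outside [0, 1] (inconsistent mediation)."""
    if abs(c) < 1e-8:
        return float("nan"), "undefined"
    ratio = ab / c
    flag = "ok" if 0.0 <= ratio <= 1.0 else "out_of_range"
    return float(ratio), flag


# ---------------------------------------------------------------------------
# model / results

@dataclass(frozen=True)
class TripletSpec:
    """One (exposure, mediator, outcome) pathway to test."""

    x: str
    m: str
    y: str
    y_type: Literal["continuous", "binary"] = "continuous"
    covariates: tuple[str, ...] = ("age", "sex")


def select_triplets(
    mediator_screen, outcome_screen, y_types: dict | None = None,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> list[TripletSpec]:
    """Cross each exposure's significant mediators with its significant
    outcomes.

    Both arguments are :class:`~expomic.screen.ScreenResults`; only
    exposures significant in *both* screens yield triplets.
    """
    m_sig = mediator_screen.significant_pairs()
    y_sig = outcome_screen.significant_pairs()
    y_types = y_types or {}
    triplets = []
    for x in sorted(set(m_sig["x"]) & set(y_sig["x"])):
        ms = sorted(m_sig.loc[m_sig["x"] == x, "dv"])
        ys = sorted(y_sig.loc[y_sig["x"] == x, "dv"])
        for m in ms:
            for y in ys:
                triplets.append(TripletSpec(
                    x=x, m=m, y=y,
                    y_type=y_types.get(y, "continuous"),
                    covariates=covariates))
    return triplets


class MediationResults:
    """Fitted path coefficients, indirect-effect CI and classification.

    Attributes
    ----------
    a, b, c, c_prime : float
        Path coefficients (b, c, c' on the log-odds scale for binary Y).
    ab : float
        Indirect effect a * b.
    ab_ci : (float, float)
        95% CI for ab (bootstrap percentile or distribution-of-product).
    prop_mediated, prop_flag : float, str
        ab/c and its validity flag; for binary outcomes the mixed
        linear/logistic scale makes this a descriptive, non-collapsible
        quantity (``scale_caveat`` is set).
    classification : {"full", "partial", "inconsistent", "none"}
    """

    def __init__(self, model: "MediationModel", params: dict):
        self.model = model
        for key, val in params.items():
            setattr(self, key, val)
        self.prop_mediated, self.prop_flag = proportion_mediated(self.ab, self.c)
        self.classification = classify(
            self.ab, self.ab_ci, self.c_prime, self.c_prime_p,
            alpha=self.alpha)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Mediation analysis",
            "==================",
            f"exposure:  {m.exposure}   mediator: {m.mediator}   "
            f"outcome: {m.outcome} ({m.outcome_type})",
            f"covariates: {', '.join(m.covariates) or 'none'}    "
            f"n = {self.n}    method = {self.method}",
            "-" * 60,
            f"a  (X -> M)        {self.a: .5f}  (SE {self.se_a:.5f})",
            f"b  (M -> Y | X)    {self.b: .5f}  (SE {self.se_b:.5f})",
            f"c  (total X -> Y)  {self.c: .5f}",
            f"c' (direct X -> Y) {self.c_prime: .5f}  (p = {self.c_prime_p:.3g})",
            f"ab (indirect)      {self.ab: .5f}  "
            f"95% CI [{self.ab_ci[0]:.5f}, {self.ab_ci[1]:.5f}]",
            f"proportion mediated (ab/c): {self.prop_mediated:.4f} "
            f"[{self.prop_flag}]",
            f"classification: {self.classification}",
        ]
        if self.model.outcome_type == "binary":
            lines.append(
                "note: b, c, c' are log-odds; ab/c mixes linear and "
                "logistic scales (non-collapsibility caveat)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "x": self.model.exposure, "m": self.model.mediator,
            "y": self.model.outcome, "y_type": self.model.outcome_type,
            "a": self.a, "se_a": self.se_a, "b": self.b, "se_b": self.se_b,
            "c": self.c, "c_prime": self.c_prime,
            "c_prime_p": self.c_prime_p, "ab": self.ab,
            "ab_ci_low": self.ab_ci[0], "ab_ci_high": self.ab_ci[1],
            "prop_mediated": self.prop_mediated, "prop_flag": self.prop_flag,
            "classification": self.classification, "method": self.method,
            "n": self.n, "seed": self.seed,
        }


class MediationModel:
    """Single-mediator mediation model with covariate adjustment.

    Parameters
    ----------
    data : DataFrame
        Analysis table holding exposure, mediator, outcome and covariate
        columns.  Rows with a missing value in any used column are
        dropped (listwise deletion); the exposure is then Z-scored on
        the retained rows.
    exposure, mediator, outcome : str
        Column names for X, M, Y.
    outcome_type : {"continuous", "binary"}
        Chooses the OLS/OLS (bootstrap CI) or OLS/logistic
        (distribution-of-product CI) engine.
    covariates : sequence of str
        Confounders entered in every regression (default age, sex).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        exposure: str,
        mediator: str,
        outcome: str,
        outcome_type: Literal["continuous", "binary"] = "continuous",
        covariates: Sequence[str] = ("age", "sex"),
    ):
        self.exposure = exposure
        self.mediator = mediator
        self.outcome = outcome
        self.outcome_type = outcome_type
        self.covariates = tuple(c for c in covariates if c in data.columns)
        dropped = set(covariates) - set(self.covariates)
        if dropped:
            logger.warning("covariates absent from data, ignored: %s",
                           sorted(dropped))
        cols = [exposure, mediator, outcome, *self.covariates]
        frame = data[cols].dropna()
        if frame.shape[0] < 10:
            raise ValueError(
                f"only {frame.shape[0]} complete rows; need >= 10")
        x = frame[exposure].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("constant exposure after listwise deletion")
        # binary/dummy exposures are left on their natural 0/1 scale
        if np.unique(x).size > 2:
            x = (x - x.mean()) / sd
        self._x = x
        self._m = frame[mediator].to_numpy(dtype=float)
        self._y = frame[outcome].to_numpy(dtype=float)
        self._cov = frame[list(self.covariates)].to_numpy(dtype=float) \
            if self.covariates else np.empty((frame.shape[0], 0))
        self.nobs = frame.shape[0]
        if outcome_type == "binary":
            classes = np.unique(self._y)
            if not np.all(np.isin(classes, (0.0, 1.0))):
                raise ValueError("binary outcome must be coded 0/1")
            if classes.size < 2:
                raise ValueError("binary outcome has a single class")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: TripletSpec
                       ) -> "MediationModel":
        return cls(data, spec.x, spec.m, spec.y,
                   outcome_type=spec.y_type, covariates=spec.covariates)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_boot: int = 5000,
        seed: int | None = None,
        alpha: float = 0.05,
    ) -> MediationResults:
        if self.outcome_type == "continuous":
            return self._fit_continuous(n_boot=n_boot, seed=seed, alpha=alpha)
        return self._fit_binary(seed=seed, alpha=alpha)

    def _design(self, with_m: bool) -> np.ndarray:
        cols = [np.ones(self.nobs), self._x]
        if with_m:
            cols.append(self._m)
        X = np.column_stack(cols + [self._cov])
        return X

    def _fit_continuous(self, n_boot: int, seed, alpha: float
                        ) -> MediationResults:
        if n_boot < 100:
            logger.warning("n_boot=%d is very small; CI will be unstable",
                           n_boot)
        Xc = self._design(with_m=False)
        Xm = self._design(with_m=True)
        if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
            raise ValueError("rank-deficient design matrix")
        fit_c = sm.OLS(self._y, Xc).fit()
        fit_a = sm.OLS(self._m, Xc).fit()
        fit_b = sm.OLS(self._y, Xm).fit()
        a, se_a = fit_a.params[1], fit_a.bse[1]
        c = fit_c.params[1]
        c_prime, b = fit_b.params[1], fit_b.params[2]
        se_b = fit_b.bse[2]
        c_prime_p = fit_b.pvalues[1]
        ab = a * b
        # nonparametric bootstrap of rows; a*b recomputed per resample
        rng = np.random.default_rng(seed)
        ab_boot = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, self.nobs, self.nobs)
            Xa_i, Xb_i = Xc[idx], Xm[idx]
            beta_a = np.linalg.lstsq(Xa_i, self._m[idx], rcond=None)[0]
            beta_b = np.linalg.lstsq(Xb_i, self._y[idx], rcond=None)[0]
            ab_boot[i] = beta_a[1] * beta_b[2]
        lo, hi = np.percentile(
            ab_boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        params = dict(
            a=float(a), se_a=float(se_a), b=float(b), se_b=float(se_b),
            c=float(c), c_prime=float(c_prime), c_prime_p=float(c_prime_p),
            ab=float(ab), ab_ci=(float(lo), float(hi)),
            method="bootstrap", n=self.nobs, seed=seed, alpha=alpha,
            ab_boot_sd=float(ab_boot.std(ddof=1)),
        )
        return MediationResults(self, params)

    def _fit_binary(self, seed, alpha: float) -> MediationResults:
        Xc = self._design(with_m=False)
        Xm = self._design(with_m=True)
        fit_a = sm.OLS(self._m, Xc).fit()
        try:
            fit_c = sm.Logit(self._y, Xc).fit(disp=0)
            fit_b = sm.Logit(self._y, Xm).fit(disp=0)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"logistic fit failed: {err}") from err
        if not (np.all(np.isfinite(fit_c.bse)) and np.all(np.isfinite(fit_b.bse))):
            raise ValueError(
                "perfect separation detected in logistic fit for outcome "
                f"{self.outcome!r}")
        a, se_a = fit_a.params[1], fit_a.bse[1]
        c = fit_c.params[1]
        c_prime, b = fit_b.params[1], fit_b.params[2]
        se_b = fit_b.bse[2]
        c_prime_p = fit_b.pvalues[1]
        ab = a * b
        lo, hi = dist_of_product_ci(a, se_a, b, se_b, level=1 - alpha)
        params = dict(
            a=float(a), se_a=float(se_a), b=float(b), se_b=float(se_b),
            c=float(c), c_prime=float(c_prime), c_prime_p=float(c_prime_p),
            ab=float(ab), ab_ci=(float(lo), float(hi)),
            method="dist_of_product", n=self.nobs, seed=seed, alpha=alpha,
        )
        res = MediationResults(self, params)
        res.scale_caveat = True
        return res


# ---------------------------------------------------------------------------
# functional wrappers

def mediate_continuous(
    X, M, Y, covariates: pd.DataFrame | None = None,
    n_boot: int = 5000, seed: int | None = None,
) -> MediationResults:
    """Continuous-outcome mediation with bootstrap percentile CI."""
    frame = _assemble(X, M, Y, covariates)
    model = MediationModel(
        frame, "x", "m", "y", outcome_type="continuous",
        covariates=tuple(c for c in frame.columns if c not in ("x", "m", "y")))
    return model.fit(n_boot=n_boot, seed=seed)


def mediate_binary(
    X, M, Y, covariates: pd.DataFrame | None = None,
    seed: int | None = None,
) -> MediationResults:
    """Binary-outcome mediation with distribution-of-product CI."""
    frame = _assemble(X, M, Y, covariates)
    model = MediationModel(
        frame, "x", "m", "y", outcome_type="binary",
        covariates=tuple(c for c in frame.columns if c not in ("x", "m", "y")))
    return model.fit(seed=seed)


def _assemble(X, M, Y, covariates) -> pd.DataFrame:
    frame = pd.DataFrame({"x": np.asarray(X, dtype=float),
                          "m": np.asarray(M, dtype=float),
                          "y": np.asarray(Y, dtype=float)})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for col in cov.columns:
            frame[str(col)] = cov[col].to_numpy(dtype=float)
    return frame
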