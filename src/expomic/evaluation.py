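"""Simulation studies of the pipeline's statistical operating characteristics.

Self-contained studies used to validate the estimators on synthetic data
with known ground truth: parameter recovery and CI coverage of the
mediation engines, accuracy of the distribution-of-product CI against a
Monte-Carlo oracle, false-positive control of the dual-criterion screen,
type-I error of the group-comparison tests, and the acceptance behaviour
of the KS-gated subsampler.  Every study takes a single integer seed and
is deterministic given it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .groupstats import mann_whitney, permanova
from .mediation import dist_of_product_ci, mediate_binary, mediate_continuous
from .screen import screen
from .synthetic import SyntheticTruth, generate_city_samples, \
    generate_mediation_triplet
from .environment import subsample_city

__all__ = [
    "frequency_codes",
    "mediation_identity_error",
    "dop_ci_grid_accuracy",
    "mediation_recovery_study",
    "null_screen_fpr",
    "mann_whitney_type_i",
    "permanova_type_i",
    "subsampler_first_draw_acceptance",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds below 2^31 derived from one master seed."""
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def frequency_codes(decimals: int = 3) -> dict[str, float]:
    """The daily-occurrence questionnaire codes, rounded for printing."""
    from .exposures import FREQUENCY_CODES
    return {k: round(v, decimals) for k, v in FREQUENCY_CODES.items()}


def mediation_identity_error(n: int = 500, seed: int = 0) -> float:
    """|c - (c' + a b)| for a continuous-outcome triplet with shared
    covariates (exact OLS decomposition; should be ~ machine precision)."""
    truth = SyntheticTruth("identity", a=0.5, b=0.4, c_prime=0.3,
                           n=n, seed=int(seed))
    x, m, y, cov = generate_mediation_triplet(truth)
    res = mediate_continuous(x, m, y, cov, n_boot=100, seed=int(seed))
    return abs(res.c - (res.c_prime + res.a * res.b))


def dop_ci_grid_accuracy(
    z_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 5.0),
    se: float = 0.1,
    n_draws: int = 2_000_000,
    seed: int = 0,
) -> dict:
    """Worst-case endpoint error of the distribution-of-product CI
    against a Monte-Carlo oracle over a grid of standardized effects.

    For each pair of standardized effects (z_a, z_b) the CI for the
    product of N(z_a*se, se^2) and N(z_b*se, se^2) is compared with the
    empirical 2.5%/97.5% quantiles of ``n_draws`` simulated products.
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for za in z_grid:
        for zb in z_grid:
            a, b = za * se, zb * se
            lo, hi = dist_of_product_ci(a, se, b, se)
            draws = rng.normal(a, se, n_draws) * rng.normal(b, se, n_draws)
            mlo, mhi = np.percentile(draws, [2.5, 97.5])
            max_err = max(max_err, abs(lo - mlo), abs(hi - mhi))
    return {"max_endpoint_error": float(max_err),
            "grid_points": len(z_grid) ** 2, "n_draws": n_draws}


def mediation_recovery_study(
    outcome_type: str = "continuous",
    n: int = 5000,
    a: float = 0.5,
    b: float = 0.4,
    c_prime: float = 0.3,
    reps: int = 500,
    n_boot: int = 300,
    seed: int = 0,
) -> dict:
    """Parameter recovery and CI coverage of the mediation engines.

    Simulates ``reps`` cohorts with planted paths, fits the matching
    engine, and reports the mean estimated indirect effect ab and the
    fraction of 95% CIs covering the planted ab.
    """
    planted_ab = a * b
    seeds = _child_seeds(seed, 2 * reps)
    abs_, covered = [], 0
    for i in range(reps):
        truth = SyntheticTruth(
            f"rep{i}", a=a, b=b, c_prime=c_prime, n=n,
            seed=int(seeds[i]), outcome_type=outcome_type,
            baseline=-1.0 if outcome_type == "binary" else 0.0)
        x, m, y, cov = generate_mediation_triplet(truth)
        if outcome_type == "continuous":
            res = mediate_continuous(x, m, y, cov, n_boot=n_boot,
                                     seed=int(seeds[reps + i]))
        else:
            res = mediate_binary(x, m, y, cov, seed=int(seeds[reps + i]))
        abs_.append(res.ab)
        covered += res.ab_ci[0] <= planted_ab <= res.ab_ci[1]
    return {
        "mean_ab": float(np.mean(abs_)),
        "planted_ab": planted_ab,
        "relative_error": float(abs(np.mean(abs_) - planted_ab) / planted_ab),
        "coverage": covered / reps,
        "reps": reps,
        "n": n,
    }


def null_screen_fpr(
    n_x: int = 50,
    n_dv: int = 10,
    n: int = 1000,
    reps: int = 20,
    seed: int = 0,
) -> dict:
    """False-positive fraction of the dual-criterion screen on fully
    null data (independent standard normals), averaged over replicates."""
    seeds = _child_seeds(seed, reps)
    rates = []
    for s in seeds:
        r = np.random.default_rng(int(s))
        X = pd.DataFrame(r.standard_normal((n, n_x)),
                         columns=[f"x{i}" for i in range(n_x)])
        DV = pd.DataFrame(r.standard_normal((n, n_dv)),
                          columns=[f"dv{i}" for i in range(n_dv)])
        res = screen(X, DV)
        rates.append(res.n_significant / (n_x * n_dv))
    return {"mean_fpr": float(np.mean(rates)), "reps": reps,
            "pairs_per_rep": n_x * n_dv, "n": n}


def mann_whitney_type_i(
    reps: int = 500, n: int = 50, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Rejection rate of the Mann-Whitney test under the null."""
    seeds = _child_seeds(seed, reps)
    rej = 0
    for s in seeds:
        r = np.random.default_rng(int(s))
        _, p = mann_whitney(r.standard_normal(n), r.standard_normal(n))
        rej += p < alpha
    return {"type_i": rej / reps, "reps": reps, "n_per_group": n}


def permanova_type_i(
    reps: int = 500, n: int = 24, n_perm: int = 99,
    alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Rejection rate of PERMANOVA under random labels on iid data."""
    from scipy.spatial.distance import pdist, squareform
    seeds = _child_seeds(seed, reps)
    rej = 0
    for s in seeds:
        r = np.random.default_rng(int(s))
        pts = r.standard_normal((n, 3))
        labels = np.repeat(["a", "b"], n // 2)
        res = permanova(squareform(pdist(pts)), labels,
                        n_perm=n_perm, seed=int(s))
        rej += res.pvalue <= alpha
    return {"type_i": rej / reps, "reps": reps, "n_samples": n,
            "n_perm": n_perm}


def subsampler_first_draw_acceptance(
    n_seeds: int = 100, city_n: int = 100, target: int = 55, seed: int = 0
) -> dict:
    """Fraction of seeds for which an iid city's first random subset
    passes the KS gate (expected ~ P(p > 0.05) ~ 0.95 under the null)."""
    city = generate_city_samples(1, [city_n], seed=seed)[0]
    seeds = _child_seeds(seed, n_seeds)
    first = 0
    for s in seeds:
        _, iters = subsample_city(city, target, seed=int(s))
        first += iters == 1
    return {"first_draw_acceptance": first / n_seeds, "n_seeds": n_seeds,
            "city_n": city_n, "target": target}
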