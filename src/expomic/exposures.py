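"""Derivation of the coded independent-variable (exposure) matrix.

Turns raw questionnaire responses, long-format environmental time series,
and regional mycotoxin surveillance tables into numeric exposure columns:

* questionnaire coding — binary yes/no, daily-occurrence frequency scale,
  and 0..N-1 ordinal codes;
* two-step missingness filtering (variables first, then participants);
* greedy Spearman collinearity pruning;
* three-year retrospective exposure windows with fallback to the most
  recent available preceding years;
* dietary mycotoxin exposure from regional representative concentrations
  and weighted food-frequency profiles;
* assignment of participants to city centers within a 5 km radius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FREQUENCY_CODES",
    "MycotoxinSource",
    "FoodFrequencyProfile",
    "code_response",
    "filter_missing",
    "spearman_prune",
    "average_three_year_window",
    "regional_concentration",
    "individual_mycotoxin_exposure",
    "assign_city",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0

# Daily-occurrence equivalents of the food/activity frequency vocabulary.
# Exact quotients are stored; the commonly printed 3-dp values (0.066,
# 0.214, 0.571) are roundings of these.
FREQUENCY_CODES: dict[str, float] = {
    "never": 0.0,
    "rarely": 2.0 / 30.4,        # 2 occurrences per month (30.4 days)
    "occasionally": 1.5 / 7.0,   # 1.5 occurrences per week
    "often": 4.0 / 7.0,          # 4 occurrences per week
    "every day": 1.0,
}

_BINARY_CODES = {
    "yes": 1, "true": 1, "no": 0, "false": 0,
}


@dataclass(frozen=True)
class MycotoxinSource:
    """Regional surveillance record for one toxin in one country/region.

    Parameters
    ----------
    region : str
        Country or region identifier.
    toxin : str
        Mycotoxin name (e.g. ``"DON"``, ``"AFB1"``).
    detection_rate : float
        Fraction of surveyed samples in which the toxin was detected,
        in ``[0, 1]``.
    median_concentration : float
        Median concentration among surveyed samples, in ug/kg (>= 0).
    """

    region: str
    toxin: str
    detection_rate: float
    median_concentration: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_rate <= 1.0:
            raise ValueError(
                f"detection_rate must be in [0, 1], got {self.detection_rate}"
            )
        if self.median_concentration < 0:
            raise ValueError(
                "median_concentration must be >= 0, got "
                f"{self.median_concentration}"
            )


#: Default dimensionless weights of the three mycotoxin-source food groups.
#: Grains carry the bulk of contamination risk, followed by dairy
#: (feed carry-over) and nuts.
DEFAULT_FOOD_WEIGHTS: dict[str, float] = {"grains": 0.5, "dairy": 0.3, "nuts": 0.2}


@dataclass(frozen=True)
class FoodFrequencyProfile:
    """Per-participant intake frequencies for the mycotoxin source foods.

    Frequencies are daily-occurrence codes (times/day); weights default
    to (grains 0.5, dairy 0.3, nuts 0.2).
    """

    grains: float
    dairy: float
    nuts: float
    weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOOD_WEIGHTS)
    )

    def __post_init__(self) -> None:
        for name in ("grains", "dairy", "nuts"):
            if getattr(self, name) < 0:
                raise ValueError(f"frequency {name!r} must be >= 0")


def code_response(question_kind: str, raw_response, n_options: int | None = None):
    """Code a raw questionnaire response as a number.

    Parameters
    ----------
    question_kind : {"binary", "frequency", "ordinal"}
        Coding scheme. ``binary`` maps yes/true -> 1 and no/false -> 0.
        ``frequency`` maps the five-level daily-occurrence vocabulary
        (never, rarely, occasionally, often, every day) onto [0, 1].
        ``ordinal`` maps option index onto 0..N-1 (``raw_response`` may be
        the option itself when ``n_options`` options are given as a list).
    raw_response
        The raw answer. Already-numeric input is returned unchanged
        (idempotence) after range validation where applicable.
    n_options : int or sequence, optional
        For ordinal questions: the option count, or the ordered option
        vocabulary.

    Returns
    -------
    float or int
    """
    if question_kind == "binary":
        if isinstance(raw_response, (int, float, np.integer, np.floating)) \
                and not isinstance(raw_response, bool):
            if raw_response in (0, 1):
                return int(raw_response)
            raise ValueError(f"binary code must be 0 or 1, got {raw_response}")
        key = str(raw_response).strip().lower()
        if isinstance(raw_response, bool):
            key = "true" if raw_response else "false"
        if key in _BINARY_CODES:
            return _BINARY_CODES[key]
        raise ValueError(
            f"unknown binary response {raw_response!r}; allowed: "
            f"{sorted(_BINARY_CODES)}"
        )
    if question_kind == "frequency":
        if isinstance(raw_response, (int, float, np.integer, np.floating)):
            if 0.0 <= float(raw_response) <= 1.0:
                return float(raw_response)
            raise ValueError(
                f"frequency code must be in [0, 1], got {raw_response}"
            )
        key = str(raw_response).strip().lower()
        # tolerate the parenthesised long forms, e.g. "rarely (2 times/month)"
        for name, value in FREQUENCY_CODES.items():
            if key == name or key.startswith(name + " ("):
                return value
        if key in ("daily", "everyday"):
            return 1.0
        raise ValueError(
            f"unknown frequency response {raw_response!r}; allowed: "
            f"{list(FREQUENCY_CODES)}"
        )
    if question_kind == "ordinal":
        if n_options is None:
            raise ValueError("ordinal coding requires n_options")
        if isinstance(n_options, (list, tuple)):
            options = [str(o).strip().lower() for o in n_options]
            if isinstance(raw_response, (int, np.integer)) \
                    and not isinstance(raw_response, bool):
                idx = int(raw_response)
            else:
                key = str(raw_response).strip().lower()
                if key not in options:
                    raise ValueError(
                        f"unknown ordinal response {raw_response!r}; "
                        f"allowed: {list(n_options)}"
                    )
                idx = options.index(key)
            n = len(options)
        else:
            idx = int(raw_response)
            n = int(n_options)
        if not 0 <= idx <= n - 1:
            raise ValueError(f"ordinal code must be in 0..{n - 1}, got {idx}")
        return idx
    raise ValueError(
        f"unknown question_kind {question_kind!r}; "
        "expected binary, frequency or ordinal"
    )


def filter_missing(
    table: pd.DataFrame,
    var_threshold: float = 0.5,
    sample_threshold: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Two-step missingness filter: variables first, then participants.

    Variables whose missing fraction is strictly greater than
    ``var_threshold`` are dropped; participants (rows) missing strictly
    more than ``sample_threshold`` of the *remaining* variables are then
    dropped.

    Returns
    -------
    (filtered, log) : (DataFrame, dict)
        ``log`` records the dropped variable and participant labels and
        an ``empty`` flag when nothing survives.
    """
    for name, thr in (("var_threshold", var_threshold),
                      ("sample_threshold", sample_threshold)):
        if not 0.0 < thr <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {thr}")
    var_missing = table.isna().mean(axis=0)
    dropped_vars = var_missing.index[var_missing > var_threshold].tolist()
    kept = table.drop(columns=dropped_vars)
    if kept.shape[1] == 0:
        return kept, {"dropped_variables": dropped_vars,
                      "dropped_participants": [], "empty": True}
    row_missing = kept.isna().mean(axis=1)
    dropped_rows = row_missing.index[row_missing > sample_threshold].tolist()
    kept = kept.drop(index=dropped_rows)
    log = {
        "dropped_variables": dropped_vars,
        "dropped_participants": dropped_rows,
        "empty": kept.shape[0] == 0,
    }
    return kept, log


def spearman_prune(
    matrix: pd.DataFrame, cutoff: float = 0.85
) -> tuple[list, list, list[dict]]:
    """Greedy pruning of highly rank-correlated variable pairs.

    Pairs with ``|Spearman rho| > cutoff`` (pairwise-complete
    observations) are processed in descending ``|rho|``; from each pair
    still fully present, the member with more missing values is dropped
    (tie: the lexicographically later name).  Constant variables have
    undefined rho for their pairs; these are treated as below the cutoff
    with a warning.

    Returns
    -------
    (kept, dropped, pair_log)
        ``pair_log`` has one entry per flagged pair with the decision.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 variables to prune")
    cols = list(matrix.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = matrix.corr(method="spearman", min_periods=2)
    constant = [c for c in cols if matrix[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(
            f"constant variables with undefined correlations: {constant}",
            stacklevel=2,
        )
    flagged = []
    for i, ci in enumerate(cols):
        for cj in cols[i + 1:]:
            r = rho.loc[ci, cj]
            if np.isfinite(r) and abs(r) > cutoff:
                flagged.append((abs(r), ci, cj))
    flagged.sort(key=lambda t: (-t[0], t[1], t[2]))
    missing_counts = matrix.isna().sum()
    dropped: list = []
    pair_log: list[dict] = []
    for absr, ci, cj in flagged:
        if ci in dropped or cj in dropped:
            pair_log.append({"pair": (ci, cj), "abs_rho": absr,
                             "dropped": None, "reason": "already resolved"})
            continue
        mi, mj = missing_counts[ci], missing_counts[cj]
        if mi > mj:
            victim = ci
        elif mj > mi:
            victim = cj
        else:
            victim = max(ci, cj)  # lexicographically later name
        dropped.append(victim)
        pair_log.append({"pair": (ci, cj), "abs_rho": absr, "dropped": victim,
                         "reason": "missing-count then lexicographic"})
    kept = [c for c in cols if c not in dropped]
    return kept, dropped, pair_log


def average_three_year_window(
    series: Mapping[int, float], sample_year: int
) -> tuple[float, str]:
    """Average exposure over the three calendar years preceding sampling.

    Uses ``sample_year - 1, -2, -3`` when all three are present;
    otherwise falls back to the three most recent available years
    strictly before ``sample_year``.  With only 1-2 preceding years the
    mean of what exists is returned and flagged; with none, NaN.

    Returns
    -------
    (value, flag) : (float, str)
        ``flag`` is ``"window"``, ``"fallback"``, ``"partial"`` or
        ``"missing"``.
    """
    if not series:
        return float("nan"), "missing"
    target = [sample_year - k for k in (1, 2, 3)]
    if all(y in series for y in target):
        return float(np.mean([series[y] for y in target])), "window"
    preceding = sorted((y for y in series if y < sample_year), reverse=True)
    if not preceding:
        return float("nan"), "missing"
    chosen = preceding[:3]
    value = float(np.mean([series[y] for y in chosen]))
    return value, ("fallback" if len(chosen) == 3 else "partial")


def regional_concentration(detection_rate: float, median_concentration: float) -> float:
    """Regional representative concentration C = D x M (ug/kg)."""
    if not 0.0 <= detection_rate <= 1.0:
        raise ValueError(f"detection rate must be in [0, 1], got {detection_rate}")
    if median_concentration < 0:
        raise ValueError("median concentration must be >= 0")
    return detection_rate * median_concentration


def individual_mycotoxin_exposure(
    concentration: float, profile: FoodFrequencyProfile
) -> float:
    """Estimated individual exposure E = C x sum_f F_f W_f (ug/day).

    ``concentration`` is the regional representative concentration for
    the participant's region; the profile supplies intake frequencies
    (times/day) and food-group weights.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    w = profile.weights
    return concentration * (
        profile.grains * w["grains"]
        + profile.dairy * w["dairy"]
        + profile.nuts * w["nuts"]
    )


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (haversine, mean Earth radius 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = math.radians(lat2 - lat1)
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def assign_city(
    lat: float,
    lon: float,
    centers: Mapping[str, tuple[float, float]],
    radius_km: float = 5.0,
) -> str | None:
    """Assign a participant to the nearest city center within ``radius_km``.

    Ties at identical distance are broken by lexicographic city id.
    Returns ``None`` when no center qualifies.
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude out of range: {lat}")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude out of range: {lon}")
    best: tuple[float, str] | None = None
    for city in sorted(centers):
        clat, clon = centers[city]
        d = haversine_km(lat, lon, clat, clon)
        if d <= radius_km and (best is None or d < best[0]):
            best = (d, city)
    return None if best is None else best[1]
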