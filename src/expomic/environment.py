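"""Standardization of unevenly sampled per-city environmental microbiomes.

Cities with more than 14 samples are eligible; collections larger than
the target size (median eligible city size, or a configured override)
are reduced by iterative random subsampling gated on a two-sample
Kolmogorov-Smirnov test of the per-sample alpha-diversity distribution
(subset vs. full city, accept at p > 0.05).  Also provides per-sample
alpha diversity and obligate/facultative pathogen load sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import indices

__all__ = [
    "OBLIGATE_PATHOGENS",
    "FACULTATIVE_PATHOGENS",
    "CitySampleSet",
    "SubsampleError",
    "eligible_cities",
    "target_size",
    "subsample_city",
    "env_alpha_diversity",
    "pathogen_load",
]

#: Obligate pathogen species whose environmental abundances are summed.
OBLIGATE_PATHOGENS = (
    "Brucella ovis", "Brucella pinnipedialis", "Salmonella enterica",
    "Campylobacter jejuni", "Listeria monocytogenes", "Helicobacter pylori",
    "Neisseria gonorrhoeae", "Neisseria meningitidis",
    "Streptococcus pyogenes", "Haemophilus influenzae",
)

#: Facultative pathogen species whose environmental abundances are summed.
FACULTATIVE_PATHOGENS = (
    "Acinetobacter baumannii", "Klebsiella pneumoniae",
    "Pseudomonas aeruginosa", "Staphylococcus aureus",
    "Clostridium perfringens", "Enterococcus faecalis",
    "Enterococcus faecium", "Escherichia coli", "Mycobacterium avium",
    "Mycobacterium abscessus", "Streptococcus pneumoniae",
)


@dataclass
class CitySampleSet:
    """One city's sample x taxa abundance matrix."""

    city: str
    table: pd.DataFrame
    _alpha_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.table.shape[0] < 1:
            raise ValueError(f"city {self.city!r} has no samples")
        if (np.asarray(self.table) < 0).any():
            raise ValueError(f"city {self.city!r} has negative abundances")

    @property
    def n_samples(self) -> int:
        return self.table.shape[0]

    def alpha(self, metric: str = "fisher_alpha") -> np.ndarray:
        """Per-sample alpha diversity, cached per metric."""
        if metric not in self._alpha_cache:
            self._alpha_cache[metric] = _alpha_vector(self.table, metric)
        return self._alpha_cache[metric]


class SubsampleError(RuntimeError):
    """Raised when no subset passes the KS gate within max_iter draws.

    Carries the best (highest-p) subset seen in ``best_subset`` /
    ``best_p``.
    """

    def __init__(self, msg: str, best_subset: pd.DataFrame, best_p: float):
        super().__init__(msg)
        self.best_subset = best_subset
        self.best_p = best_p


_ALPHA_FUNCS: dict[str, Callable] = {
    "fisher_alpha": indices.fisher_alpha,
    "shannon": indices.shannon,
    "observed_features": indices.observed_features,
}


def _alpha_vector(table: pd.DataFrame, metric: str) -> np.ndarray:
    if metric not in _ALPHA_FUNCS:
        raise ValueError(
            f"unknown alpha metric {metric!r}; choose from {sorted(_ALPHA_FUNCS)}")
    func = _ALPHA_FUNCS[metric]
    return np.array([func(row) for row in np.asarray(table, dtype=float)])


def eligible_cities(
    sets: Sequence[CitySampleSet], min_n: int = 15
) -> list[CitySampleSet]:
    """Cities with strictly more than ``min_n - 1`` samples (default >14)."""
    return [s for s in sets if s.n_samples >= min_n]


def target_size(
    retained: Sequence[CitySampleSet], override: int | None = None
) -> int:
    """Standardization target: the median eligible-city sample count.

    An even number of cities uses the lower median so the target is an
    achievable city size.  ``override`` forces a fixed target (e.g. 55).
    """
    if override is not None:
        return int(override)
    if not retained:
        raise ValueError("no retained cities")
    sizes = sorted(s.n_samples for s in retained)
    return sizes[(len(sizes) - 1) // 2]


def subsample_city(
    cityset: CitySampleSet,
    target: int,
    alpha_metric: str = "fisher_alpha",
    p_threshold: float = 0.05,
    max_iter: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """KS-gated iterative random subsampling of one city to ``target``.

    Repeatedly draws a uniform random subset of ``target`` samples and
    accepts the first whose per-sample alpha-diversity distribution is
    not significantly different from the full city's (two-sample KS test,
    p > ``p_threshold``).  Cities at or below the target pass through.

    Returns
    -------
    (subset, iterations_used)

    Raises
    ------
    SubsampleError
        When ``max_iter`` draws are exhausted; the error carries the
        best (highest-p) subset seen.
    """
    n = cityset.n_samples
    if n <= target:
        return cityset.table, 0
    rng = np.random.default_rng(seed)
    full_alpha = cityset.alpha(alpha_metric)
    best_p, best_idx = -1.0, None
    for it in range(1, max_iter + 1):
        idx = rng.choice(n, size=target, replace=False)
        sub_alpha = full_alpha[idx]
        p = stats.ks_2samp(sub_alpha, full_alpha, method="asymp").pvalue
        if p > p_threshold:
            return cityset.table.iloc[np.sort(idx)], it
        if p > best_p:
            best_p, best_idx = p, idx
    raise SubsampleError(
        f"no subset of city {cityset.city!r} passed the KS gate in "
        f"{max_iter} iterations (best p={best_p:.4g})",
        cityset.table.iloc[np.sort(best_idx)], best_p,
    )


def env_alpha_diversity(cityset: CitySampleSet) -> pd.DataFrame:
    """Per-sample Fisher's alpha, Shannon entropy (bits) and observed
    features for one city's environmental matrix."""
    return pd.DataFrame(
        {
            "fisher_alpha": cityset.alpha("fisher_alpha"),
            "shannon": cityset.alpha("shannon"),
            "observed_features": cityset.alpha("observed_features"),
        },
        index=cityset.table.index,
    )


def pathogen_load(
    sample: pd.Series,
    which: Literal["obligate", "facultative"],
    obligate: Sequence[str] = OBLIGATE_PATHOGENS,
    facultative: Sequence[str] = FACULTATIVE_PATHOGENS,
) -> float:
    """Summed abundance of listed pathogen species in one sample.

    Species absent from the table contribute zero.
    """
    if which == "obligate":
        members = obligate
    elif which == "facultative":
        members = facultative
    else:
        raise ValueError("which must be 'obligate' or 'facultative'")
    return float(sample.reindex(members).fillna(0.0).sum())
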