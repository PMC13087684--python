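"""Gut-microbiome mediator indices from a genus-level count table.

Ten per-sample indices: Shannon entropy (bits), observed features,
Fisher's alpha, the first two principal coordinates of a Bray-Curtis
ordination, the Firmicutes/Bacteroidetes and Gram-positive/Gram-negative
ratios, and the summed relative abundances of three functional guilds
(risk-associated, butyrate-producing, lactate-producing taxa).

Indices are computed on raw counts (no rarefaction); guild membership
and phylum/Gram lookups ship as defaults and are overridable via config.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "GUILD_DEFINITIONS",
    "PHYLUM_LOOKUP",
    "GRAM_LOOKUP",
    "TaxonGroupDefinition",
    "shannon",
    "observed_features",
    "fisher_alpha",
    "bray_curtis",
    "pcoa",
    "group_ratio",
    "guild_abundance",
    "compute_index_set",
    "INDEX_COLUMNS",
]

# ---------------------------------------------------------------------------
# default taxon-group definitions

RISK_TAXA = ["Eggerthella", "Anaerotruncus", "Klebsiella"]

BUTYRATE_TAXA = [
    "Butyricimonas", "Odoribacter", "Anaerostipes", "Anaerobutyricum",
    "Agathobacter", "Butyrivibrio", "Coprococcus", "Roseburia",
    "Shuttleworthia", "Butyricicoccus", "Oscillibacter", "Faecalibacterium",
    "Flavonifractor", "Pseudoflavonifractor", "Subdoligranulum",
    "Subdoligranulum variabile", "Eubacterium ventriosum",
]

LACTATE_TAXA = [
    "Bifidobacterium", "Lactobacillus", "Streptococcus", "Enterococcus",
    "Leuconostoc", "Lactococcus", "Pediococcus",
]

#: genus -> phylum, covering the genera the synthetic generator emits plus
#: common gut genera; extend via config for real tables.
PHYLUM_LOOKUP: dict[str, str] = {
    # Firmicutes
    "Anaerostipes": "Firmicutes", "Anaerobutyricum": "Firmicutes",
    "Agathobacter": "Firmicutes", "Butyrivibrio": "Firmicutes",
    "Coprococcus": "Firmicutes", "Roseburia": "Firmicutes",
    "Shuttleworthia": "Firmicutes", "Butyricicoccus": "Firmicutes",
    "Oscillibacter": "Firmicutes", "Faecalibacterium": "Firmicutes",
    "Flavonifractor": "Firmicutes", "Pseudoflavonifractor": "Firmicutes",
    "Subdoligranulum": "Firmicutes", "Subdoligranulum variabile": "Firmicutes",
    "Eubacterium ventriosum": "Firmicutes", "Lactobacillus": "Firmicutes",
    "Streptococcus": "Firmicutes", "Enterococcus": "Firmicutes",
    "Leuconostoc": "Firmicutes", "Lactococcus": "Firmicutes",
    "Pediococcus": "Firmicutes", "Anaerotruncus": "Firmicutes",
    "Blautia": "Firmicutes", "Ruminococcus": "Firmicutes",
    "Dialister": "Firmicutes", "Veillonella": "Firmicutes",
    "Clostridium": "Firmicutes", "Dorea": "Firmicutes",
    # Bacteroidetes
    "Bacteroides": "Bacteroidetes", "Prevotella": "Bacteroidetes",
    "Parabacteroides": "Bacteroidetes", "Alistipes": "Bacteroidetes",
    "Butyricimonas": "Bacteroidetes", "Odoribacter": "Bacteroidetes",
    # Actinobacteria
    "Bifidobacterium": "Actinobacteria", "Eggerthella": "Actinobacteria",
    "Collinsella": "Actinobacteria",
    # Proteobacteria
    "Klebsiella": "Proteobacteria", "Escherichia": "Proteobacteria",
    "Sutterella": "Proteobacteria", "Bilophila": "Proteobacteria",
    "Campylobacter": "Proteobacteria",
    # Verrucomicrobia
    "Akkermansia": "Verrucomicrobia",
    # Fusobacteria
    "Fusobacterium": "Fusobacteria",
}

#: Gram stain by phylum; genera are resolved through PHYLUM_LOOKUP.
_GRAM_BY_PHYLUM = {
    "Firmicutes": "positive",
    "Actinobacteria": "positive",
    "Bacteroidetes": "negative",
    "Proteobacteria": "negative",
    "Verrucomicrobia": "negative",
    "Fusobacteria": "negative",
}

GRAM_LOOKUP: dict[str, str] = {
    taxon: _GRAM_BY_PHYLUM[phylum] for taxon, phylum in PHYLUM_LOOKUP.items()
}


@dataclass(frozen=True)
class TaxonGroupDefinition:
    """A named group of taxa (guild or phylum/Gram class) and its members."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")


def _lookup_group(lookup: Mapping[str, str], value: str) -> tuple[str, ...]:
    return tuple(t for t, v in lookup.items() if v == value)


GUILD_DEFINITIONS: dict[str, TaxonGroupDefinition] = {
    "risk": TaxonGroupDefinition("risk", tuple(RISK_TAXA)),
    "butyrate": TaxonGroupDefinition("butyrate", tuple(BUTYRATE_TAXA)),
    "lactate": TaxonGroupDefinition("lactate", tuple(LACTATE_TAXA)),
    "firmicutes": TaxonGroupDefinition(
        "firmicutes", _lookup_group(PHYLUM_LOOKUP, "Firmicutes")),
    "bacteroidetes": TaxonGroupDefinition(
        "bacteroidetes", _lookup_group(PHYLUM_LOOKUP, "Bacteroidetes")),
    "gram_positive": TaxonGroupDefinition(
        "gram_positive", _lookup_group(GRAM_LOOKUP, "positive")),
    "gram_negative": TaxonGroupDefinition(
        "gram_negative", _lookup_group(GRAM_LOOKUP, "negative")),
}

INDEX_COLUMNS = [
    "shannon", "observed_features", "fisher_alpha", "pcoa1", "pcoa2",
    "fb_ratio", "gp_gn_ratio", "risk_abund", "butyrate_abund", "lactate_abund",
]


# ---------------------------------------------------------------------------
# alpha diversity

def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy of one sample, -sum p_i log_base p_i (default bits)."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count row")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def observed_features(counts) -> int:
    """Number of taxa present (count > 0) in one sample."""
    c = np.asarray(counts, dtype=float)
    return int((c > 0).sum())


def fisher_alpha(counts, tol: float = 1e-9) -> float:
    """Fisher's log-series alpha for one sample.

    Solves ``S = alpha * ln(1 + N/alpha)`` for the unique positive root,
    with S the number of observed taxa and N the total count.  When every
    individual is a distinct taxon (S == N) no finite root exists and NaN
    is returned.
    """
    c = np.asarray(counts, dtype=float)
    S = float((c > 0).sum())
    N = float(c.sum())
    if S < 1 or N < S:
        raise ValueError(f"need S >= 1 and N >= S (got S={S}, N={N})")
    if S == N:
        return float("nan")

    def f(alpha: float) -> float:
        return alpha * np.log1p(N / alpha) - S

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - S==N already excluded
            return float("nan")
    root = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    assert abs(f(root)) < tol
    return float(root)


# ---------------------------------------------------------------------------
# beta diversity

def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix for a samples x taxa count table.

    ``D(u, v) = 1 - 2 sum_i min(u_i, v_i) / (sum u + sum v)``.
    """
    X = np.asarray(table, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.any(X < 0):
        raise ValueError("negative abundances")
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("zero-sum sample(s) present")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(X[i], X[i + 1:]).sum(axis=1)
        d = 1.0 - 2.0 * shared / (totals[i] + totals[i + 1:])
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    index = table.index if isinstance(table, pd.DataFrame) else None
    return pd.DataFrame(D, index=index, columns=index)


def pcoa(distance: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates of a distance matrix (Gower double-centering).

    Eigendecomposes ``-0.5 J D^2 J`` (J the centering matrix) and returns
    coordinates ``eigvec * sqrt(eigval)`` on the ``k`` largest positive
    axes.  Negative eigenvalues are dropped with a warning; each axis is
    sign-fixed so the lexicographically first sample has a coordinate
    >= 0.

    Returns
    -------
    (coordinates, eigenvalues)
        ``coordinates`` is samples x min(k, #positive axes);
        ``eigenvalues`` are all positive eigenvalues, descending.
    """
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix diagonal must be zero")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-10, 1e-12 * abs(eigval[0]) if eigval[0] > 0 else 1e-10)
    n_pos = int(pos.sum())
    if n_pos < (eigval > -np.inf).sum() and np.any(eigval < -1e-8):
        logger.warning("dropping %d negative PCoA eigenvalues",
                       int((eigval < -1e-8).sum()))
    n_axes = min(k, n_pos)
    if n_axes < k:
        logger.warning("only %d positive axes available (requested %d)",
                       n_pos, k)
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    if isinstance(distance, pd.DataFrame):
        labels = list(distance.index)
    else:
        labels = list(range(n))
    # sign convention: coordinate of the lexicographically first sample >= 0
    first = sorted(range(n), key=lambda i: str(labels[i]))[0]
    for j in range(n_axes):
        if coords[first, j] < 0:
            coords[:, j] = -coords[:, j]
    cols = [f"pcoa{j + 1}" for j in range(n_axes)]
    return pd.DataFrame(coords, index=labels, columns=cols), eigval[:n_pos]


# ---------------------------------------------------------------------------
# composition ratios and guilds

def group_ratio(
    counts: pd.Series,
    numerator: TaxonGroupDefinition,
    denominator: TaxonGroupDefinition,
) -> float:
    """Ratio of summed counts of two taxon groups; NaN when the denominator
    (or both groups) sums to zero."""
    num = counts.reindex(numerator.members).fillna(0.0).sum()
    den = counts.reindex(denominator.members).fillna(0.0).sum()
    if den == 0:
        return float("nan")
    return float(num / den)


def guild_abundance(counts: pd.Series, group: TaxonGroupDefinition) -> float:
    """Summed relative abundance of a guild's member taxa in one sample."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero count row")
    present = counts.reindex(group.members).fillna(0.0).sum()
    return float(present / total)


def compute_index_set(
    table: pd.DataFrame,
    guilds: Mapping[str, TaxonGroupDefinition] | None = None,
    shannon_base: float = 2.0,
) -> pd.DataFrame:
    """Compute all ten mediator indices for a samples x taxa count table.

    Returns a per-sample DataFrame with columns ``INDEX_COLUMNS``.
    Unmatched guild members contribute zero (logged once).
    """
    if guilds is None:
        guilds = GUILD_DEFINITIONS
    missing = {
        name: sorted(set(g.members) - set(table.columns))
        for name, g in guilds.items()
    }
    for name, absent in missing.items():
        if absent:
            logger.info("guild %s: %d member(s) absent from table",
                        name, len(absent))
    out = pd.DataFrame(index=table.index, columns=INDEX_COLUMNS, dtype=float)
    for sid, row in table.iterrows():
        out.loc[sid, "shannon"] = shannon(row.values, base=shannon_base)
        out.loc[sid, "observed_features"] = observed_features(row.values)
        out.loc[sid, "fisher_alpha"] = fisher_alpha(row.values)
        out.loc[sid, "fb_ratio"] = group_ratio(
            row, guilds["firmicutes"], guilds["bacteroidetes"])
        out.loc[sid, "gp_gn_ratio"] = group_ratio(
            row, guilds["gram_positive"], guilds["gram_negative"])
        out.loc[sid, "risk_abund"] = guild_abundance(row, guilds["risk"])
        out.loc[sid, "butyrate_abund"] = guild_abundance(row, guilds["butyrate"])
        out.loc[sid, "lactate_abund"] = guild_abundance(row, guilds["lactate"])
    coords, _ = pcoa(bray_curtis(table), k=2)
    out["pcoa1"] = coords.get("pcoa1", pd.Series(np.nan, index=table.index))
    if "pcoa2" in coords:
        out["pcoa2"] = coords["pcoa2"]
    return out
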