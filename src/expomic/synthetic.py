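"""Synthetic cohorts with planted mediation effects.

Generates self-contained inputs with the statistical structure the
analysis pipeline assumes:

* abstract (X, M, Y) mediation triplets with planted path coefficients
  a, b, c' for parameter-recovery testing;
* full cohorts: continuous/binary exposures, Dirichlet-multinomial
  genus count tables whose taxa respond to a planted exposure effect,
  age/sex covariates, health outcomes wired to a mediator index, and
  missing-completely-at-random missingness;
* per-city environmental sample sets for the subsampling standardizer.

All generators are deterministic for a fixed seed.  Ground truth is
returned alongside the data (and written as a JSON sidecar by
:func:`write_cohort`) so downstream estimates can be checked against the
planted values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import indices
from .environment import CitySampleSet

__all__ = [
    "SyntheticTruth",
    "CommunityConfig",
    "OutcomeSpec",
    "CohortConfig",
    "generate_mediation_triplet",
    "generate_cohort",
    "generate_city_samples",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one mediation triplet.

    ``a`` is the X -> M coefficient (per SD of X), ``b`` the M -> Y
    coefficient (linear units for continuous Y, log-odds per mediator
    unit for binary Y) and ``c_prime`` the direct X -> Y coefficient on
    the same scale as ``b``.
    """

    triplet_id: str
    a: float
    b: float
    c_prime: float
    noise_sd_m: float = 1.0
    noise_sd_y: float = 1.0
    outcome_type: Literal["continuous", "binary"] = "continuous"
    baseline: float = 0.0
    n: int = 1000
    seed: int = 0
    age_coef: float = 0.0
    sex_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError(f"n must be >= 10, got {self.n}")
        if self.noise_sd_m <= 0:
            raise ValueError(f"noise_sd_m must be > 0, got {self.noise_sd_m}")
        if self.noise_sd_y <= 0:
            raise ValueError(f"noise_sd_y must be > 0, got {self.noise_sd_y}")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(
                f"outcome_type must be 'continuous' or 'binary', "
                f"got {self.outcome_type!r}")


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Age ~ Normal(45, 15) truncated to [18, 90]; sex ~ Bernoulli(0.5)."""
    age = rng.normal(45.0, 15.0, size=n)
    out_of_range = (age < 18) | (age > 90)
    while out_of_range.any():
        age[out_of_range] = rng.normal(45.0, 15.0, size=int(out_of_range.sum()))
        out_of_range = (age < 18) | (age > 90)
    sex = rng.integers(0, 2, size=n).astype(float)
    return pd.DataFrame({"age": age, "sex": sex})


def generate_mediation_triplet(
    truth: SyntheticTruth,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Draw one (X, M, Y, covariates) dataset from planted truth.

    X is standard normal; M = a X + N(0, noise_sd_m);
    continuous Y = baseline + c' X + b M (+ covariate terms) + noise;
    binary Y ~ Bernoulli(logistic(baseline + c' X + b M + covariates)).
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n
    x = rng.standard_normal(n)
    m = truth.a * x + rng.normal(0.0, truth.noise_sd_m, size=n)
    cov = _draw_covariates(rng, n)
    lin = (truth.baseline + truth.c_prime * x + truth.b * m
           + truth.age_coef * (cov["age"].to_numpy() - 45.0)
           + truth.sex_coef * cov["sex"].to_numpy())
    if truth.outcome_type == "continuous":
        y = lin + rng.normal(0.0, truth.noise_sd_y, size=n)
    else:
        p = 1.0 / (1.0 + np.exp(-lin))
        y = rng.binomial(1, p).astype(float)
    return x, m, y, cov


@dataclass(frozen=True)
class CommunityConfig:
    """Dirichlet-multinomial community model for the gut count table.

    ``effect_taxa`` maps taxon name -> per-unit-X shift of that taxon's
    log concentration (a compositional response to the exposure).
    """

    taxa: tuple[str, ...]
    concentration: tuple[float, ...]
    depth: int = 10000
    effect_taxa: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.concentration) != len(self.taxa):
            raise ValueError("concentration length must match taxa")
        if any(c <= 0 for c in self.concentration):
            raise ValueError("all concentrations must be > 0")
        if self.depth < 100:
            raise ValueError(f"depth must be >= 100, got {self.depth}")
        unknown = set(self.effect_taxa) - set(self.taxa)
        if unknown:
            raise ValueError(f"effect_taxa not in taxon set: {sorted(unknown)}")


#: default community: guild members from the index definitions plus common
#: gut genera, so every index code path is exercised.
def default_community(depth: int = 10000,
                      effect_taxa: Mapping[str, float] | None = None
                      ) -> CommunityConfig:
    taxa = list(dict.fromkeys(
        indices.RISK_TAXA + indices.BUTYRATE_TAXA + indices.LACTATE_TAXA
        + ["Bacteroides", "Prevotella", "Parabacteroides", "Alistipes",
           "Blautia", "Ruminococcus", "Akkermansia", "Escherichia",
           "Bilophila", "Campylobacter", "Dorea", "Collinsella"]))
    rng = np.random.default_rng(12345)  # fixed base community profile
    conc = np.exp(rng.normal(0.0, 1.0, size=len(taxa)))
    conc = conc / conc.sum() * 50.0  # moderate overdispersion
    # dominant commensals get higher base concentration
    for big in ("Bacteroides", "Faecalibacterium", "Prevotella", "Blautia"):
        conc[taxa.index(big)] += 5.0
    return CommunityConfig(
        taxa=tuple(taxa), concentration=tuple(conc), depth=depth,
        effect_taxa=dict(effect_taxa or {}))


@dataclass(frozen=True)
class OutcomeSpec:
    """How one synthetic health outcome is wired to exposure and mediator."""

    name: str
    exposure: str
    mediator_index: str = "shannon"
    b: float = 0.0
    c_prime: float = 0.0
    outcome_type: Literal["continuous", "binary"] = "binary"
    baseline: float = 0.0
    noise_sd: float = 1.0


@dataclass(frozen=True)
class CohortConfig:
    """Specification of a full synthetic cohort."""

    n: int = 500
    exposures: tuple[str, ...] = ("exposure_1", "exposure_2")
    binary_exposures: tuple[str, ...] = ()
    community: CommunityConfig | None = None
    community_exposure: str = "exposure_1"
    outcomes: tuple[OutcomeSpec, ...] = ()
    missingness: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        for var, rate in self.missingness.items():
            if not 0.0 <= rate < 1.0:
                raise ValueError(
                    f"missingness rate for {var!r} must be in [0, 1), "
                    f"got {rate}")


def generate_cohort(
    config: CohortConfig, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Generate (cohort table, genus count table, truth records).

    Exposures are standard normal (or Bernoulli(0.5) for binary ones);
    counts are Dirichlet-multinomial with per-taxon log-concentration
    shifts ``effect_taxa * X`` driven by ``community_exposure``;
    outcomes follow their :class:`OutcomeSpec` using the realized
    mediator index computed from the generated counts (standardized);
    missingness is injected MCAR at the configured per-variable rates.
    """
    rng = np.random.default_rng(seed)
    n = config.n
    community = config.community or default_community()
    ids = [f"P{i:05d}" for i in range(n)]

    cohort = _draw_covariates(rng, n)
    cohort.index = pd.Index(ids, name="participant")
    for name in config.exposures:
        cohort[name] = rng.standard_normal(n)
    for name in config.binary_exposures:
        cohort[name] = rng.integers(0, 2, size=n).astype(float)

    # Dirichlet-multinomial counts with planted exposure response
    x_drive = cohort[config.community_exposure].to_numpy() \
        if config.community_exposure in cohort else np.zeros(n)
    base = np.log(np.asarray(community.concentration))
    shift = np.zeros((n, len(community.taxa)))
    for taxon, coef in community.effect_taxa.items():
        shift[:, community.taxa.index(taxon)] = coef * x_drive
    conc = np.exp(base[None, :] + shift)
    counts = np.empty((n, len(community.taxa)), dtype=int)
    for i in range(n):
        p = rng.dirichlet(conc[i])
        counts[i] = rng.multinomial(community.depth, p)
    table = pd.DataFrame(counts, index=cohort.index,
                         columns=list(community.taxa))

    # outcomes wired to realized mediator indices
    truths: list[dict] = []
    if config.outcomes:
        idx_set = indices.compute_index_set(table)
        for spec in config.outcomes:
            x = cohort[spec.exposure].to_numpy(dtype=float)
            m_raw = idx_set[spec.mediator_index].to_numpy(dtype=float)
            m = (m_raw - np.nanmean(m_raw)) / np.nanstd(m_raw)
            lin = spec.baseline + spec.c_prime * x + spec.b * m
            if spec.outcome_type == "continuous":
                y = lin + rng.normal(0.0, spec.noise_sd, size=n)
            else:
                y = rng.binomial(1, 1.0 / (1.0 + np.exp(-lin))).astype(float)
            cohort[spec.name] = y
            truths.append({"triplet_id": f"{spec.exposure}->"
                                         f"{spec.mediator_index}->{spec.name}",
                           **asdict(spec)})

    # MCAR missingness
    for var, rate in config.missingness.items():
        if var in cohort:
            mask = rng.random(n) < rate
            cohort.loc[mask, var] = np.nan
    return cohort, table, truths


def generate_city_samples(
    n_cities: int,
    sizes: Sequence[int],
    seed: int = 0,
    n_taxa: int = 40,
    depth: int = 5000,
    city_shift_sd: float = 0.0,
    include_pathogens: bool = True,
) -> list[CitySampleSet]:
    """Per-city environmental sample sets for the standardizer.

    Each city's samples are Dirichlet-multinomial draws from a shared
    base community; ``city_shift_sd > 0`` adds a city-specific
    log-concentration shift so cities become distinguishable.
    ``include_pathogens`` names part of the taxa after the obligate and
    facultative pathogen species so load sums have targets to hit.
    """
    if len(sizes) != n_cities:
        raise ValueError("sizes must have one entry per city")
    if any(s <= 0 for s in sizes):
        raise ValueError("sizes must be positive integers")
    rng = np.random.default_rng(seed)
    from .environment import OBLIGATE_PATHOGENS, FACULTATIVE_PATHOGENS
    taxa: list[str] = []
    if include_pathogens:
        taxa += list(OBLIGATE_PATHOGENS[:5]) + list(FACULTATIVE_PATHOGENS[:5])
    taxa += [f"env_taxon_{i}" for i in range(n_taxa - len(taxa))]
    base = np.exp(rng.normal(0.0, 1.0, size=len(taxa)))
    base = base / base.sum() * 30.0
    sets = []
    for c in range(n_cities):
        conc = base * np.exp(rng.normal(0.0, city_shift_sd, size=len(taxa))) \
            if city_shift_sd > 0 else base
        m = sizes[c]
        counts = np.empty((m, len(taxa)), dtype=int)
        for i in range(m):
            counts[i] = rng.multinomial(depth, rng.dirichlet(conc))
        frame = pd.DataFrame(
            counts, columns=taxa,
            index=[f"city{c:02d}_s{i:03d}" for i in range(m)])
        sets.append(CitySampleSet(city=f"city{c:02d}", table=frame))
    return sets


def write_cohort(
    outdir: str | Path,
    cohort: pd.DataFrame,
    table: pd.DataFrame,
    truths: list[dict],
) -> dict[str, Path]:
    """Write cohort and feature tables as TSV plus a truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.tsv",
        "features": outdir / "features.tsv",
        "truth": outdir / "truth.json",
    }
    cohort.to_csv(paths["cohort"], sep="\t")
    table.to_csv(paths["features"], sep="\t")
    paths["truth"].write_text(json.dumps(truths, indent=2))
    return paths
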