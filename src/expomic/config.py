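"""YAML-backed configuration for lookups and thresholds.

Ships the package defaults (guild memberships, genus->phylum and Gram
lookups, pathogen lists, food-group weights) and lets users override
any subset from a YAML file, e.g.::

    guilds:
      risk: [Eggerthella, Anaerotruncus, Klebsiella, Bilophila]
    food_weights: {grains: 0.6, dairy: 0.25, nuts: 0.15}
    phylum:
      Treponema: Spirochaetes
"""

from __future__ import annotations

from pathlib import Path

import yaml

from . import environment, indices
from .exposures import DEFAULT_FOOD_WEIGHTS
from .indices import TaxonGroupDefinition

__all__ = ["default_config", "load_config"]


def default_config() -> dict:
    """The shipped defaults as a plain dict (YAML-serializable)."""
    return {
        "guilds": {name: list(g.members)
                   for name, g in indices.GUILD_DEFINITIONS.items()},
        "phylum": dict(indices.PHYLUM_LOOKUP),
        "gram": dict(indices.GRAM_LOOKUP),
        "pathogens": {
            "obligate": list(environment.OBLIGATE_PATHOGENS),
            "facultative": list(environment.FACULTATIVE_PATHOGENS),
        },
        "food_weights": dict(DEFAULT_FOOD_WEIGHTS),
    }


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with overrides from a YAML file (if given).

    Top-level sections merge key-wise; guild lists are converted to
    :class:`~expomic.indices.TaxonGroupDefinition` under
    ``guild_definitions``.
    """
    cfg = default_config()
    if path is not None:
        overrides = yaml.safe_load(Path(path).read_text()) or {}
        for section, value in overrides.items():
            if section not in cfg:
                raise ValueError(
                    f"unknown config section {section!r}; "
                    f"expected one of {sorted(cfg)}")
            if isinstance(cfg[section], dict) and isinstance(value, dict):
                cfg[section].update(value)
            else:
                cfg[section] = value
    cfg["guild_definitions"] = {
        name: TaxonGroupDefinition(name, tuple(members))
        for name, members in cfg["guilds"].items()}
    weights = cfg["food_weights"]
    if set(weights) != {"grains", "dairy", "nuts"}:
        raise ValueError("food_weights must define grains, dairy and nuts")
    return cfg
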