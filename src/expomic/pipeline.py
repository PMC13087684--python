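"""End-to-end pipeline orchestration with a reproducibility manifest.

Stages: synthesize (or ingest) -> missingness filter -> mediator indices
-> association screens (exposure -> index, exposure -> outcome) ->
triplet selection -> mediation -> report.  Every run writes plain-text
TSV outputs plus a JSON manifest carrying the config hash, seeds and
per-stage bookkeeping counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import indices, synthetic
from .exposures import filter_missing, spearman_prune
from .mediation import MediationModel, select_triplets
from .screen import AssociationScreen

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``cohort_path``/``features_path`` point at tab-delimited
    inputs, or ``synthetic`` supplies a :class:`~expomic.synthetic.CohortConfig`
    to generate them.
    """

    outdir: str = "expomic_run"
    seed: int = 0
    cohort_path: str | None = None
    features_path: str | None = None
    synthetic: synthetic.CohortConfig | None = None
    exposure_columns: Sequence[str] = ()
    outcome_columns: Sequence[str] = ()
    outcome_types: Mapping[str, str] = field(default_factory=dict)
    covariates: Sequence[str] = ("age", "sex")
    missing_var_threshold: float = 0.5
    missing_sample_threshold: float = 0.5
    spearman_cutoff: float = 0.85
    fdr_cut: float = 0.05
    r2_cut: float = 0.005
    fdr_family: str = "per-dv"
    n_boot: int = 1000

    def validate(self) -> None:
        for name in ("missing_var_threshold", "missing_sample_threshold",
                     "fdr_cut"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 < self.spearman_cutoff <= 1.0:
            raise ValueError("spearman_cutoff must be in (0, 1]")
        if self.synthetic is None and (
                self.cohort_path is None or self.features_path is None):
            raise ValueError(
                "either synthetic config or cohort/features paths required")

    def hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }

    # stage: inputs
    if config.synthetic is not None:
        cohort, table, truths = synthetic.generate_cohort(
            config.synthetic, seed=config.seed)
        synthetic.write_cohort(outdir / "inputs", cohort, table, truths)
        exposures = list(config.exposure_columns) or \
            list(config.synthetic.exposures) + \
            list(config.synthetic.binary_exposures)
        outcomes = list(config.outcome_columns) or \
            [o.name for o in config.synthetic.outcomes]
        outcome_types = dict(config.outcome_types) or {
            o.name: o.outcome_type for o in config.synthetic.outcomes}
    else:
        cohort = pd.read_csv(config.cohort_path, sep="\t", index_col=0)
        table = pd.read_csv(config.features_path, sep="\t", index_col=0)
        exposures = list(config.exposure_columns)
        outcomes = list(config.outcome_columns)
        outcome_types = dict(config.outcome_types)
    manifest["stages"]["inputs"] = {
        "n_participants": int(cohort.shape[0]),
        "n_variables": int(cohort.shape[1]),
        "n_taxa": int(table.shape[1]),
    }

    # stage: missingness filter (two-step: variables, then participants)
    filtered, flog = filter_missing(
        cohort, config.missing_var_threshold, config.missing_sample_threshold)
    exposures = [x for x in exposures if x in filtered.columns]
    outcomes = [y for y in outcomes if y in filtered.columns]
    table = table.loc[table.index.intersection(filtered.index)]
    manifest["stages"]["filter"] = {
        "dropped_variables": flog["dropped_variables"],
        "dropped_participants": len(flog["dropped_participants"]),
        "kept_participants": int(filtered.shape[0]),
    }
    if flog["empty"]:
        manifest["status"] = "empty-after-filter"
        _write_manifest(outdir, manifest)
        return manifest

    # stage: collinearity pruning among exposures
    if len(exposures) >= 2:
        kept, dropped, _ = spearman_prune(
            filtered[exposures], cutoff=config.spearman_cutoff)
        exposures = kept
        manifest["stages"]["prune"] = {"dropped": dropped}

    # stage: mediator indices
    idx = indices.compute_index_set(table)
    idx.to_csv(outdir / "indices.tsv", sep="\t")
    manifest["stages"]["indices"] = {"n_samples": int(idx.shape[0])}

    # stage: association screens
    X = filtered.loc[idx.index, exposures]
    m_screen = AssociationScreen(X, idx, fdr_family=config.fdr_family).fit(
        fdr_cut=config.fdr_cut, r2_cut=config.r2_cut)
    m_screen.table.to_csv(outdir / "screen_mediators.tsv", sep="\t", index=False)
    m_screen.signed_r2.to_csv(outdir / "signed_r2_mediators.tsv", sep="\t")
    y_screen = None
    if outcomes:
        Y = filtered.loc[idx.index, outcomes]
        y_screen = AssociationScreen(X, Y, fdr_family=config.fdr_family).fit(
            fdr_cut=config.fdr_cut, r2_cut=config.r2_cut)
        y_screen.table.to_csv(outdir / "screen_outcomes.tsv", sep="\t",
                              index=False)
    manifest["stages"]["screen"] = {
        "mediator_pairs_tested": int(len(m_screen.table)),
        "mediator_significant": m_screen.n_significant,
        "outcome_pairs_tested": int(len(y_screen.table)) if y_screen else 0,
        "outcome_significant": y_screen.n_significant if y_screen else 0,
    }

    # stage: mediation
    med_rows = []
    class_counts = {"full": 0, "partial": 0, "inconsistent": 0, "none": 0}
    if y_screen is not None:
        triplets = select_triplets(
            m_screen, y_screen, y_types=outcome_types,
            covariates=tuple(config.covariates))
        frame = filtered.loc[idx.index].join(idx)
        for t in triplets:
            try:
                model = MediationModel.from_dataframe(frame, t)
                res = model.fit(n_boot=config.n_boot, seed=config.seed)
            except ValueError as err:
                manifest["warnings"].append(
                    f"mediation {t.x}->{t.m}->{t.y}: {err}")
                continue
            med_rows.append(res.to_dict())
            class_counts[res.classification] += 1
        manifest["stages"]["mediation"] = {
            "triplets_tested": len(triplets),
            "triplets_fit": len(med_rows),
            "classes": class_counts,
        }
        if med_rows:
            pd.DataFrame(med_rows).to_csv(
                outdir / "mediation.tsv", sep="\t", index=False)

    manifest["status"] = "complete"
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
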