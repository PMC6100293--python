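"""Pipeline configuration and the end-to-end run.

``run_pipeline`` chains the full analysis: descending-activity train/test
split -> position-wise encoding -> autoscaling -> stepwise screening ->
VIF check -> model fitting (any of MLR/PLS/SVR/RF) -> metric table ->
residue contributions -> candidate design. Every artifact lands in a run
directory together with provenance metadata (config hash, seeds).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aaindex import filter_complete, parse_aaindex
from .contributions import rank_residues, residue_contributions, write_contributions_csv
from .design import enumerate_candidates, score_candidates
from .encoding import autoscale, encode_peptides, read_peptide_csv
from .models import fit_mlr, fit_pls, fit_rf, fit_svr, split_train_test, summarize
from .selection import check_selection, stepwise_select, vif
from .synthetic import default_properties, generate_peptide_dataset

VALID_METHODS = ("MLR", "PLS", "SVR", "RF")


class ConfigError(ValueError):
    """Configuration failed validation before any computation."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable to/from YAML.

    When ``peptide_csv`` is None the run uses the synthetic default
    dataset (seeded); when ``aaindex_path`` is None the bundled + seeded
    synthetic property panel is used.
    """

    output_dir: str = "pepqsar_run"
    peptide_csv: str | None = None
    aaindex_path: str | None = None
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    vif_limit: float = 5.0
    methods: list[str] = field(default_factory=lambda: list(VALID_METHODS))
    k_values: list[int] = field(default_factory=lambda: [4, 6, 10])
    seed: int = 0
    design_constraints: dict[int, list[str]] | None = None
    design_top: int = 20

    def validate(self) -> None:
        if self.alpha_enter > self.alpha_remove:
            raise ConfigError(
                f"significance-to-enter ({self.alpha_enter}) must not exceed "
                f"significance-to-remove ({self.alpha_remove})"
            )
        bad = [m for m in self.methods if m.upper() not in VALID_METHODS]
        if bad:
            raise ConfigError(f"unknown methods: {bad}")
        if not self.methods:
            raise ConfigError("no methods configured")
        if any(k < 2 for k in self.k_values):
            raise ConfigError("k-fold k values must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "design_constraints" in payload and payload["design_constraints"]:
            payload["design_constraints"] = {
                int(k): list(v) for k, v in payload["design_constraints"].items()
            }
        return cls(**payload)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.aaindex_path:
        with open(config.aaindex_path) as fh:
            properties = filter_complete(parse_aaindex(fh))
    else:
        properties = default_properties()
    if config.peptide_csv:
        peptides = read_peptide_csv(config.peptide_csv)
    else:
        peptides = generate_peptide_dataset(seed=config.seed, properties=properties).peptides
    return peptides, properties


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Any stage failure raises with the stage name prefixed; artifacts
    written before the failure are retained.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        peptides, properties = _load_inputs(config)

        stage = "split"
        train, test = split_train_test(peptides)

        stage = "encode"
        y_train = np.array([p.activity for p in train])
        y_test = np.array([p.activity for p in test])
        X_train = encode_peptides(train, properties)
        X_test = encode_peptides(test, properties) if test else None

        stage = "autoscale"
        Z_train, scaling = autoscale(X_train, activities=y_train, scale_response=True)
        Z_test = scaling.transform(X_test) if X_test is not None else None
        y_train_scaled = scaling.scale_y(y_train)

        stage = "select"
        result = stepwise_select(
            Z_train, y_train_scaled, config.alpha_enter, config.alpha_remove
        )
        if len(result.selected) >= 2:
            result.vifs = vif(Z_train[result.selected])
            report = check_selection(result, config.vif_limit)
        else:
            report = None
        with open(out / "selection.json", "w") as fh:
            json.dump(
                {
                    **result.to_dict(),
                    "vif_check": None
                    if report is None
                    else {"passed": report.passed, "offenders": report.offenders},
                },
                fh,
                indent=2,
                default=float,
            )
        if not result.selected:
            raise RuntimeError("no variables selected; nothing to model")

        stage = "fit"
        fitters = {
            "MLR": lambda: fit_mlr(Z_train[result.selected], y_train_scaled, scaling),
            "PLS": lambda: fit_pls(Z_train[result.selected], y_train_scaled, scaling),
            "SVR": lambda: fit_svr(
                Z_train[result.selected], y_train_scaled, scaling, seed=config.seed
            ),
            "RF": lambda: fit_rf(
                Z_train[result.selected], y_train_scaled, scaling, seed=config.seed
            ),
        }
        models = {}
        metric_rows = []
        for method in [m.upper() for m in config.methods]:
            model = fitters[method]()
            summarize(
                model,
                Z_train,
                y_train,
                Z_test,
                y_test if test else None,
                k_values=config.k_values,
                seed=config.seed,
            )
            models[method] = model
            with open(out / f"model_{method.lower()}.json", "w") as fh:
                json.dump(model.to_dict(), fh, indent=2, default=float)
            met = model.metrics
            row = {
                "method": method,
                "n": met.n_train,
                "m": met.n_variables,
                "r2_train": met.r2_train,
                "sd": met.sd,
                "f": met.f_stat,
                "q2_loo": met.q2_loo,
            }
            for k in config.k_values:
                row[f"q2_{k}fold"] = met.q2_kfold[k]
            row.update({"press": met.press, "n_test": len(test), "r2_test": met.r2_test})
            metric_rows.append(row)
        pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False, float_format="%.6f")

        stage = "contributions"
        linear = models.get("MLR") or models.get("PLS")
        if linear is not None:
            table = residue_contributions(linear, properties)
            write_contributions_csv(table, out / "contributions.csv")
            with open(out / "residue_ranks.json", "w") as fh:
                json.dump(rank_residues(table), fh, indent=2)

        stage = "design"
        scorer = models.get("MLR") or next(iter(models.values()))
        constraints = None
        if config.design_constraints:
            constraints = [
                config.design_constraints.get(j) for j in (1, 2, 3)
            ]
        candidates = enumerate_candidates(constraints)
        scored = score_candidates(candidates, scorer, properties)
        scored.head(config.design_top).to_csv(
            out / "candidates.csv", index=False, float_format="%.6f"
        )

        stage = "provenance"
        with open(out / "provenance.json", "w") as fh:
            json.dump(
                {
                    "pepqsar_version": __version__,
                    "config": asdict(config),
                    "config_digest": config.digest(),
                    "seed": config.seed,
                    "n_train": len(train),
                    "n_test": len(test),
                    "n_properties": len(properties),
                    "n_descriptors": X_train.shape[1],
                },
                fh,
                indent=2,
                default=str,
            )
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return out
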