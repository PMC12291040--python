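"""End-to-end screening workflow: build → split → explore → fit → validate → screen.

`run_pipeline` ties the library stages together with stable output
filenames and a content-hash manifest, so a rerun on identical inputs and
configuration reproduces identical artifacts.  The CLI in
:mod:`npscreen.cli` is a thin wrapper over this module; every result it
produces is reproducible by direct library calls.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .chemometrics import autoscale_fit, influence_table, kennard_stone_split, pca_fit
from .features import (
    FeatureMatrix,
    build_matrix,
    read_feature_table,
    write_feature_table,
)
from .simca import classify, coomans_table, fit_all_classes, save_models, validate
from .spectra import parse_spectra

__all__ = [
    "RunConfig",
    "run_pipeline",
    "reproduce_published_configuration",
    "PUBLISHED_PC_COUNTS",
]

log = logging.getLogger("npscreen")

#: Per-class component counts of the published screening configuration.
PUBLISHED_PC_COUNTS: dict[str, int] = {
    "benzodiazepines": 2,
    "cathinones": 4,
    "fentanyls": 4,
    "JWH": 3,
    "nitazenes": 2,
    "PINACA": 1,
    "tryptamines": 1,
    "arylcyclohexylamines": 1,
    "phenethylamines": 2,
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults follow the screening protocol: 10% relative-intensity
    threshold, 75/25 Kennard-Stone split, 95% confidence limits, modeling
    floor of four analytes per class.  The neutral-loss reference defaults
    to the precursor ion at the pipeline level so that all eight matrix
    variables are informative (with a base-peak reference the top fragment's
    loss is identically zero — a constant column that cannot be autoscaled);
    ``nl_reference: base_peak`` remains available.
    """

    # inputs (exactly one of spectra/feature_table)
    spectra: str | None = None
    spectra_format: str = "mgf"
    feature_table: str | None = None
    # extraction
    rel_intensity_threshold: float = 0.10
    nl_reference: str = "precursor"
    include_base_peak: bool = True
    # split
    train_fraction: float = 0.75
    train_size: int | None = None
    # modeling
    alpha: float = 0.05
    threshold_rule: str = "combined_chi2"
    classes_min: int = 4
    cv_scheme: str = "auto"
    missing_policy: str = "mean_impute"
    pc_counts: dict[str, int] | None = None
    explore_components: int = 3
    # screening / comparison
    screen: str | None = None
    screen_format: str = "mgf"
    coomans_pair: tuple[str, str] | None = None
    # bookkeeping
    out_dir: str = "npscreen_out"
    seed: int = 7

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if cfg.coomans_pair is not None:
            cfg.coomans_pair = tuple(cfg.coomans_pair)  # type: ignore[assignment]
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["coomans_pair"] is not None:
            d["coomans_pair"] = list(d["coomans_pair"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def _load_matrix(config: RunConfig) -> FeatureMatrix:
    if (config.spectra is None) == (config.feature_table is None):
        raise ValueError("exactly one of 'spectra' or 'feature_table' must be set")
    if config.feature_table is not None:
        return read_feature_table(config.feature_table)
    records = parse_spectra(config.spectra, config.spectra_format)
    if not records:
        raise ValueError(f"no spectra found in {config.spectra}")
    return build_matrix(
        records,
        rel_intensity_threshold=config.rel_intensity_threshold,
        nl_reference=config.nl_reference,  # type: ignore[arg-type]
        include_base_peak=config.include_base_peak,
    )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full workflow and return the artifact bundle.

    Writes (into ``config.out_dir``): ``matrix.csv``, ``train.csv``,
    ``test.csv``, ``split.json``, ``pca_scores.csv``, ``pca_loadings.csv``,
    ``influence.csv``, ``models.json``, ``report.csv``, optionally
    ``predictions.csv`` and ``coomans.csv``, plus ``manifest.json`` listing
    every output with its SHA-256 content hash and the resolved config.
    Returns the in-memory objects alongside the paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("resolved config: %s", json.dumps(config.to_dict(), sort_keys=True))

    matrix = _load_matrix(config)
    write_feature_table(matrix, out / "matrix.csv")

    scaling, scaled = autoscale_fit(matrix, missing_policy=config.missing_policy)
    split = kennard_stone_split(
        scaled, train_fraction=config.train_fraction, train_size=config.train_size
    )
    train = matrix.subset(split.train_indices)
    test = matrix.subset(split.test_indices)
    write_feature_table(train, out / "train.csv")
    write_feature_table(test, out / "test.csv")
    (out / "split.json").write_text(
        json.dumps(
            {
                "train_indices": split.train_indices,
                "test_indices": split.test_indices,
                "selection_order": split.selection_order,
            }
        )
    )

    # exploratory PCA on the training set (global autoscaling)
    tr_scaling, tr_scaled = autoscale_fit(train, missing_policy=config.missing_policy)
    A_explore = min(config.explore_components, tr_scaled.shape[0] - 1, 8)
    explore = pca_fit(tr_scaled, A_explore, tr_scaling)
    scores = tr_scaled @ explore.loadings
    score_frame = pd.DataFrame(
        scores, columns=[f"PC{a + 1}" for a in range(A_explore)]
    )
    score_frame.insert(0, "class", train.class_labels)
    score_frame.insert(0, "analyte_id", train.analyte_ids)
    _write_csv(score_frame, out / "pca_scores.csv")
    loading_frame = pd.DataFrame(
        explore.loadings,
        columns=[f"PC{a + 1}" for a in range(A_explore)],
    )
    loading_frame.insert(0, "variable", list(matrix.columns))
    _write_csv(loading_frame, out / "pca_loadings.csv")
    _write_csv(
        influence_table(explore, train.values, train.analyte_ids),
        out / "influence.csv",
    )

    models = fit_all_classes(
        train,
        alpha=config.alpha,
        threshold_rule=config.threshold_rule,  # type: ignore[arg-type]
        classes_min=config.classes_min,
        cv_scheme=config.cv_scheme,
        missing_policy=config.missing_policy,
        pc_counts=config.pc_counts,
    )
    save_models(models, out / "models.json")

    report_train = validate(models, train, set_label="train")
    report_test = validate(models, test, set_label="test")
    report = pd.concat([report_train.rows, report_test.rows], ignore_index=True)
    _write_csv(report, out / "report.csv")

    bundle: dict[str, Any] = {
        "matrix": matrix,
        "split": split,
        "train": train,
        "test": test,
        "explore_pca": explore,
        "models": models,
        "report": report,
        "out_dir": out,
    }

    if config.screen is not None:
        unknowns = parse_spectra(config.screen, config.screen_format)
        screen_matrix = build_matrix(
            unknowns,
            rel_intensity_threshold=config.rel_intensity_threshold,
            nl_reference=config.nl_reference,  # type: ignore[arg-type]
            include_base_peak=config.include_base_peak,
        )
        predictions = classify(models, screen_matrix)
        _write_csv(predictions.to_frame(), out / "predictions.csv")
        bundle["predictions"] = predictions

    if config.coomans_pair is not None:
        a, b = config.coomans_pair
        if a not in models or b not in models:
            raise ValueError(f"coomans pair ({a}, {b}) must both be modeled classes")
        _write_csv(
            coomans_table(models[a], models[b], matrix),
            out / "coomans.csv",
        )

    manifest = {
        "config": config.to_dict(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.name != "manifest.json" and p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle


def reproduce_published_configuration(
    feature_table: str | Path,
    pc_counts: dict[str, int] | None = None,
    alpha: float = 0.05,
    threshold_rule: str = "combined_chi2",
    train_fraction: float = 0.75,
    train_size: int | None = None,
):
    """Rerun the published screening configuration on a supplied feature table.

    Reads an externally provided 8-variable feature table (e.g. a published
    supplementary table), performs the 75/25 Kennard-Stone split, fits the
    nine class models with the published per-class component counts
    (:data:`PUBLISHED_PC_COUNTS` by default) and returns the train/test
    validation report.  The headline figures of merit of the original study
    are only recoverable when the original feature data are supplied; on any
    other table this reports the metrics of that table.
    """
    matrix = read_feature_table(feature_table)
    _, scaled = autoscale_fit(matrix)
    split = kennard_stone_split(
        scaled, train_fraction=train_fraction, train_size=train_size
    )
    train = matrix.subset(split.train_indices)
    test = matrix.subset(split.test_indices)
    models = fit_all_classes(
        train,
        alpha=alpha,
        threshold_rule=threshold_rule,  # type: ignore[arg-type]
        pc_counts=pc_counts if pc_counts is not None else PUBLISHED_PC_COUNTS,
    )
    report = pd.concat(
        [
            validate(models, train, set_label="train").rows,
            validate(models, test, set_label="test").rows,
        ],
        ignore_index=True,
    )
    return models, report, split
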