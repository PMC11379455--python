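"""End-to-end workflow wiring: simulate -> batch QC -> classify ->
evaluate -> extract/cluster -> differential analysis.

:class:`RunConfig` captures everything a run needs; every run writes its
resolved config (plus package version) next to its outputs so artifacts
are self-describing. Steps execute in the canonical order regardless of
how they are listed, each step's outputs feeding the next; a step whose
prerequisites did not run raises a dependency error naming both steps.
No step mutates its inputs on disk.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .batch import DEFAULT_EMD_THRESHOLD, batch_diagnostics
from .classify import (
    abundance_table,
    binarize,
    classify_cells,
    extract_population,
)
from .diffstats import (
    abundance_feature_table,
    run_differential,
    state_marker_table,
)
from .errors import ConfigurationError, ParameterError
from .experiment import DEFAULT_COFACTOR, arcsinh_transform, load_experiment
from .metrics import class_metrics_table
from .signatures import parse_classification_matrix
from .simulate import default_spec, generate_experiment, write_fcs_set
from .subcluster import cluster_subset

logger = logging.getLogger(__name__)

STEP_ORDER = ("simulate", "qc-batch", "classify", "evaluate", "cluster", "diff")


@dataclass
class RunConfig:
    """Resolved inputs and parameters of one pipeline run."""

    out_dir: str
    fcs_dir: str | None = None
    metadata: str | None = None
    panel: str | None = None
    matrix: str | None = None
    truth: str | None = None
    cofactor: float = DEFAULT_COFACTOR
    scope: str = "pooled"
    emd_threshold: float = DEFAULT_EMD_THRESHOLD
    alpha: float = 0.05
    posthoc: str = "dunn"
    min_cells: int = 3
    seed: int = 0
    n_cells_per_sample: int = 5000
    population: str | None = None  # for the cluster step
    cluster_method: str = "kmeans"
    cluster_k: int = 8
    artifacts: dict[str, str] = field(default_factory=dict)


def run_pipeline(config: RunConfig, steps: list[str]) -> dict[str, str]:
    """Execute the requested steps in canonical order; returns artifact paths.

    "simulate" writes the default synthetic fixture into ``out_dir/fcs``
    and points the config at it; otherwise ``fcs_dir``/``metadata``/
    ``panel``/``matrix`` must name existing files. "evaluate" needs a
    truth CSV (written by simulate, or supplied). "cluster" needs
    ``population``.
    """
    unknown = [s for s in steps if s not in STEP_ORDER]
    if unknown:
        raise ParameterError(
            f"unknown step(s) {unknown}; choose from {list(STEP_ORDER)}"
        )
    ordered = [s for s in STEP_ORDER if s in steps]
    os.makedirs(config.out_dir, exist_ok=True)

    experiment = None
    annotation = None
    truth = None

    def path(name: str) -> str:
        return os.path.join(config.out_dir, name)

    for step in ordered:
        logger.info("pipeline step: %s", step)
        if step == "simulate":
            spec = default_spec(
                n_cells_per_sample=config.n_cells_per_sample, seed=config.seed
            )
            exp, truth_labels = generate_experiment(spec)
            fcs_dir = path("fcs")
            paths = write_fcs_set(exp, truth_labels, fcs_dir, spec)
            config.fcs_dir = fcs_dir
            config.metadata = paths["metadata"]
            config.panel = paths["panel"]
            config.matrix = paths["matrix"]
            config.truth = paths["truth"]
            config.artifacts.update(paths)

        elif step in ("qc-batch", "classify"):
            if experiment is None:
                experiment = _load(config)
            matrix, missing = parse_classification_matrix(
                config.matrix, experiment.marker_names
            )
            if missing:
                raise ConfigurationError(
                    f"matrix markers missing from experiment: {missing}"
                )
            if step == "qc-batch":
                report = batch_diagnostics(
                    experiment, matrix, emd_threshold=config.emd_threshold
                )
                report.marker_table.to_csv(path("batch_report.csv"), index=False)
                report.proportions.to_csv(path("batch_proportions.csv"))
                config.artifacts["batch_report"] = path("batch_report.csv")
                logger.info("flagged (marker, batch) pairs: %s", report.flags)
            else:
                binarization = binarize(experiment, matrix, scope=config.scope)
                annotation = classify_cells(binarization, matrix)
                labels = annotation.to_frame(experiment)
                labels.to_csv(path("labels.csv"), index=False)
                abundance = abundance_table(annotation, experiment)
                abundance.to_csv(path("abundance.csv"))
                binarization.thresholds.to_csv(path("thresholds.csv"))
                config.artifacts["labels"] = path("labels.csv")
                config.artifacts["abundance"] = path("abundance.csv")
                logger.info(
                    "classified %d cells into %d labels",
                    annotation.n_cells,
                    len(set(annotation.labels)),
                )

        elif step == "evaluate":
            if annotation is None:
                raise ConfigurationError("step 'evaluate' requires step 'classify'")
            if config.truth is None:
                raise ConfigurationError("step 'evaluate' needs a truth CSV")
            truth = pd.read_csv(config.truth)["true_label"].to_numpy(dtype=object)
            table = class_metrics_table(annotation.labels, truth)
            table.to_csv(path("metrics.csv"), index=False)
            config.artifacts["metrics"] = path("metrics.csv")

        elif step == "cluster":
            if annotation is None or experiment is None:
                raise ConfigurationError("step 'cluster' requires step 'classify'")
            if config.population is None:
                raise ConfigurationError("step 'cluster' needs config.population")
            subset = extract_population(experiment, annotation, config.population)
            result = cluster_subset(
                subset, config.cluster_method, config.cluster_k, config.seed
            )
            pd.DataFrame(
                {"sample_id": subset.cell_sample_ids, "cluster": result.labels}
            ).to_csv(path("cluster_labels.csv"), index=False)
            result.medians.to_csv(path("cluster_medians.csv"))
            config.artifacts["cluster_labels"] = path("cluster_labels.csv")

        elif step == "diff":
            if annotation is None or experiment is None:
                raise ConfigurationError("step 'diff' requires step 'classify'")
            features = abundance_feature_table(annotation, experiment)
            _, frame = run_differential(
                features, posthoc=config.posthoc, alpha=config.alpha
            )
            frame.to_csv(path("diff_abundance.csv"), index=False)
            config.artifacts["diff_abundance"] = path("diff_abundance.csv")
            state = experiment.markers_of_class("state")
            if state:
                sfeat = state_marker_table(
                    experiment, annotation, state, min_cells=config.min_cells
                )
                _, sframe = run_differential(
                    sfeat, posthoc=config.posthoc, alpha=config.alpha
                )
                sframe.to_csv(path("diff_state.csv"), index=False)
                config.artifacts["diff_state"] = path("diff_state.csv")

    resolved = asdict(config)
    resolved["version"] = __version__
    resolved["steps"] = ordered
    with open(path("run_config.json"), "w") as fh:
        json.dump(resolved, fh, indent=2, default=str)
    return dict(config.artifacts)


def _load(config: RunConfig):
    for name in ("fcs_dir", "metadata", "panel", "matrix"):
        if getattr(config, name) is None:
            raise ConfigurationError(
                f"config.{name} is required (or run the 'simulate' step first)"
            )
    experiment = load_experiment(config.fcs_dir, config.metadata, config.panel)
    return arcsinh_transform(experiment, cofactor=config.cofactor)
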