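"""Synthetic CyTOF experiment generator with ground-truth labels.

Emulates the distributional shape the binarization classifier relies on:
on the arcsinh scale each marker is a two-mode mixture with zero inflation
-- the negative mode is a point mass at exactly zero mixed with a
half-normal (non-expressing cells still register small counts), the
positive mode is a normal well separated from it. A cell's lineage fixes
which mode each signature marker is drawn from, subject to a small
"noise flip" probability standing in for misexpression and spillover;
markers a lineage is agnostic about ('A'), and all state markers, draw
from the mixture at the marker's mixing weight. Condition effects scale
lineage proportions or shift state-marker locations; batch effects add a
location offset per (batch, marker). Everything is deterministic given
the spec's seed.

Deliberately not modelled: ion-count physics, spillover matrices,
doublets, acquisition drift within a run.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import yaml

from .errors import ValidationError
from .experiment import (
    DEFAULT_COFACTOR,
    Experiment,
    assemble_experiment,
    inverse_arcsinh,
)
from .fcs import write_fcs
from .signatures import ClassificationMatrix, write_classification_matrix


@dataclass
class MarkerModel:
    """Mixture shape of one marker on the transformed scale."""

    name: str
    marker_class: str = "type"  # "type" or "state"
    neg_scale: float = 0.5  # half-normal scale of the negative mode
    zero_inflation: float = 0.3  # point mass at exactly 0 within the negative mode
    pos_loc: float = 3.0
    pos_scale: float = 0.5
    mix_weight: float = 0.3  # P(positive mode) for signature-'A' draws

    def __post_init__(self) -> None:
        if self.neg_scale <= 0 or self.pos_scale <= 0:
            raise ValidationError(f"marker {self.name}: scales must be positive")
        if not 0 <= self.zero_inflation <= 1 or not 0 <= self.mix_weight <= 1:
            raise ValidationError(f"marker {self.name}: weights must lie in [0,1]")


@dataclass
class CellTypeSpec:
    name: str
    signature: dict[str, str]  # marker -> '+', '-' or 'A'
    proportion: float


@dataclass
class SampleSpec:
    sample_id: str
    condition: str
    batch: str
    n_cells: int
    is_replicate_reference: bool = False


@dataclass
class SimulationSpec:
    """Full description of a synthetic study.

    ``abundance_effects[(condition, cell_type)]`` multiplies that
    lineage's baseline proportion in that condition (proportions are then
    renormalised per sample); ``state_effects[(condition, marker,
    cell_type)]`` adds a location shift to that marker in those cells;
    ``batch_shifts[(batch, marker)]`` adds a location offset to every
    cell of the batch.
    """

    cell_types: list[CellTypeSpec]
    markers: list[MarkerModel]
    samples: list[SampleSpec]
    abundance_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    state_effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    batch_shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_flip: float = 0.01
    seed: int = 0
    cofactor: float = DEFAULT_COFACTOR

    def __post_init__(self) -> None:
        if not 0 <= self.noise_flip < 0.5:
            raise ValidationError("noise_flip must lie in [0, 0.5)")
        total = sum(ct.proportion for ct in self.cell_types)
        if total <= 0:
            raise ValidationError("cell-type proportions are not normalizable")
        marker_names = [m.name for m in self.markers]
        if len(set(marker_names)) != len(marker_names):
            raise ValidationError("duplicate marker names in spec")
        for ct in self.cell_types:
            unknown = set(ct.signature) - set(marker_names)
            if unknown:
                raise ValidationError(
                    f"cell type {ct.name}: signature names unknown markers {sorted(unknown)}"
                )

    @property
    def type_names(self) -> list[str]:
        return [ct.name for ct in self.cell_types]

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def effective_proportions(self, sample: SampleSpec) -> np.ndarray:
        """Per-lineage proportions after condition multipliers, renormalised."""
        p = np.asarray(
            [
                ct.proportion
                * self.abundance_effects.get((sample.condition, ct.name), 1.0)
                for ct in self.cell_types
            ],
            dtype=float,
        )
        if p.sum() <= 0:
            raise ValidationError("effective proportions are not normalizable")
        return p / p.sum()

    def classification_matrix(self) -> ClassificationMatrix:
        """Signature table over the type markers (state markers excluded)."""
        type_markers = [m.name for m in self.markers if m.marker_class == "type"]
        entries = pd.DataFrame(
            {
                m: [ct.signature.get(m, "A") for ct in self.cell_types]
                for m in type_markers
            },
            index=self.type_names,
        )
        return ClassificationMatrix(entries)

    def samples_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "batch": [s.batch for s in self.samples],
                "is_replicate_reference": [
                    s.is_replicate_reference for s in self.samples
                ],
            }
        )

    def panel_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": [f"Ch{i + 1:02d}" for i in range(len(self.markers))],
                "antigen": self.marker_names,
                "marker_class": [m.marker_class for m in self.markers],
            }
        )


def default_spec(
    n_cells_per_sample: int = 5000,
    seed: int = 0,
    noise_flip: float = 0.01,
    abundance_effects: dict[tuple[str, str], float] | None = None,
    state_effects: dict[tuple[str, str, str], float] | None = None,
    batch_shifts: dict[tuple[str, str], float] | None = None,
) -> SimulationSpec:
    """The shipped study design: 3 conditions x 6 samples, 3 batches,
    7 PBMC lineages, 12 markers (8 phenotypic + 4 state).

    One healthy sample per batch is flagged as a technical-replicate
    reference; with no effects configured (the default) the replicates
    are identically distributed across batches, as real anchors would be.
    """
    # lineage signatures over the 8 phenotypic markers; mutually exclusive
    sig = {
        "CD4 T cells": {"CD3": "+", "CD4": "+", "CD8a": "-", "TCRgd": "-"},
        "CD8 T cells": {"CD3": "+", "CD8a": "+", "CD4": "-", "TCRgd": "-"},
        "TCRgd T cells": {"CD3": "+", "TCRgd": "+"},
        "B cells": {"CD3": "-", "CD19": "+"},
        "NK cells": {"CD3": "-", "CD19": "-", "CD56": "+", "CD14": "-"},
        "Monocytes": {"CD3": "-", "CD19": "-", "CD14": "+"},
        "Dendritic cells": {
            "CD3": "-", "CD19": "-", "CD14": "-", "CD56": "-", "HLA-DR": "+",
        },
    }
    proportions = {
        "CD4 T cells": 0.36,
        "CD8 T cells": 0.18,
        "TCRgd T cells": 0.03,
        "B cells": 0.11,
        "NK cells": 0.11,
        "Monocytes": 0.17,
        "Dendritic cells": 0.04,
    }
    cell_types = [
        CellTypeSpec(name, sig[name], proportions[name]) for name in sig
    ]
    type_markers = ["CD3", "CD4", "CD8a", "CD19", "CD56", "CD14", "TCRgd", "HLA-DR"]
    state_markers = ["CD25", "CD38", "PD-1", "Ki-67"]
    markers = [MarkerModel(m, marker_class="type") for m in type_markers] + [
        MarkerModel(m, marker_class="state") for m in state_markers
    ]
    # monocytes and DCs express HLA-DR too; make the agnostic draw reflect it
    conditions = ["healthy", "mild", "severe"]
    batches = ["b1", "b2", "b3"]
    samples = []
    idx = 0
    for cond in conditions:
        for j in range(6):
            idx += 1
            samples.append(
                SampleSpec(
                    sample_id=f"s{idx:02d}",
                    condition=cond,
                    batch=batches[j % 3],
                    n_cells=n_cells_per_sample,
                    is_replicate_reference=(cond == "healthy" and j < 3),
                )
            )
    return SimulationSpec(
        cell_types=cell_types,
        markers=markers,
        samples=samples,
        abundance_effects=dict(abundance_effects or {}),
        state_effects=dict(state_effects or {}),
        batch_shifts=dict(batch_shifts or {}),
        noise_flip=noise_flip,
        seed=seed,
    )


def simulate_abundance_counts(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Multinomial per-sample lineage counts (samples x cell types).

    This is the abundance layer of the generator on its own -- handy for
    statistical simulations that do not need marker intensities.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rows = {}
    for sample in spec.samples:
        p = spec.effective_proportions(sample)
        rows[sample.sample_id] = rng.multinomial(sample.n_cells, p)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=spec.type_names)
    df.index.name = "sample_id"
    return df


def generate_experiment(
    spec: SimulationSpec,
) -> tuple[Experiment, np.ndarray]:
    """Draw a full experiment (transformed scale) plus per-cell true labels.

    Cell order is sample-major, matching what reading the written FCS
    fixture back produces, so the truth vector aligns either way.
    """
    rng = np.random.default_rng(spec.seed)
    counts = simulate_abundance_counts(spec, rng)
    sig_code = {  # per marker: per type +1 / -1 / 0 ('A')
        m.name: np.asarray(
            [
                {"+": 1, "-": -1, "A": 0}[ct.signature.get(m.name, "A")]
                for ct in spec.cell_types
            ],
            dtype=np.int8,
        )
        for m in spec.markers
    }
    blocks: list[np.ndarray] = []
    truth_parts: list[np.ndarray] = []
    sample_ids: list[np.ndarray] = []
    for sample in spec.samples:
        n = sample.n_cells
        type_idx = np.repeat(
            np.arange(len(spec.cell_types)), counts.loc[sample.sample_id].to_numpy()
        )
        rng.shuffle(type_idx)
        block = np.empty((n, len(spec.markers)), dtype=np.float64)
        for j, marker in enumerate(spec.markers):
            code = sig_code[marker.name][type_idx]
            positive = np.empty(n, dtype=bool)
            informative = code != 0
            # signature-driven modes, flipped with probability noise_flip
            flips = rng.random(n) < spec.noise_flip
            positive[informative] = np.where(
                flips[informative], code[informative] < 0, code[informative] > 0
            )
            agnostic = ~informative
            positive[agnostic] = rng.random(int(agnostic.sum())) < marker.mix_weight

            values = np.empty(n, dtype=np.float64)
            n_pos = int(positive.sum())
            values[positive] = rng.normal(marker.pos_loc, marker.pos_scale, n_pos)
            n_neg = n - n_pos
            neg = np.abs(rng.normal(0.0, marker.neg_scale, n_neg))
            neg[rng.random(n_neg) < marker.zero_inflation] = 0.0
            values[~positive] = neg

            for t, ct in enumerate(spec.cell_types):
                shift = spec.state_effects.get(
                    (sample.condition, marker.name, ct.name), 0.0
                )
                if shift:
                    values[type_idx == t] += shift
            values += spec.batch_shifts.get((sample.batch, marker.name), 0.0)
            block[:, j] = values
        blocks.append(block)
        truth_parts.append(
            np.asarray([spec.cell_types[t].name for t in type_idx], dtype=object)
        )
        sample_ids.append(np.full(n, sample.sample_id, dtype=object))

    experiment = Experiment(
        intensities=np.vstack(blocks),
        marker_names=spec.marker_names,
        cell_sample_ids=np.concatenate(sample_ids),
        samples=spec.samples_table(),
        panel=spec.panel_table(),
        transformed=True,
        provenance=[f"simulated (seed={spec.seed})"],
    )
    return experiment, np.concatenate(truth_parts)


def write_fcs_set(
    experiment: Experiment,
    truth: np.ndarray,
    out_dir: str | os.PathLike,
    spec: SimulationSpec,
) -> dict[str, str]:
    """Write a complete runnable fixture: one FCS per sample (raw scale),
    metadata.csv, panel.csv, matrix.csv and truth.csv.

    Returns the paths written, keyed by role. The FCS files carry the
    inverse-transformed (ion-count scale) intensities; reading them back
    through the loader and re-transforming reproduces the experiment to
    float32 precision.
    """
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    panel = spec.panel_table()
    raw = inverse_arcsinh(experiment.intensities, spec.cofactor)
    for sample_id in experiment.samples["sample_id"].astype(str):
        mask = experiment.cell_sample_ids == sample_id
        write_fcs(
            os.path.join(out, f"{sample_id}.fcs"),
            raw[mask],
            short_names=list(panel["channel"]),
            stain_names=list(panel["antigen"]),
        )
    paths = {
        "metadata": os.path.join(out, "metadata.csv"),
        "panel": os.path.join(out, "panel.csv"),
        "matrix": os.path.join(out, "matrix.csv"),
        "truth": os.path.join(out, "truth.csv"),
    }
    experiment.samples.to_csv(paths["metadata"], index=False)
    panel.to_csv(paths["panel"], index=False)
    write_classification_matrix(spec.classification_matrix(), paths["matrix"])
    pd.DataFrame(
        {"sample_id": experiment.cell_sample_ids, "true_label": truth}
    ).to_csv(paths["truth"], index=False)
    return paths


# ---------------------------------------------------------------------------
# YAML (de)serialization of simulation specs


def spec_to_yaml(spec: SimulationSpec, path: str | os.PathLike) -> None:
    doc = {
        "seed": spec.seed,
        "cofactor": spec.cofactor,
        "noise_flip": spec.noise_flip,
        "cell_types": [
            {"name": ct.name, "signature": ct.signature, "proportion": ct.proportion}
            for ct in spec.cell_types
        ],
        "markers": [
            {
                "name": m.name,
                "marker_class": m.marker_class,
                "neg_scale": m.neg_scale,
                "zero_inflation": m.zero_inflation,
                "pos_loc": m.pos_loc,
                "pos_scale": m.pos_scale,
                "mix_weight": m.mix_weight,
            }
            for m in spec.markers
        ],
        "samples": [
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "batch": s.batch,
                "n_cells": s.n_cells,
                "is_replicate_reference": s.is_replicate_reference,
            }
            for s in spec.samples
        ],
        "abundance_effects": [
            {"condition": c, "cell_type": t, "multiplier": v}
            for (c, t), v in spec.abundance_effects.items()
        ],
        "state_effects": [
            {"condition": c, "marker": m, "cell_type": t, "shift": v}
            for (c, m, t), v in spec.state_effects.items()
        ],
        "batch_shifts": [
            {"batch": b, "marker": m, "shift": v}
            for (b, m), v in spec.batch_shifts.items()
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path: str | os.PathLike) -> SimulationSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return SimulationSpec(
            cell_types=[
                CellTypeSpec(d["name"], dict(d["signature"]), float(d["proportion"]))
                for d in doc["cell_types"]
            ],
            markers=[MarkerModel(**d) for d in doc["markers"]],
            samples=[SampleSpec(**d) for d in doc["samples"]],
            abundance_effects={
                (d["condition"], d["cell_type"]): float(d["multiplier"])
                for d in doc.get("abundance_effects", [])
            },
            state_effects={
                (d["condition"], d["marker"], d["cell_type"]): float(d["shift"])
                for d in doc.get("state_effects", [])
            },
            batch_shifts={
                (d["batch"], d["marker"]): float(d["shift"])
                for d in doc.get("batch_shifts", [])
            },
            noise_flip=float(doc.get("noise_flip", 0.01)),
            seed=int(doc.get("seed", 0)),
            cofactor=float(doc.get("cofactor", DEFAULT_COFACTOR)),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed simulation spec ({exc})") from exc
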