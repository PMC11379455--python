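"""The experiment container: cells x markers with sample and panel metadata.

An :class:`Experiment` holds a dense intensity matrix together with a
per-cell sample id, a sample metadata table (condition, batch, technical-
replicate flag) and the antibody-panel table. Markers whose panel class is
``none`` (beads, DNA intercalators, event length...) are dropped at assembly
so every downstream module sees only analysable markers. Intensities start
as raw ion counts and are moved onto the variance-stabilised analysis scale
exactly once with :func:`arcsinh_transform`.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError, StateError, ValidationError
from .fcs import read_fcs_file

#: Community-standard arcsinh cofactor for CyTOF ion counts.
DEFAULT_COFACTOR = 5.0

MARKER_CLASSES = ("type", "state", "none")

SAMPLE_COLUMNS = ("sample_id", "condition", "batch", "is_replicate_reference")
PANEL_COLUMNS = ("channel", "antigen", "marker_class")


@dataclass
class Experiment:
    """Cells x markers intensity matrix with aligned metadata.

    Attributes
    ----------
    intensities:
        float array, ``n_cells x n_markers``. Raw nonnegative ion counts
        before transformation, unitless arcsinh scale after.
    marker_names:
        antigen names, one per column, unique.
    cell_sample_ids:
        per-cell sample identifier (length ``n_cells``).
    samples:
        one row per sample: sample_id, condition, batch,
        is_replicate_reference.
    panel:
        the antibody panel restricted to retained markers: channel,
        antigen, marker_class in {type, state}.
    transformed:
        whether the arcsinh transform has been applied.
    provenance:
        free-form notes recording how this object was derived.
    """

    intensities: np.ndarray
    marker_names: list[str]
    cell_sample_ids: np.ndarray
    samples: pd.DataFrame
    panel: pd.DataFrame
    transformed: bool = False
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.cell_sample_ids = np.asarray(self.cell_sample_ids)
        if self.intensities.ndim != 2:
            raise ValidationError("intensities must be a 2-D cells x markers matrix")
        n_cells, n_markers = self.intensities.shape
        if len(self.marker_names) != n_markers:
            raise ValidationError("marker_names length must match matrix width")
        if len(set(self.marker_names)) != n_markers or any(
            not m for m in self.marker_names
        ):
            raise ValidationError("marker names must be unique and non-empty")
        if len(self.cell_sample_ids) != n_cells:
            raise ValidationError("cell_sample_ids length must match cell count")
        missing_cols = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing_cols:
            raise ValidationError(f"samples table missing columns {sorted(missing_cols)}")
        known = set(self.samples["sample_id"].astype(str))
        present = set(np.unique(self.cell_sample_ids).astype(str))
        orphans = present - known
        if orphans:
            raise ValidationError(
                f"cells reference sample ids absent from metadata: {sorted(orphans)}"
            )
        bad_class = set(self.panel["marker_class"]) - {"type", "state"}
        if bad_class:
            raise ValidationError(
                f"assembled experiment may only contain type/state markers, got {sorted(bad_class)}"
            )

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_markers(self) -> int:
        return self.intensities.shape[1]

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError as exc:
            raise ConfigurationError(
                f"marker {name!r} not in experiment (have {self.marker_names})"
            ) from exc

    def marker_values(self, name: str) -> np.ndarray:
        return self.intensities[:, self.marker_index(name)]

    def markers_of_class(self, marker_class: str) -> list[str]:
        sel = self.panel.loc[self.panel["marker_class"] == marker_class, "antigen"]
        return [m for m in self.marker_names if m in set(sel)]

    def subset_cells(self, mask: np.ndarray, note: str | None = None) -> "Experiment":
        """Row-subset preserving metadata; used by population extraction."""
        mask = np.asarray(mask)
        if mask.dtype != bool or mask.shape != (self.n_cells,):
            raise ParameterError("mask must be a boolean vector of length n_cells")
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return replace(
            self,
            intensities=self.intensities[mask],
            cell_sample_ids=self.cell_sample_ids[mask],
            provenance=prov,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.marker_names)
        df.insert(0, "sample_id", self.cell_sample_ids)
        return df


def arcsinh_transform(
    experiment: Experiment, cofactor: float = DEFAULT_COFACTOR
) -> Experiment:
    """Apply ``asinh(x / cofactor)`` to every intensity, once.

    The transform is strictly increasing, so per-marker rank order of cells
    is preserved; the inverse is ``sinh(y) * cofactor``.
    """
    if cofactor <= 0 or not np.isfinite(cofactor):
        raise ParameterError(f"cofactor must be a positive real, got {cofactor}")
    if experiment.transformed:
        raise StateError("experiment is already arcsinh-transformed")
    out = replace(
        experiment,
        intensities=np.arcsinh(experiment.intensities / cofactor),
        transformed=True,
    )
    out.provenance = experiment.provenance + [f"arcsinh(cofactor={cofactor})"]
    return out


def inverse_arcsinh(values: np.ndarray, cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    if cofactor <= 0:
        raise ParameterError(f"cofactor must be positive, got {cofactor}")
    return np.sinh(values) * cofactor


def read_samples_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read sample metadata (CSV/TSV): sample_id, condition, batch,
    is_replicate_reference (optional, default false)."""
    df = _read_table(path)
    if "is_replicate_reference" not in df.columns:
        df["is_replicate_reference"] = False
    missing = {"sample_id", "condition", "batch"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: metadata missing columns {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dupes}")
    df["is_replicate_reference"] = df["is_replicate_reference"].map(_as_bool)
    return df[list(SAMPLE_COLUMNS)]


def read_panel_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the panel table (CSV/TSV): channel, antigen, marker_class."""
    df = _read_table(path)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: panel missing columns {sorted(missing)}")
    df["marker_class"] = df["marker_class"].astype(str).str.strip().str.lower()
    bad = set(df["marker_class"]) - set(MARKER_CLASSES)
    if bad:
        raise ValidationError(
            f"{path}: marker_class must be one of {MARKER_CLASSES}, got {sorted(bad)}"
        )
    df["antigen"] = df["antigen"].astype(str).str.strip()
    df["channel"] = df["channel"].astype(str).str.strip()
    return df[list(PANEL_COLUMNS)]


def assemble_experiment(
    per_sample: dict[str, tuple[np.ndarray, list[str]]],
    samples: pd.DataFrame,
    panel: pd.DataFrame,
    transformed: bool = False,
) -> Experiment:
    """Concatenate per-sample event matrices into one Experiment.

    ``per_sample`` maps sample_id -> (events x channels matrix, channel
    names, i.e. $PnN identifiers). The panel maps channels to antigens and
    selects which are kept: markers with class ``none`` are dropped here,
    never silently retained. The metadata join is strict -- samples without
    a metadata row abort with a listing.
    """
    known = set(samples["sample_id"].astype(str))
    unmatched = sorted(set(per_sample) - known)
    if unmatched:
        raise ValidationError(
            f"samples without a metadata row: {unmatched}; "
            "add them to the metadata table or remove the files"
        )
    keep = panel[panel["marker_class"] != "none"].reset_index(drop=True)
    if keep.empty:
        raise ValidationError("panel retains no type/state markers")
    blocks: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    for sample_id in samples["sample_id"].astype(str):
        if sample_id not in per_sample:
            continue
        matrix, channels = per_sample[sample_id]
        matrix = np.asarray(matrix, dtype=np.float64)
        col_of = {c: i for i, c in enumerate(channels)}
        missing = [c for c in keep["channel"] if c not in col_of]
        if missing:
            raise ValidationError(
                f"sample {sample_id!r} lacks panel channels {missing}"
            )
        blocks.append(matrix[:, [col_of[c] for c in keep["channel"]]])
        ids.append(np.full(matrix.shape[0], sample_id, dtype=object))
    if not blocks:
        raise ValidationError("no samples to assemble")
    return Experiment(
        intensities=np.vstack(blocks),
        marker_names=list(keep["antigen"]),
        cell_sample_ids=np.concatenate(ids),
        samples=samples.reset_index(drop=True),
        panel=keep,
        transformed=transformed,
        provenance=[f"assembled from {len(blocks)} sample(s)"],
    )


def load_experiment(
    fcs_dir: str | os.PathLike,
    metadata_path: str | os.PathLike,
    panel_path: str | os.PathLike,
) -> Experiment:
    """Load ``<sample_id>.fcs`` files named in the metadata table.

    Channel matching uses $PnN identifiers against the panel's channel
    column; the panel's antigen names override any $PnS the files carry.
    Returns an untransformed experiment.
    """
    samples = read_samples_table(metadata_path)
    panel = read_panel_table(panel_path)
    per_sample: dict[str, tuple[np.ndarray, list[str]]] = {}
    missing_files: list[str] = []
    for sample_id in samples["sample_id"]:
        path = os.path.join(os.fspath(fcs_dir), f"{sample_id}.fcs")
        if not os.path.exists(path):
            missing_files.append(path)
            continue
        parsed = read_fcs_file(path)
        per_sample[sample_id] = (parsed.matrix, parsed.short_names)
    if missing_files:
        raise ValidationError(f"metadata rows without an FCS file: {missing_files}")
    return assemble_experiment(per_sample, samples, panel)


def export_experiment(experiment: Experiment, out_prefix: str | os.PathLike) -> None:
    """Write ``<prefix>.csv`` (cells x markers plus sample_id) and
    ``<prefix>.meta.json`` (samples, panel, flags)."""
    prefix = os.fspath(out_prefix)
    experiment.to_frame().to_csv(prefix + ".csv", index=False)
    meta = {
        "transformed": experiment.transformed,
        "provenance": experiment.provenance,
        "samples": experiment.samples.to_dict(orient="records"),
        "panel": experiment.panel.to_dict(orient="records"),
    }
    with open(prefix + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    sep = "\t" if os.fspath(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes", "y"}
    return bool(value)
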