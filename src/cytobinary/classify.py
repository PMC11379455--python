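"""Semi-supervised lineage classification by per-marker binarization.

Each phenotypic marker named in the signature matrix is split into a
negative and a positive population with exact one-dimensional two-means:
because the optimal 2-means partition of points on a line is contiguous in
sorted order, the global within-cluster-sum-of-squares minimiser is found by
scanning every breakpoint of the sorted values with prefix sums -- no
iterative refinement, no initialisation, no seed, O(n log n). Cells are then
matched against the signature rows: '+' requires the cell above the
marker's threshold, '-' below, 'A' is ignored. Cells matching no row are
"Unclassified"; cells matching several get the most specific row (fewest
'A' entries), ties broken by matrix row order, with the raw match count
kept for auditing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ParameterError, PopulationLookupError
from .experiment import Experiment
from .signatures import ClassificationMatrix

logger = logging.getLogger(__name__)

UNCLASSIFIED = "Unclassified"

POOLED = "pooled"
PER_SAMPLE = "per_sample"


def two_means_1d(
    values: np.ndarray,
) -> tuple[float, np.ndarray, tuple[float, float], bool]:
    """Exact two-means split of a 1-D sample.

    Returns ``(threshold, labels, (low_mean, high_mean), degenerate)``.
    The positive cluster is the one with the higher mean; ``labels`` is
    True for positive cells; the threshold is the midpoint between the
    maximum of the lower cluster and the minimum of the upper cluster, so
    ``labels == values > threshold`` exactly. All-equal input is flagged
    degenerate with every cell negative.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 1:
        raise DataError("two_means_1d needs at least one value")
    if not np.all(np.isfinite(x)):
        raise DataError("two_means_1d input contains NaN or Inf")

    xs = np.sort(x, kind="stable")
    n = xs.size
    if xs[0] == xs[-1]:
        m = float(xs[0])
        return m, np.zeros(n, dtype=bool), (m, m), True

    # WSS of the split (xs[:i] | xs[i:]) via prefix sums:
    #   WSS(i) = ssq_total - s_lo(i)^2/i - s_hi(i)^2/(n-i)
    csum = np.cumsum(xs)
    total = csum[-1]
    ssq_total = float(np.dot(xs, xs))
    i = np.arange(1, n)
    s_lo = csum[:-1]
    s_hi = total - s_lo
    wss = ssq_total - s_lo**2 / i - s_hi**2 / (n - i)
    # Only breakpoints between distinct values yield a separating
    # threshold; splits inside a tie block never beat the block boundary.
    valid = xs[1:] > xs[:-1]
    wss = np.where(valid, wss, np.inf)
    best = int(np.argmin(wss))  # first minimiser: deterministic tie-break
    cut = best + 1
    threshold = float((xs[cut - 1] + xs[cut]) / 2.0)
    low_mean = float(s_lo[best] / cut)
    high_mean = float(s_hi[best] / (n - cut))
    labels = x > threshold
    return threshold, labels, (low_mean, high_mean), False


@dataclass
class BinarizationResult:
    """Per-marker thresholds and the resulting cells x markers binary calls.

    ``thresholds`` has one row per fitting stratum ("pooled", or one row
    per sample id under per-sample scope) and one column per binarized
    marker. ``degenerate`` flags markers that were constant in at least one
    stratum (those strata's cells are all-negative for the marker).
    """

    thresholds: pd.DataFrame
    binary: np.ndarray  # bool, n_cells x len(markers)
    markers: list[str]
    degenerate: pd.Series
    positive_fraction: pd.Series
    scope: str = POOLED

    def column(self, marker: str) -> np.ndarray:
        try:
            return self.binary[:, self.markers.index(marker)]
        except ValueError as exc:
            raise ConfigurationError(f"marker {marker!r} was not binarized") from exc


def binarize(
    experiment: Experiment,
    matrix: ClassificationMatrix,
    scope: str = POOLED,
) -> BinarizationResult:
    """Two-means binarization of every informative matrix marker.

    ``scope="pooled"`` (default) fits one threshold per marker on all cells
    concatenated; ``scope="per_sample"`` fits within each sample, for data
    with strong uncorrected batch structure. Markers in the matrix but
    absent from the experiment raise a configuration error; markers whose
    matrix column is all 'A' are skipped entirely.
    """
    if not experiment.transformed:
        raise ParameterError(
            "binarize expects arcsinh-transformed intensities; "
            "call arcsinh_transform first"
        )
    if scope not in (POOLED, PER_SAMPLE):
        raise ParameterError(f"scope must be 'pooled' or 'per_sample', got {scope!r}")
    markers = matrix.informative_markers()
    missing = [m for m in markers if m not in experiment.marker_names]
    if missing:
        raise ConfigurationError(
            f"classification-matrix markers missing from experiment: {missing}"
        )

    n_cells = experiment.n_cells
    binary = np.zeros((n_cells, len(markers)), dtype=bool)
    if scope == POOLED:
        strata: list[tuple[str, np.ndarray]] = [
            (POOLED, np.ones(n_cells, dtype=bool))
        ]
    else:
        strata = [
            (sid, experiment.cell_sample_ids == sid)
            for sid in experiment.samples["sample_id"].astype(str)
            if (experiment.cell_sample_ids == sid).any()
        ]
    thresholds = pd.DataFrame(
        np.nan, index=[s for s, _ in strata], columns=markers, dtype=float
    )
    degenerate_any = pd.Series(False, index=markers)
    for j, marker in enumerate(markers):
        col = experiment.marker_values(marker)
        for stratum, mask in strata:
            thr, labels, _, degen = two_means_1d(col[mask])
            thresholds.loc[stratum, marker] = thr
            binary[mask, j] = labels
            if degen:
                degenerate_any[marker] = True
                logger.warning(
                    "marker %r is constant in stratum %r; all cells called "
                    "negative there",
                    marker,
                    stratum,
                )
    positive_fraction = pd.Series(binary.mean(axis=0), index=markers)
    return BinarizationResult(
        thresholds=thresholds,
        binary=binary,
        markers=markers,
        degenerate=degenerate_any,
        positive_fraction=positive_fraction,
        scope=scope,
    )


@dataclass
class CellAnnotation:
    """Per-cell lineage labels plus the number of signature rows matched.

    ``match_counts[i] == 0`` iff ``labels[i] == "Unclassified"``; counts
    above 1 reveal cells whose signature membership was ambiguous before
    the most-specific-row tie-break.
    """

    labels: np.ndarray  # dtype=object strings
    match_counts: np.ndarray  # int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.match_counts = np.asarray(self.match_counts, dtype=np.int64)
        if self.labels.shape != self.match_counts.shape:
            raise DataError("labels and match_counts must align")

    @property
    def n_cells(self) -> int:
        return self.labels.size

    def to_frame(self, experiment: Experiment | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_index": np.arange(self.n_cells),
                "label": self.labels,
                "match_count": self.match_counts,
            }
        )
        if experiment is not None:
            df.insert(1, "sample_id", experiment.cell_sample_ids)
        return df


def classify_cells(
    binarization: BinarizationResult, matrix: ClassificationMatrix
) -> CellAnnotation:
    """Match binarized cells against signature rows.

    A cell matches a row iff every '+' marker is positive and every '-'
    marker negative; 'A' markers never constrain. Zero matches yields
    "Unclassified". Multiple matches resolve to the most specific row
    (fewest 'A' entries over the matrix's marker set), then earliest row.
    Fully deterministic; invariant to cell order and marker column order.
    """
    missing = [
        m for m in matrix.informative_markers() if m not in binarization.markers
    ]
    if missing:
        raise ConfigurationError(
            f"binarization lacks matrix markers {missing}; re-run binarize"
        )
    n_cells = binarization.binary.shape[0]
    n_types = len(matrix.cell_types)
    match = np.ones((n_cells, n_types), dtype=bool)
    for t, cell_type in enumerate(matrix.cell_types):
        for marker in matrix.markers:
            symbol = matrix.entries.loc[cell_type, marker]
            if symbol == "A":
                continue
            col = binarization.column(marker)
            match[:, t] &= col if symbol == "+" else ~col

    counts = match.sum(axis=1)
    # Most-specific first, original order among equals: stable argsort of
    # descending specificity gives the priority permutation.
    specificity = matrix.specificity().to_numpy()
    priority = np.argsort(-specificity, kind="stable")
    ranked = match[:, priority]
    first = np.argmax(ranked, axis=1)  # first True in priority order
    chosen = priority[first]
    type_names = np.asarray(matrix.cell_types, dtype=object)
    labels = np.where(counts > 0, type_names[chosen], UNCLASSIFIED)
    return CellAnnotation(labels=labels, match_counts=counts)


def abundance_table(
    annotation: CellAnnotation,
    experiment: Experiment,
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Percent of each sample's cells per lineage (samples x cell types).

    The denominator is every cell of the sample, so "Unclassified" is a
    first-class column and each row sums to 100. Samples present in the
    metadata but with no cells are excluded with a warning.
    """
    if annotation.n_cells != experiment.n_cells:
        raise DataError("annotation does not align with experiment")
    if cell_types is None:
        seen = [str(c) for c in pd.unique(annotation.labels) if c != UNCLASSIFIED]
        cell_types = sorted(seen) + [UNCLASSIFIED]
    counts = (
        pd.crosstab(experiment.cell_sample_ids, annotation.labels)
        .reindex(columns=cell_types, fill_value=0)
    )
    counts.index.name = "sample_id"
    empty = [
        s
        for s in experiment.samples["sample_id"].astype(str)
        if s not in counts.index
    ]
    if empty:
        logger.warning("samples with zero cells excluded from abundance: %s", empty)
    totals = counts.sum(axis=1)
    return counts.div(totals, axis=0) * 100.0


def population_counts(
    annotation: CellAnnotation, experiment: Experiment
) -> pd.DataFrame:
    """Raw per-sample cell counts per lineage (same layout as abundances)."""
    counts = pd.crosstab(experiment.cell_sample_ids, annotation.labels)
    counts.index.name = "sample_id"
    return counts


def extract_population(
    experiment: Experiment, annotation: CellAnnotation, cell_type: str
) -> Experiment:
    """Subset the experiment to cells annotated ``cell_type``.

    Metadata tables are carried over unchanged and a provenance note is
    recorded. Asking for a label that annotated no cell raises a lookup
    error listing the labels that do exist.
    """
    if annotation.n_cells != experiment.n_cells:
        raise DataError("annotation does not align with experiment")
    mask = annotation.labels == cell_type
    if not mask.any():
        available = sorted({str(c) for c in pd.unique(annotation.labels)})
        raise PopulationLookupError(
            f"no cells labelled {cell_type!r}; available labels: {available}"
        )
    return experiment.subset_cells(
        mask, note=f"extracted population {cell_type!r} ({int(mask.sum())} cells)"
    )
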