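"""Replicate-anchored batch-effect diagnostics.

Acquisition batches are compared on technical replicates of the same
material, so any distributional difference is non-biological. Two levels
are reported, mirroring how batch effects manifest: per-marker
distribution distances (1-D earth-mover's distance on the transformed
scale, estimated from matched quantiles) plus median shifts, and
per-batch cell-type proportions from a quick run of the binarization
classifier on the replicate cells. Diagnostics are strictly read-only;
correction is delegated to dedicated normalisation tools that consume
this report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import abundance_table, binarize, classify_cells
from .errors import ConfigurationError, ParameterError
from .experiment import Experiment
from .signatures import ClassificationMatrix

#: default flag threshold, transformed-scale units
DEFAULT_EMD_THRESHOLD = 0.3
#: quantile grid resolution for the EMD estimate
EMD_QUANTILES = 1000


def earth_movers_distance_1d(
    x: np.ndarray, y: np.ndarray, n_quantiles: int = EMD_QUANTILES
) -> float:
    """1-D EMD (Wasserstein-1) as mean absolute difference of matched
    quantiles.

    For a pure location shift y = x + delta this equals |delta| exactly in
    distribution, which is what makes it readable as "how far apart, in
    marker units, are these two batches".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("EMD needs nonempty samples")
    q = (np.arange(n_quantiles) + 0.5) / n_quantiles
    return float(np.abs(np.quantile(x, q) - np.quantile(y, q)).mean())


@dataclass
class BatchReport:
    """Diagnostics per (marker, batch) and per batch.

    ``marker_table`` columns: batch, marker, emd (vs the pooled replicate
    distribution of the other batches), median_shift, flagged.
    ``proportions``: batch x cell type percent table from classifying the
    replicate cells. ``flags``: the flagged (marker, batch) pairs.
    """

    marker_table: pd.DataFrame
    proportions: pd.DataFrame
    emd_threshold: float

    @property
    def flags(self) -> list[tuple[str, str]]:
        sel = self.marker_table[self.marker_table["flagged"]]
        return list(zip(sel["marker"], sel["batch"]))


def batch_diagnostics(
    experiment: Experiment,
    matrix: ClassificationMatrix,
    emd_threshold: float = DEFAULT_EMD_THRESHOLD,
) -> BatchReport:
    """Compare each batch's replicate distribution against the others.

    Requires >= 2 batches, each containing at least one sample flagged
    ``is_replicate_reference``. For every marker the EMD and median shift
    of a batch's replicate cells are computed against the replicate cells
    of all *other* batches pooled, so a shift confined to one batch is
    attributed to it at full magnitude. Pairs with EMD above the threshold
    are flagged. Cell-type proportions per batch come from running the
    binarization classifier on replicate cells only.
    """
    if emd_threshold < 0:
        raise ParameterError("emd_threshold must be nonnegative")
    samples = experiment.samples
    batches = sorted(samples["batch"].astype(str).unique())
    if len(batches) < 2:
        raise ConfigurationError("batch diagnostics need at least two batches")
    rep_samples = samples[samples["is_replicate_reference"].astype(bool)]
    missing = [
        b for b in batches if b not in set(rep_samples["batch"].astype(str))
    ]
    if missing:
        raise ConfigurationError(
            f"batches without a replicate-reference sample: {missing}"
        )

    rep_ids = set(rep_samples["sample_id"].astype(str))
    cell_is_rep = np.isin(experiment.cell_sample_ids.astype(str), list(rep_ids))
    batch_of = samples.set_index(samples["sample_id"].astype(str))["batch"].astype(str)
    cell_batch = np.asarray(
        [batch_of[s] for s in experiment.cell_sample_ids.astype(str)], dtype=object
    )

    rows = []
    for marker in experiment.marker_names:
        col = experiment.marker_values(marker)
        for batch in batches:
            own = col[cell_is_rep & (cell_batch == batch)]
            ref = col[cell_is_rep & (cell_batch != batch)]
            emd = earth_movers_distance_1d(own, ref)
            shift = float(np.median(own) - np.median(ref))
            rows.append(
                {
                    "batch": batch,
                    "marker": marker,
                    "emd": emd,
                    "median_shift": shift,
                    "flagged": emd > emd_threshold,
                }
            )
    marker_table = pd.DataFrame(rows)

    replicate_exp = experiment.subset_cells(
        cell_is_rep, note="replicate cells for batch QC"
    )
    replicate_exp.samples = samples[
        samples["sample_id"].astype(str).isin(rep_ids)
    ].reset_index(drop=True)
    binarization = binarize(replicate_exp, matrix)
    annotation = classify_cells(binarization, matrix)
    pct = abundance_table(annotation, replicate_exp)
    pct["batch"] = [batch_of[s] for s in pct.index.astype(str)]
    proportions = pct.groupby("batch").mean()

    return BatchReport(
        marker_table=marker_table,
        proportions=proportions,
        emd_threshold=emd_threshold,
    )
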