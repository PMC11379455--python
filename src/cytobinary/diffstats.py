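"""Differential analysis of abundances and state-marker expression.

Per-sample features (percent lineage abundance, or median state-marker
intensity per lineage) are compared across study conditions with the
distribution-free two-branch scheme standard in cytometry: two groups get
a two-sided Mann-Whitney U test per feature; three or more groups get
Kruskal-Wallis with tie correction, and features passing the
Benjamini-Hochberg threshold get post hoc pairwise resolution by Dunn's
z-test (tie-corrected mean-rank differences) or pairwise Wilcoxon.
BH families: abundance features are corrected together across cell types;
state-marker features across (cell type x marker) within one comparison;
each feature's post hoc pairs form their own BH family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import CellAnnotation, abundance_table, population_counts
from .errors import ConfigurationError, DataError, ParameterError
from .experiment import Experiment

logger = logging.getLogger(__name__)

#: minimum cells per (sample, cell type) stratum for a meaningful median
DEFAULT_MIN_CELLS = 3

STAR_BANDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Figure-legend star bands: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for cut, stars in STAR_BANDS:
        if p < cut:
            return stars
    return "ns"


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one family)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def abundance_feature_table(
    annotation: CellAnnotation, experiment: Experiment
) -> pd.DataFrame:
    """Long table of per-sample percent abundances joined to conditions.

    Columns: sample_id, cell_type, feature, value (percent), group,
    n_cells. One row per (sample, cell type), "Unclassified" included.
    """
    pct = abundance_table(annotation, experiment)
    counts = population_counts(annotation, experiment).reindex(
        index=pct.index, columns=pct.columns, fill_value=0
    )
    long = pct.reset_index().melt(
        id_vars="sample_id", var_name="cell_type", value_name="value"
    )
    long["n_cells"] = counts.reset_index().melt(
        id_vars="sample_id", var_name="cell_type", value_name="n"
    )["n"]
    cond = experiment.samples.set_index(
        experiment.samples["sample_id"].astype(str)
    )["condition"]
    long["group"] = long["sample_id"].astype(str).map(cond)
    long["feature"] = long["cell_type"]
    return long[["sample_id", "cell_type", "feature", "value", "group", "n_cells"]]


def state_marker_table(
    experiment: Experiment,
    annotation: CellAnnotation,
    state_markers: list[str] | None = None,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """Median transformed intensity per (sample, cell type, state marker).

    Strata with fewer than ``min_cells`` cells get a missing value, never a
    zero, so sparse populations cannot masquerade as low expressors.
    Columns: sample_id, cell_type, marker, feature, value, group, n_cells.
    """
    if state_markers is None:
        state_markers = experiment.markers_of_class("state")
    if not state_markers:
        raise ConfigurationError(
            "no state markers: pass state_markers or set marker_class='state' "
            "in the panel"
        )
    missing = [m for m in state_markers if m not in experiment.marker_names]
    if missing:
        raise ConfigurationError(f"state markers absent from experiment: {missing}")
    cond = experiment.samples.set_index(
        experiment.samples["sample_id"].astype(str)
    )["condition"]
    df = pd.DataFrame(
        experiment.intensities[:, [experiment.marker_index(m) for m in state_markers]],
        columns=state_markers,
    )
    df["sample_id"] = experiment.cell_sample_ids.astype(str)
    df["cell_type"] = annotation.labels
    rows = []
    for (sample_id, cell_type), grp in df.groupby(
        ["sample_id", "cell_type"], sort=True
    ):
        n = len(grp)
        for marker in state_markers:
            rows.append(
                {
                    "sample_id": sample_id,
                    "cell_type": cell_type,
                    "marker": marker,
                    "feature": f"{cell_type}::{marker}",
                    "value": float(grp[marker].median()) if n >= min_cells else np.nan,
                    "group": cond.get(sample_id),
                    "n_cells": n,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TestResult:
    """One feature's test: statistic, raw and BH-adjusted p, post hoc pairs."""

    feature: str
    test_name: str
    statistic: float
    p_raw: float
    p_adj: float = np.nan
    posthoc: list[tuple[tuple[str, str], float, float, float]] = field(
        default_factory=list
    )  # ((group_a, group_b), statistic, p_raw, p_adj)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adj)


def _feature_groups(features: pd.DataFrame, feature: str) -> dict[str, np.ndarray]:
    sub = features[(features["feature"] == feature) & features["value"].notna()]
    return {
        str(g): grp["value"].to_numpy(dtype=float)
        for g, grp in sub.groupby("group", sort=True)
    }


def _results_frame(results: list[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "feature": r.feature,
                "test": r.test_name,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "stars": r.stars,
                "posthoc": "; ".join(
                    f"{a}|{b}: stat={s:.4g}, p_adj={padj:.4g}"
                    for (a, b), s, _, padj in r.posthoc
                ),
            }
        )
    return pd.DataFrame(rows)


def test_two_groups(
    features: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[TestResult], pd.DataFrame]:
    """Two-sided Mann-Whitney U per feature, BH across the feature family.

    Exact null enumeration when both groups have n <= 8 and no ties;
    midrank normal approximation with tie correction otherwise (scipy's
    default policy). Features with fewer than two non-missing samples in
    either group are skipped with a warning.
    """
    group_names = sorted({str(g) for g in features["group"].dropna().unique()})
    if len(group_names) != 2:
        raise ParameterError(
            f"test_two_groups needs exactly 2 groups, found {group_names}; "
            "use test_multi_groups for 3 or more"
        )
    results: list[TestResult] = []
    for feature in pd.unique(features["feature"]):
        groups = _feature_groups(features, feature)
        if any(len(groups.get(g, ())) < 2 for g in group_names):
            logger.warning("feature %r skipped: a group has <2 samples", feature)
            continue
        x, y = groups[group_names[0]], groups[group_names[1]]
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        results.append(
            TestResult(
                feature=str(feature),
                test_name="mann-whitney",
                statistic=float(res.statistic),
                p_raw=float(res.pvalue),
            )
        )
    adj = bh_adjust([r.p_raw for r in results])
    for r, p in zip(results, adj):
        r.p_adj = float(p)
    return results, _results_frame(results)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> list[tuple[tuple[str, str], float, float]]:
    """Dunn's pairwise z-tests after Kruskal-Wallis.

    All observations are ranked jointly with midranks; for groups i, j the
    statistic is z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    where T = sum(t^3 - t) / (12 (N - 1)) corrects for ties. Returns
    ((a, b), z, two-sided p) per pair; p-values are raw (the caller owns
    the BH family).
    """
    names = sorted(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [groups[g].size for g in names])
    mean_ranks = {
        g: float(ranks[offsets[i] : offsets[i + 1]].mean())
        for i, g in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    out = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / groups[a].size + 1.0 / groups[b].size))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        out.append(((a, b), float(z), float(min(p, 1.0))))
    return out


def pairwise_wilcoxon_posthoc(
    groups: dict[str, np.ndarray],
) -> list[tuple[tuple[str, str], float, float]]:
    """All pairwise two-sided Mann-Whitney tests (raw p-values)."""
    out = []
    for a, b in itertools.combinations(sorted(groups), 2):
        res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        out.append(((a, b), float(res.statistic), float(res.pvalue)))
    return out


def test_multi_groups(
    features: pd.DataFrame,
    posthoc: str = "dunn",
    alpha: float = 0.05,
) -> tuple[list[TestResult], pd.DataFrame]:
    """Kruskal-Wallis per feature (>= 3 groups), BH across features, then
    post hoc pairwise tests for features with adjusted p < alpha.

    ``posthoc`` selects "dunn" (default) or "wilcoxon"; each significant
    feature's pairwise p-values form their own BH family. Groups with
    fewer than two non-missing samples drop the feature with a warning.
    """
    if posthoc not in ("dunn", "wilcoxon"):
        raise ParameterError(f"posthoc must be 'dunn' or 'wilcoxon', got {posthoc!r}")
    group_names = sorted({str(g) for g in features["group"].dropna().unique()})
    if len(group_names) < 3:
        raise ParameterError(
            f"test_multi_groups needs >= 3 groups, found {group_names}; "
            "use test_two_groups for 2"
        )
    results: list[TestResult] = []
    kept_groups: dict[str, dict[str, np.ndarray]] = {}
    for feature in pd.unique(features["feature"]):
        groups = _feature_groups(features, feature)
        if len(groups) < 3 or any(v.size < 2 for v in groups.values()):
            logger.warning(
                "feature %r skipped: needs >=3 groups with >=2 samples each", feature
            )
            continue
        pooled = np.concatenate(list(groups.values()))
        if np.ptp(pooled) == 0:  # scipy.kruskal rejects all-identical input
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups.values())
        results.append(
            TestResult(
                feature=str(feature),
                test_name="kruskal-wallis",
                statistic=float(h),
                p_raw=float(p),
            )
        )
        kept_groups[str(feature)] = groups
    adj = bh_adjust([r.p_raw for r in results])
    for r, p in zip(results, adj):
        r.p_adj = float(p)
        if r.p_adj < alpha:
            fn = dunn_posthoc if posthoc == "dunn" else pairwise_wilcoxon_posthoc
            pairs = fn(kept_groups[r.feature])
            pair_adj = bh_adjust([pr for _, _, pr in pairs])
            r.posthoc = [
                (pair, stat, p_raw, float(p_a))
                for (pair, stat, p_raw), p_a in zip(pairs, pair_adj)
            ]
    return results, _results_frame(results)


def run_differential(
    features: pd.DataFrame, posthoc: str = "dunn", alpha: float = 0.05
) -> tuple[list[TestResult], pd.DataFrame]:
    """Route on the number of study groups: 2 -> Mann-Whitney branch,
    >= 3 -> Kruskal-Wallis branch."""
    groups = {str(g) for g in features["group"].dropna().unique()}
    if len(groups) < 2:
        raise ParameterError("differential analysis needs at least two groups")
    if len(groups) == 2:
        return test_two_groups(features, alpha=alpha)
    return test_multi_groups(features, posthoc=posthoc, alpha=alpha)
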