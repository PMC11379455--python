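"""Differential testing: MW/KW branches, BH correction, Dunn post hoc."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytobinary.classify import CellAnnotation, binarize, classify_cells
from cytobinary.diffstats import test_multi_groups as kw_branch
from cytobinary.diffstats import test_two_groups as mw_branch
from cytobinary.diffstats import (
    abundance_feature_table,
    bh_adjust,
    dunn_posthoc,
    run_differential,
    significance_stars,
    state_marker_table,
)
from cytobinary.errors import ConfigurationError, ParameterError


def _features(values_by_group, feature="f1"):
    rows = []
    for group, values in values_by_group.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "sample_id": f"{group}{i}",
                    "feature": feature,
                    "value": v,
                    "group": group,
                    "n_cells": 100,
                }
            )
    return pd.DataFrame(rows)


class TestTwoGroups:
    def test_identical_groups_u_and_p(self):
        # identical value multisets: U = n1*n2/2, p = 1
        feats = _features({"g1": [1, 2, 3, 4], "g2": [1, 2, 3, 4]})
        results, _ = mw_branch(feats)
        assert results[0].statistic == pytest.approx(8.0)
        assert results[0].p_raw == pytest.approx(1.0)

    def test_exact_enumeration_small_samples(self):
        # complete separation of 3 vs 3: one-sided tail 1/20 -> two-sided 0.1
        feats = _features({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        results, _ = mw_branch(feats)
        assert results[0].p_raw == pytest.approx(0.1)

    def test_three_groups_routed_away(self):
        feats = pd.concat(
            [
                _features({"g1": [1, 2], "g2": [3, 4]}),
                _features({"g3": [5, 6]}),
            ]
        )
        with pytest.raises(ParameterError, match="exactly 2"):
            mw_branch(feats)

    def test_bh_applied_across_feature_family(self, rng):
        frames = []
        for i, shift in enumerate([0.0, 0.0, 5.0]):
            frames.append(
                _features(
                    {
                        "g1": rng.normal(0, 1, 8),
                        "g2": rng.normal(shift, 1, 8),
                    },
                    feature=f"f{i}",
                )
            )
        results, frame = mw_branch(pd.concat(frames))
        raw = np.array([r.p_raw for r in results])
        np.testing.assert_allclose(
            [r.p_adj for r in results], bh_adjust(raw), atol=1e-12
        )
        assert (frame["p_adj"] >= frame["p_raw"] - 1e-15).all()


class TestBH:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_bruteforce_step_up(self, p_values):
        def brute(p):
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * m / rank)
                adj[idx] = running
            return adj

        np.testing.assert_allclose(
            bh_adjust(p_values), brute(np.asarray(p_values)), atol=1e-12
        )


class TestMultiGroups:
    def test_kruskal_hand_computed_h(self):
        # {1,2},{3,4},{5,6}: H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 3*7 = 32/7
        feats = _features({"g1": [1, 2], "g2": [3, 4], "g3": [5, 6]})
        results, _ = kw_branch(feats, alpha=1.1)
        assert results[0].statistic == pytest.approx(32 / 7)

    def test_two_groups_routed_away(self):
        feats = _features({"g1": [1, 2], "g2": [3, 4]})
        with pytest.raises(ParameterError, match=">= 3"):
            kw_branch(feats)

    def test_posthoc_isolates_shifted_pair(self, rng):
        feats = _features(
            {
                "a": rng.normal(0, 1, 10),
                "b": rng.normal(0, 1, 10),
                "c": rng.normal(3, 1, 10),  # 3 SD shift
            }
        )
        results, _ = kw_branch(feats, posthoc="dunn")
        r = results[0]
        assert r.p_adj < 0.05
        pair_p = {pair: p_adj for pair, _, _, p_adj in r.posthoc}
        assert pair_p[("a", "c")] < 0.05
        assert pair_p[("b", "c")] < 0.05
        assert pair_p[("a", "b")] > 0.05

    def test_wilcoxon_posthoc_available(self, rng):
        feats = _features(
            {
                "a": rng.normal(0, 1, 10),
                "b": rng.normal(0, 1, 10),
                "c": rng.normal(4, 1, 10),
            }
        )
        results, _ = kw_branch(feats, posthoc="wilcoxon")
        assert results[0].posthoc  # pairs populated for the significant feature

    def test_results_invariant_to_sample_order_and_group_names(self, rng):
        feats = _features(
            {"a": rng.normal(0, 1, 6), "b": rng.normal(1, 1, 6), "c": rng.normal(2, 1, 6)}
        )
        shuffled = feats.sample(frac=1.0, random_state=3).reset_index(drop=True)
        renamed = feats.assign(
            group=feats["group"].map({"a": "zz", "b": "yy", "c": "xx"})
        )
        h0 = kw_branch(feats)[0][0].statistic
        assert kw_branch(shuffled)[0][0].statistic == pytest.approx(h0)
        assert kw_branch(renamed)[0][0].statistic == pytest.approx(h0)


class TestDunn:
    def test_frozen_hand_computation_no_ties(self):
        """z = (Rbar_i - Rbar_j) / sqrt(N(N+1)/12 * (1/n_i + 1/n_j))."""
        groups = {
            "A": np.array([1.0, 2.0, 3.0]),
            "B": np.array([4.0, 5.0, 6.0]),
            "C": np.array([7.0, 8.0, 9.0]),
        }
        out = {pair: (z, p) for pair, z, p in dunn_posthoc(groups)}
        assert out[("A", "B")][0] == pytest.approx(-1.3416407865, abs=1e-9)
        assert out[("A", "B")][1] == pytest.approx(0.1797124949, abs=1e-9)
        assert out[("A", "C")][0] == pytest.approx(-2.6832815730, abs=1e-9)
        assert out[("A", "C")][1] == pytest.approx(0.0072903581, abs=1e-9)

    def test_tie_correction_reduces_variance(self):
        z_no_ties = dunn_posthoc(
            {"A": np.array([1.0, 2.0]), "B": np.array([3.0, 4.0])}
        )[0][1]
        z_with_ties = dunn_posthoc(
            {"A": np.array([1.0, 1.0]), "B": np.array([3.0, 3.0])}
        )[0][1]
        # same mean-rank gap, smaller variance under ties -> larger |z|
        assert abs(z_with_ties) > abs(z_no_ties)


class TestFeatureTables:
    def test_abundance_features_join_conditions(
        self, small_experiment, small_matrix
    ):
        experiment, _ = small_experiment
        ann = classify_cells(binarize(experiment, small_matrix), small_matrix)
        feats = abundance_feature_table(ann, experiment)
        assert set(feats["group"]) == {"healthy", "mild", "severe"}
        per_sample = feats.groupby("sample_id")["value"].sum()
        np.testing.assert_allclose(per_sample, 100.0, atol=1e-9)

    def test_small_stratum_is_missing_not_zero(self, small_experiment):
        experiment, _ = small_experiment
        labels = np.full(experiment.n_cells, "bulk", dtype=object)
        labels[0] = "rare"  # a single cell in one sample
        ann = CellAnnotation(labels, np.ones(experiment.n_cells, dtype=int))
        feats = state_marker_table(experiment, ann, min_cells=3)
        rare = feats[feats["cell_type"] == "rare"]
        assert rare["value"].isna().all()
        assert (rare["n_cells"] == 1).all()

    def test_medians_match_direct_computation(self, small_experiment, rng):
        experiment, _ = small_experiment
        labels = rng.choice(["p", "q"], size=experiment.n_cells).astype(object)
        ann = CellAnnotation(labels, np.ones(experiment.n_cells, dtype=int))
        feats = state_marker_table(experiment, ann, state_markers=["CD25"])
        sid = str(experiment.samples["sample_id"].iloc[0])
        mask = (experiment.cell_sample_ids == sid) & (labels == "p")
        expected = np.median(experiment.marker_values("CD25")[mask])
        got = feats[
            (feats["sample_id"] == sid)
            & (feats["cell_type"] == "p")
            & (feats["marker"] == "CD25")
        ]["value"].iloc[0]
        assert got == pytest.approx(expected)

    def test_no_state_markers_is_configuration_error(self, small_experiment):
        experiment, _ = small_experiment
        ann = CellAnnotation(
            np.full(experiment.n_cells, "x", dtype=object),
            np.ones(experiment.n_cells, dtype=int),
        )
        with pytest.raises(ConfigurationError):
            state_marker_table(experiment, ann, state_markers=[])


def test_routing_on_group_count(rng):
    two = _features({"g1": rng.normal(size=5), "g2": rng.normal(size=5)})
    results, _ = run_differential(two)
    assert results[0].test_name == "mann-whitney"
    three = _features(
        {"g1": rng.normal(size=5), "g2": rng.normal(size=5), "g3": rng.normal(size=5)}
    )
    results, _ = run_differential(three)
    assert results[0].test_name == "kruskal-wallis"


def test_significance_star_bands():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.00005) == "****"
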