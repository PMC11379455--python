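"""Binarization, signature matching, abundance and extraction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cytobinary.classify import (
    BinarizationResult,
    abundance_table,
    binarize,
    classify_cells,
    extract_population,
    population_counts,
)
from cytobinary.errors import (
    ConfigurationError,
    ParameterError,
    PopulationLookupError,
)
from cytobinary.signatures import ClassificationMatrix
from cytobinary.simulate import default_spec, generate_experiment


def _binarization_from_bits(bits: np.ndarray, markers) -> BinarizationResult:
    bits = np.asarray(bits, dtype=bool)
    return BinarizationResult(
        thresholds=pd.DataFrame(
            0.5, index=["pooled"], columns=list(markers), dtype=float
        ),
        binary=bits,
        markers=list(markers),
        degenerate=pd.Series(False, index=list(markers)),
        positive_fraction=pd.Series(bits.mean(axis=0), index=list(markers)),
    )


class TestClassifyCells:
    def test_forced_assignments(self, tiny_matrix):
        bits = np.array([[1, 0], [0, 1], [1, 1], [0, 0]], dtype=bool)
        ann = classify_cells(
            _binarization_from_bits(bits, ["CD3", "CD19"]), tiny_matrix
        )
        assert list(ann.labels) == ["T", "B", "Unclassified", "Unclassified"]
        assert list(ann.match_counts) == [1, 1, 0, 0]

    def test_unclassified_iff_zero_matches(self, tiny_matrix, rng):
        bits = rng.random((200, 2)) < 0.5
        ann = classify_cells(
            _binarization_from_bits(bits, ["CD3", "CD19"]), tiny_matrix
        )
        np.testing.assert_array_equal(
            ann.match_counts == 0, ann.labels == "Unclassified"
        )

    def test_enumeration_oracle_with_tie_break(self):
        """All 2^4 signatures vs literal rule application, including the
        most-specific-then-row-order resolution."""
        markers = ["m1", "m2", "m3", "m4"]
        entries = pd.DataFrame(
            {
                "m1": ["+", "+", "A"],
                "m2": ["A", "-", "A"],
                "m3": ["A", "A", "+"],
                "m4": ["A", "A", "A"],
            },
            index=["broad", "narrow", "third"],
        )
        matrix = ClassificationMatrix(entries)
        bits = np.array(
            list(itertools.product([False, True], repeat=4)), dtype=bool
        )
        ann = classify_cells(_binarization_from_bits(bits, markers), matrix)

        specificity = (entries != "A").sum(axis=1)
        for cell_bits, label, count in zip(bits, ann.labels, ann.match_counts):
            matched = [
                name
                for name, row in entries.iterrows()
                if all(
                    s == "A" or (s == "+") == b
                    for s, b in zip(row, cell_bits)
                )
            ]
            assert count == len(matched)
            if not matched:
                assert label == "Unclassified"
            else:
                best = max(specificity[m] for m in matched)
                expected = next(
                    m for m in entries.index
                    if m in matched and specificity[m] == best
                )
                assert label == expected

    def test_invariant_to_marker_column_order(self, small_experiment, small_spec):
        experiment, _ = small_experiment
        matrix = small_spec.classification_matrix()
        shuffled = ClassificationMatrix(
            matrix.entries[list(reversed(matrix.markers))]
        )
        a = classify_cells(binarize(experiment, matrix), matrix)
        b = classify_cells(binarize(experiment, shuffled), shuffled)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_deterministic_across_runs(self, small_experiment, small_matrix):
        experiment, _ = small_experiment
        a = classify_cells(binarize(experiment, small_matrix), small_matrix)
        b = classify_cells(binarize(experiment, small_matrix), small_matrix)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestBinarize:
    def test_untransformed_experiment_rejected(self, small_spec, small_matrix):
        experiment, _ = generate_experiment(small_spec)
        object.__setattr__(experiment, "transformed", False)
        with pytest.raises(ParameterError, match="transform"):
            binarize(experiment, small_matrix)
        object.__setattr__(experiment, "transformed", True)

    def test_constant_marker_flagged_degenerate(self, small_experiment, small_matrix):
        experiment, _ = small_experiment
        frozen = experiment.subset_cells(np.ones(experiment.n_cells, dtype=bool))
        frozen.intensities = frozen.intensities.copy()
        idx = frozen.marker_index("CD3")
        frozen.intensities[:, idx] = 1.5
        result = binarize(frozen, small_matrix)
        assert bool(result.degenerate["CD3"])
        assert not result.column("CD3").any()

    def test_threshold_between_modes_and_positive_fraction(self, small_spec):
        experiment, truth = generate_experiment(small_spec)
        matrix = small_spec.classification_matrix()
        result = binarize(experiment, matrix)
        thr = float(result.thresholds.loc["pooled", "CD19"])
        assert 0.3 < thr < 3.0  # strictly between the two modes
        # expected positive fraction from the generative mixture:
        # '+' -> 1-flip, '-' -> flip, 'A' -> the marker's mixing weight
        marker = next(m for m in small_spec.markers if m.name == "CD19")
        per_type = {
            ct.name: {
                "+": 1 - small_spec.noise_flip,
                "-": small_spec.noise_flip,
                "A": marker.mix_weight,
            }[ct.signature.get("CD19", "A")]
            for ct in small_spec.cell_types
        }
        shares = pd.Series(truth).value_counts(normalize=True)
        expected = sum(per_type[t] * shares[t] for t in per_type)
        n = experiment.n_cells
        sd = np.sqrt(expected * (1 - expected) / n)
        assert result.positive_fraction["CD19"] == pytest.approx(
            expected, abs=3 * sd + 0.02  # binarization boundary leak
        )

    def test_missing_marker_is_configuration_error(self, small_experiment):
        experiment, _ = small_experiment
        matrix = ClassificationMatrix(
            pd.DataFrame({"NotAMarker": ["+", "-"]}, index=["x", "y"])
        )
        with pytest.raises(ConfigurationError, match="NotAMarker"):
            binarize(experiment, matrix)

    def test_all_any_marker_column_excluded(self, small_experiment):
        experiment, _ = small_experiment
        matrix = ClassificationMatrix(
            pd.DataFrame(
                {"CD3": ["+", "-"], "CD19": ["A", "A"]}, index=["T", "notT"]
            )
        )
        result = binarize(experiment, matrix)
        assert result.markers == ["CD3"]

    def test_per_sample_scope_fits_one_threshold_per_sample(
        self, small_experiment, small_matrix
    ):
        experiment, _ = small_experiment
        result = binarize(experiment, small_matrix, scope="per_sample")
        assert list(result.thresholds.index) == list(
            experiment.samples["sample_id"]
        )


class TestAbundance:
    def test_single_label_gives_100_percent(self, small_experiment):
        experiment, _ = small_experiment
        from cytobinary.classify import CellAnnotation

        ann = CellAnnotation(
            labels=np.full(experiment.n_cells, "Only", dtype=object),
            match_counts=np.ones(experiment.n_cells, dtype=int),
        )
        table = abundance_table(ann, experiment)
        assert (table["Only"] == 100.0).all()

    def test_rows_sum_to_100(self, small_experiment, small_matrix):
        experiment, _ = small_experiment
        ann = classify_cells(binarize(experiment, small_matrix), small_matrix)
        table = abundance_table(ann, experiment)
        np.testing.assert_allclose(table.sum(axis=1), 100.0, atol=1e-9)
        assert "Unclassified" in table.columns

    def test_matches_direct_tally(self, small_experiment, rng):
        experiment, _ = small_experiment
        from cytobinary.classify import CellAnnotation

        labels = rng.choice(["a", "b", "c"], size=experiment.n_cells).astype(object)
        ann = CellAnnotation(labels, np.ones(experiment.n_cells, dtype=int))
        table = abundance_table(ann, experiment)
        for sid in experiment.samples["sample_id"]:
            in_sample = experiment.cell_sample_ids == sid
            for lab in ["a", "b", "c"]:
                expected = 100 * (labels[in_sample] == lab).mean()
                assert table.loc[sid, lab] == pytest.approx(expected)


class TestExtraction:
    def test_extract_all_cells_is_identity_size(self, small_experiment):
        experiment, _ = small_experiment
        from cytobinary.classify import CellAnnotation

        ann = CellAnnotation(
            np.full(experiment.n_cells, "All", dtype=object),
            np.ones(experiment.n_cells, dtype=int),
        )
        subset = extract_population(experiment, ann, "All")
        assert subset.n_cells == experiment.n_cells

    def test_missing_label_lists_available(self, small_experiment, small_matrix):
        experiment, _ = small_experiment
        ann = classify_cells(binarize(experiment, small_matrix), small_matrix)
        with pytest.raises(PopulationLookupError, match="available labels"):
            extract_population(experiment, ann, "Platelets")

    def test_subset_sizes_match_abundance_counts(
        self, small_experiment, small_matrix
    ):
        experiment, _ = small_experiment
        ann = classify_cells(binarize(experiment, small_matrix), small_matrix)
        counts = population_counts(ann, experiment)
        for cell_type in ("B cells", "NK cells"):
            subset = extract_population(experiment, ann, cell_type)
            assert subset.n_cells == counts[cell_type].sum()
            # metadata preserved
            pd.testing.assert_frame_equal(subset.samples, experiment.samples)
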