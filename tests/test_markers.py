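"""Per-mask intensity aggregation, normalization, and anchored thresholds."""
import numpy as np
import pandas as pd
import pytest

from scaffoldquant.errors import ConfigurationError, DegenerateDistributionError
from scaffoldquant.markers import (
    LOG_EPS,
    add_normalized_intensities,
    aggregate_mask_intensities,
    classify_cells,
    compute_percentile_threshold,
    compute_thresholds,
    normalize_log,
)
from scaffoldquant.stacks import ImageStack, LabelVolume


def _toy_stack_and_labels(rng, shape=(16, 16, 16), n_masks=5):
    data = rng.uniform(0, 100, size=(3, *shape))
    stack = ImageStack(data, ("nuclei", "CD19", "CD3"))
    labels = np.zeros(shape, dtype=np.int32)
    flat = rng.choice(np.prod(shape), size=n_masks * 20, replace=False)
    labels.ravel()[flat] = rng.integers(1, n_masks + 1, size=flat.size)
    return stack, LabelVolume(labels)


class TestAggregate:
    def test_three_voxel_mask_total(self):
        data = np.zeros((2, 1, 1, 3))
        data[1, 0, 0, :] = [1.0, 2.0, 3.0]
        stack = ImageStack(data, ("nuclei", "CD3"))
        labels = LabelVolume(np.ones((1, 1, 3), dtype=np.int32))
        table = aggregate_mask_intensities(stack, labels, channels=("CD3",))
        assert table.loc[0, "total_CD3"] == pytest.approx(6.0)
        assert table.loc[0, "volume_voxels"] == 3

    def test_matches_per_voxel_loop_oracle(self, rng):
        stack, labels = _toy_stack_and_labels(rng)
        table = aggregate_mask_intensities(stack, labels, channels=("CD19", "CD3"))
        for _, row in table.iterrows():
            mask = labels.labels == row["cell_id"]
            for c in ("CD19", "CD3"):
                expected = float(stack.channel(c)[mask].sum())
                assert row[f"total_{c}"] == pytest.approx(expected, abs=1e-9)

    def test_empty_labels_warn_and_return_empty(self, rng):
        stack, _ = _toy_stack_and_labels(rng)
        empty = LabelVolume(np.zeros((16, 16, 16), dtype=np.int32))
        with pytest.warns(UserWarning, match="empty"):
            table = aggregate_mask_intensities(stack, empty, channels=("CD3",))
        assert table.empty

    def test_shape_mismatch_rejected(self, rng):
        stack, _ = _toy_stack_and_labels(rng)
        with pytest.raises(ConfigurationError):
            aggregate_mask_intensities(stack, LabelVolume(np.zeros((4, 4, 4), dtype=np.int32)))


class TestNormalizeLog:
    def test_stated_transform(self):
        out = normalize_log(np.array([2.0, 4.0, 6.0]))
        expected = np.log(np.array([0.0, 0.5, 1.0]) + LOG_EPS)
        assert np.allclose(out, expected)

    def test_rank_order_preserved(self, rng):
        values = rng.uniform(0, 1000, size=200)
        out = normalize_log(values)
        assert np.array_equal(np.argsort(values), np.argsort(out))

    def test_affine_invariance(self, rng):
        values = rng.uniform(10, 500, size=50)
        assert np.allclose(normalize_log(values), normalize_log(3.7 * values + 11.0))

    def test_identical_values_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            normalize_log(np.full(10, 3.0))


def _anchors(fractions, group="G1", marker="CD19"):
    return pd.DataFrame(
        [
            dict(group=group, condition=c, marker=marker, positive_fraction=f, replicate_id=i)
            for i, (c, f) in enumerate(fractions)
        ]
    )


class TestPercentileThreshold:
    def test_anchor_mean_and_percentile_formula(self):
        anchors = _anchors([("mock", 30.0), ("car", 20.0)])
        entry = compute_percentile_threshold(np.arange(1.0, 101.0), anchors, "G1", "CD19")
        assert entry.anchor_fraction_used == pytest.approx(25.0)
        assert entry.percentile_n == pytest.approx(75.0)
        assert entry.threshold_value == pytest.approx(75.25)  # linear interpolation

    def test_zero_anchor_yields_no_positives(self):
        anchors = _anchors([("mock", 0.0), ("car", 0.0)])
        values = np.arange(1.0, 101.0)
        entry = compute_percentile_threshold(values, anchors, "G1", "CD19")
        assert entry.threshold_value == pytest.approx(values.max())
        assert (values > entry.threshold_value).sum() == 0  # strict inequality

    def test_missing_marker_rows_rejected(self):
        anchors = _anchors([("mock", 30.0)])
        with pytest.raises(ConfigurationError, match="CD3"):
            compute_percentile_threshold(np.arange(10.0), anchors, "G1", "CD3")


def _cell_table(rng, n=1000, pos_fraction=0.3):
    """Tie-free two-channel table with known positives (last fraction by rank)."""
    cd19 = rng.permutation(np.linspace(1, 2, n))
    cd3 = rng.permutation(np.linspace(5, 9, n))
    return pd.DataFrame(
        dict(
            stack_id="s1",
            patient_id="P1",
            group="G1",
            condition="car",
            cell_id=np.arange(1, n + 1),
            total_CD19=cd19,
            total_CD3=cd3,
        )
    )


class TestClassify:
    def test_call_combinations_map_to_classes(self):
        table = pd.DataFrame(
            dict(
                patient_id="P1",
                group="G1",
                cell_id=[1, 2, 3, 4],
                normlog_CD19=[1.0, 1.0, -1.0, -1.0],
                normlog_CD3=[1.0, -1.0, 1.0, -1.0],
            )
        )
        thresholds = pd.DataFrame(
            [
                dict(patient_id="P1", channel="CD19", anchor_fraction_used=50, percentile_n=50, threshold_value=0.0),
                dict(patient_id="P1", channel="CD3", anchor_fraction_used=50, percentile_n=50, threshold_value=0.0),
            ]
        )
        out = classify_cells(table, thresholds)
        assert list(out["cell_class"]) == ["coloc", "bcell_only", "tcell_only", "stromal"]

    def test_value_at_threshold_is_negative_call(self):
        table = pd.DataFrame(
            dict(patient_id="P1", group="G1", cell_id=[1], normlog_CD19=[0.0], normlog_CD3=[0.0])
        )
        thresholds = pd.DataFrame(
            [
                dict(patient_id="P1", channel="CD19", anchor_fraction_used=50, percentile_n=50, threshold_value=0.0),
                dict(patient_id="P1", channel="CD3", anchor_fraction_used=50, percentile_n=50, threshold_value=0.0),
            ]
        )
        out = classify_cells(table, thresholds)
        assert out.loc[0, "cell_class"] == "stromal"

    def test_missing_threshold_lists_keys(self):
        table = pd.DataFrame(
            dict(patient_id=["P1", "P2"], group="G1", cell_id=[1, 2], normlog_CD19=[0.0, 1.0])
        )
        thresholds = pd.DataFrame(
            [dict(patient_id="P1", channel="CD19", anchor_fraction_used=50, percentile_n=50, threshold_value=0.0)]
        )
        with pytest.raises(ConfigurationError, match="P2"):
            classify_cells(table, thresholds)

    @pytest.mark.parametrize("anchor", [5.0, 25.0, 50.0, 75.0, 95.0])
    def test_calibration_identity(self, rng, anchor):
        """Called-positive fraction matches the anchor on tie-free values."""
        table = add_normalized_intensities(_cell_table(rng), channels=("CD19", "CD3"))
        anchors = pd.concat(
            [_anchors([("mock", anchor), ("car", anchor)], marker=m) for m in ("CD19", "CD3")]
        )
        cells = classify_cells(table, compute_thresholds(table, anchors))
        for c in ("CD19", "CD3"):
            assert abs(cells[f"call_{c}"].mean() * 100 - anchor) <= 1.0

    def test_classes_partition_the_table(self, rng):
        table = add_normalized_intensities(_cell_table(rng, n=300), channels=("CD19", "CD3"))
        anchors = pd.concat(
            [_anchors([("car", 40.0)], marker=m) for m in ("CD19", "CD3")]
        )
        cells = classify_cells(table, compute_thresholds(table, anchors))
        counts = cells["cell_class"].value_counts()
        assert counts.sum() == len(cells)
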