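"""Synthetic scaffold generator: placement contracts, truth semantics,
anchor and assay table generation."""
import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from scaffoldquant.errors import ConfigurationError, PlacementError
from scaffoldquant.simulate import (
    AssaySimConfig,
    GroundTruth,
    generate_anchor_table,
    generate_assay_tables,
    generate_scaffold_stack,
)

from conftest import tiny_config

STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class TestScaffoldStack:
    def test_seeded_determinism(self):
        a = generate_scaffold_stack(tiny_config(seed=7))
        b = generate_scaffold_stack(tiny_config(seed=7))
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].labels, b[1].labels)
        assert a[2].cells.equals(b[2].cells)

    def test_no_tcells_means_no_coloc(self):
        _, _, truth = generate_scaffold_stack(tiny_config(n_tcell=0, seed=1))
        assert not truth.cells["cell_class"].eq("tcell").any()
        assert not truth.cells["coloc_flag"].any()

    @pytest.mark.parametrize("n_bcell,coloc_fraction", [(12, 0.25), (10, 0.3), (8, 0.0)])
    def test_exact_coloc_count(self, n_bcell, coloc_fraction):
        cfg = tiny_config(n_bcell=n_bcell, n_tcell=n_bcell, coloc_fraction=coloc_fraction, seed=2)
        _, _, truth = generate_scaffold_stack(cfg)
        assert int(truth.cells["coloc_flag"].sum()) == round(coloc_fraction * n_bcell)

    def test_labels_match_truth_and_masks_connected(self, tiny_sim):
        _, _, labels, truth = tiny_sim
        assert set(labels.ids) == set(truth.cells["cell_id"])
        for cell_id in labels.ids:
            _, n = ndimage.label(labels.labels == cell_id, structure=STRUCT26)
            assert n == 1

    def test_exactly_flagged_bcells_touch_a_tcell(self, tiny_sim):
        _, _, labels, truth = tiny_sim
        t_ids = truth.cells.query("cell_class == 'tcell'")["cell_id"].to_numpy()
        t_dilated = ndimage.binary_dilation(np.isin(labels.labels, t_ids), structure=STRUCT26)
        bcells = truth.cells.query("cell_class == 'bcell'")
        touches = np.array(
            [bool((t_dilated & (labels.labels == cid)).any()) for cid in bcells["cell_id"]]
        )
        assert (touches == bcells["coloc_flag"].to_numpy()).all()

    def test_region_partition_and_fraction_sums(self, tiny_sim):
        _, _, _, truth = tiny_sim
        assert truth.cells["region"].isin(["core", "periphery"]).all()
        for region in (None, "core", "periphery"):
            frac = truth.class_fractions(region)
            if frac.sum() > 0:  # region may be empty in a tiny volume
                assert frac.sum() == pytest.approx(1.0)

    def test_positive_masks_brighter_than_negative_at_zero_noise(self):
        cfg = tiny_config(noise_sd=0.0, seed=3)
        stack, labels, truth = generate_scaffold_stack(cfg)
        for marker in ("CD90", "CD19", "CD3", "CAR"):
            totals = ndimage.sum_labels(
                stack.channel(marker), labels.labels, index=truth.cells["cell_id"].to_numpy()
            )
            pos = truth.marker_positive(marker).to_numpy()
            if pos.any() and (~pos).any():
                assert totals[pos].mean() > totals[~pos].mean()

    def test_overfull_volume_raises_placement_error(self):
        cfg = tiny_config(volume_shape=(24, 24, 24), n_stromal=2, n_bcell=60, n_tcell=0, seed=0)
        with pytest.raises(PlacementError, match="bcell"):
            generate_scaffold_stack(cfg)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_scaffold_stack(tiny_config(coloc_fraction=1.5))


def _fabricated_truth(n_tcell, n_other):
    """Minimal truth table with a known CD3 fraction (no geometry needed)."""
    rows = []
    for i in range(n_tcell + n_other):
        rows.append(
            dict(
                cell_id=i + 1,
                cell_class="tcell" if i < n_tcell else "stromal",
                car_flag=False,
                coloc_flag=False,
                partner_id=-1,
                region="core",
                centroid_z=0.0,
                centroid_y=0.0,
                centroid_x=0.0,
            )
        )
    return GroundTruth(pd.DataFrame(rows))


class TestAnchorTable:
    def test_zero_cv_reproduces_truth(self, tiny_sim):
        _, _, _, truth = tiny_sim
        anchors = generate_anchor_table(truth, cv=0.0, n_replicates=3, seed=0)
        for marker in ("CD3", "CD19"):
            expected = 100.0 * truth.marker_fraction(marker)
            got = anchors.loc[anchors["marker"] == marker, "positive_fraction"]
            assert np.allclose(got, expected)

    def test_noisy_replicate_mean_close_to_truth(self):
        truth = _fabricated_truth(n_tcell=20, n_other=80)  # CD3 fraction 20%
        anchors = generate_anchor_table(truth, cv=0.1, n_replicates=50, seed=0)
        cd3 = anchors.loc[anchors["marker"] == "CD3", "positive_fraction"]
        assert abs(cd3.mean() - 20.0) < 3.0

    def test_single_replicate_reproducible(self, tiny_sim):
        _, _, _, truth = tiny_sim
        a = generate_anchor_table(truth, cv=0.2, n_replicates=1, seed=9)
        b = generate_anchor_table(truth, cv=0.2, n_replicates=1, seed=9)
        assert a.equals(b)

    def test_bad_parameters_rejected(self, tiny_sim):
        _, _, _, truth = tiny_sim
        with pytest.raises(ConfigurationError):
            generate_anchor_table(truth, cv=-0.1)
        with pytest.raises(ConfigurationError):
            generate_anchor_table(truth, n_replicates=0)


class TestAssayTables:
    def test_zero_lysis_equals_target_alone(self):
        cfg = AssaySimConfig(car_lysis={(g, r): 0.0 for g in ("CLL", "ALL") for r in ("periphery", "core")})
        assays = generate_assay_tables(cfg, seed=0)
        v = assays.viability.pivot_table(index=["group", "region"], columns="condition", values="percent_live")
        assert np.allclose(v["car"], v["target_alone"])

    def test_specified_lysis_arithmetic(self):
        cfg = AssaySimConfig(
            target_alone_live=80.0,
            car_lysis={(g, r): 0.5 for g in ("CLL", "ALL") for r in ("periphery", "core")},
        )
        assays = generate_assay_tables(cfg, seed=0)
        car = assays.viability.query("condition == 'car'")["percent_live"]
        assert np.allclose(car, 40.0)

    def test_basal_trace_deterministic(self):
        a = generate_assay_tables(AssaySimConfig(), seed=4).basal
        b = generate_assay_tables(AssaySimConfig(), seed=4).basal
        assert a.equals(b)

    def test_lysis_above_one_rejected(self):
        cfg = AssaySimConfig(car_lysis={(g, r): 1.2 for g in ("CLL", "ALL") for r in ("periphery", "core")})
        with pytest.raises(ConfigurationError):
            generate_assay_tables(cfg)
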