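"""Composition summaries, per-patient aggregation, and test designs."""
import numpy as np
import pandas as pd
import pytest

from scaffoldquant.errors import DesignError
from scaffoldquant.spatial import (
    aggregate_per_patient,
    assign_region,
    compare_conditions,
    composition_summary,
)


def _cells(classes, stack="s1", patient="P1", group="G1"):
    return pd.DataFrame(
        dict(
            stack_id=stack,
            patient_id=patient,
            group=group,
            cell_id=np.arange(1, len(classes) + 1),
            cell_class=classes,
        )
    )


class TestComposition:
    def test_counting_example(self):
        cells = _cells(["stromal"] * 4 + ["bcell_only"] * 3 + ["tcell_only"] * 2 + ["coloc"])
        out = composition_summary(cells, by=("stack_id",))
        row = out.iloc[0]
        assert (row[["fraction_stromal", "fraction_bcell_only", "fraction_tcell_only", "fraction_coloc"]]
                == [0.4, 0.3, 0.2, 0.1]).all()
        assert row["coloc_of_b"] == pytest.approx(0.25)
        assert row["n_cells"] == 10

    def test_fractions_are_probability_vector(self, rng):
        classes = rng.choice(["stromal", "bcell_only", "tcell_only", "coloc"], size=200)
        out = composition_summary(_cells(classes), by=("stack_id",))
        total = out[[f"fraction_{c}" for c in ("stromal", "bcell_only", "tcell_only", "coloc")]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_no_cd19_masks_reports_missing_not_zero(self):
        cells = _cells(["stromal", "tcell_only"])
        with pytest.warns(UserWarning, match="coloc_of_b"):
            out = composition_summary(cells, by=("stack_id",))
        assert np.isnan(out.loc[0, "coloc_of_b"])

    def test_coloc_of_b_monotone_in_coloc_count(self):
        values = []
        for n_coloc in (1, 2, 3):
            cells = _cells(["coloc"] * n_coloc + ["bcell_only"] * (6 - n_coloc))
            values.append(composition_summary(cells, by=("stack_id",)).loc[0, "coloc_of_b"])
        assert values == sorted(values)


class TestAggregatePerPatient:
    def _summaries(self):
        return pd.DataFrame(
            dict(
                group=["G1"] * 2 + ["G2"],
                patient_id=["P1", "P1", "P2"],
                stack_id=["a", "b", "c"],
                fraction_stromal=[0.5, 0.3, 0.2],
                fraction_bcell_only=[0.2, 0.4, 0.3],
                fraction_tcell_only=[0.2, 0.2, 0.4],
                fraction_coloc=[0.1, 0.1, 0.1],
                coloc_of_b=[0.2, 0.4, 0.5],
            )
        )

    def test_patient_mean_of_images(self):
        patient, group = aggregate_per_patient(self._summaries())
        p1 = patient.set_index("patient_id").loc["P1"]
        assert p1["coloc_of_b"] == pytest.approx(0.3)
        p2 = patient.set_index("patient_id").loc["P2"]
        assert p2["coloc_of_b"] == pytest.approx(0.5)  # single image passes through

    def test_permutation_invariance(self):
        df = self._summaries()
        a, _ = aggregate_per_patient(df)
        b, _ = aggregate_per_patient(df.sample(frac=1.0, random_state=0))
        merged = a.merge(b, on=["group", "patient_id"], suffixes=("_a", "_b"))
        assert np.allclose(merged["coloc_of_b_a"], merged["coloc_of_b_b"])

    def test_group_level_reports_sem(self):
        _, group = aggregate_per_patient(self._summaries())
        assert {"coloc_of_b_mean", "coloc_of_b_sem", "coloc_of_b_count"} <= set(group.columns)


class TestAssignRegion:
    def test_partition_and_extremes(self, rng):
        table = pd.DataFrame(
            dict(
                centroid_z=rng.uniform(0, 31, 50),
                centroid_y=rng.uniform(0, 63, 50),
                centroid_x=rng.uniform(0, 63, 50),
            )
        )
        out = assign_region(table, (32, 64, 64), core_radius_fraction=0.5)
        assert out["region"].isin(["core", "periphery"]).all()
        center = pd.DataFrame(dict(centroid_z=[0.0], centroid_y=[31.5], centroid_x=[31.5]))
        assert assign_region(center, (32, 64, 64), 0.5).loc[0, "region"] == "core"
        corner = pd.DataFrame(dict(centroid_z=[0.0], centroid_y=[0.0], centroid_x=[0.0]))
        assert assign_region(corner, (32, 64, 64), 0.5).loc[0, "region"] == "periphery"


class TestCompareConditions:
    def test_paired_t_zero_differences(self):
        data = pd.DataFrame(
            dict(
                patient=["P1", "P2", "P3"] * 2,
                region=["periphery"] * 3 + ["core"] * 3,
                value=[1.0, 2.0, 3.0] * 2,
            )
        )
        out = compare_conditions(
            data, dict(test="paired_t", value="value", factor="region", pair="patient")
        )
        assert out.loc[0, "statistic"] == 0.0
        assert out.loc[0, "n"] == 3

    def test_mannwhitney_identical_samples_exact(self):
        data = pd.DataFrame(dict(group=["a"] * 3 + ["b"] * 3, value=[1, 2, 3, 1, 2, 3]))
        out = compare_conditions(data, dict(test="mannwhitney", value="value", factor="group"))
        assert out.loc[0, "statistic"] == pytest.approx(4.5)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_anova_tukey_reports_omnibus_and_pairs(self, rng):
        data = pd.DataFrame(
            dict(
                cond=np.repeat(["a", "b", "c"], 6),
                value=np.concatenate([rng.normal(0, 1, 6), rng.normal(0, 1, 6), rng.normal(3, 1, 6)]),
            )
        )
        out = compare_conditions(data, dict(test="anova_tukey", value="value", factor="cond"))
        assert (out["comparison"] == "omnibus").sum() == 1
        assert len(out) == 4  # omnibus + 3 pairs
        assert out.query("comparison == 'b vs c'")["p_adjusted"].iloc[0] < 0.05

    def test_sidak_adjusted_not_smaller_than_raw(self, rng):
        data = pd.DataFrame(
            dict(cond=np.repeat(["a", "b", "c"], 5), value=rng.normal(0, 1, 15))
        )
        out = compare_conditions(data, dict(test="anova_sidak", value="value", factor="cond"))
        pairs = out[out["comparison"] != "omnibus"]
        assert (pairs["p_adjusted"] >= pairs["p_value"] - 1e-12).all()

    def test_unpairable_design_rejected(self):
        data = pd.DataFrame(
            dict(patient=["P1", "P2"], region=["periphery", "core"], value=[1.0, 2.0])
        )
        with pytest.raises(DesignError):
            compare_conditions(
                data, dict(test="paired_t", value="value", factor="region", pair="patient")
            )

    def test_unknown_test_rejected(self):
        with pytest.raises(DesignError):
            compare_conditions(
                pd.DataFrame(dict(g=["a"], value=[1.0])),
                dict(test="bootstrap", value="value", factor="g"),
            )
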