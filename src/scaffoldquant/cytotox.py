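"""Cytotoxicity assay arithmetic: endpoint cytolysis and kinetic lysis curves.

Endpoint cytolysis is the percentage reduction of live target cells
relative to the target-alone condition::

    % cytolysis = (live[target alone] - live[sample]) / live[target alone] x 100

Negative values (target outgrowth) are reported and flagged, not clamped.
Kinetic live-cell lysis traces (per-object double-positive areas on a
regular time grid) are background-filtered (objects <= 10 um excluded),
corrected by subtracting the time-matched spontaneous (basal) trace, and
normalized to the maximal lysis signal of the assay's CAR traces.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, DesignError

SIZE_EXCLUSION_UM = 10.0


def percent_cytolysis(live_target_alone: float, live_sample: float) -> float:
    """Endpoint cytolysis percentage (see module docstring).

    Strictly decreasing in ``live_sample``: 0 for equal viabilities, 100
    when no live targets remain, negative when the sample outgrows the
    target-alone control. ``live_target_alone`` must be positive.
    """
    if live_target_alone == 0:
        raise ZeroDivisionError("live_target_alone is 0; cytolysis undefined")
    if live_target_alone < 0:
        raise ConfigurationError("live_target_alone must be > 0")
    return (live_target_alone - live_sample) / live_target_alone * 100.0


def cytolysis_table(viability: pd.DataFrame):
    """Per group/region/condition cytolysis against the matched target-alone row.

    ``viability`` columns: group, region, condition, percent_live, plus an
    optional patient_id column carried through. Returns
    ``(table, region_difference)``: the cytolysis table (with a
    ``flagged_negative`` column and the effector-specificity contrast
    ``car - mock`` where both exist), and per-stratum core-minus-periphery
    differences per condition.
    """
    required = {"group", "region", "condition", "percent_live"}
    if not required <= set(viability.columns):
        raise ConfigurationError(f"viability table needs columns {sorted(required)}")
    keys = ["group"] + (["patient_id"] if "patient_id" in viability.columns else []) + ["region"]

    rows = []
    for stratum, sub in viability.groupby(keys, sort=False):
        stratum = stratum if isinstance(stratum, tuple) else (stratum,)
        baseline = sub[sub["condition"] == "target_alone"]
        if baseline.empty:
            raise DesignError(f"no target_alone baseline for stratum {dict(zip(keys, stratum))}")
        live_ta = float(baseline["percent_live"].mean())
        lysis_by_condition = {}
        for condition, csub in sub[sub["condition"] != "target_alone"].groupby("condition", sort=False):
            value = percent_cytolysis(live_ta, float(csub["percent_live"].mean()))
            lysis_by_condition[condition] = value
            rows.append(
                dict(
                    **dict(zip(keys, stratum)),
                    condition=condition,
                    cytolysis_pct=value,
                    flagged_negative=value < 0,
                )
            )
        if {"car", "mock"} <= set(lysis_by_condition):
            rows.append(
                dict(
                    **dict(zip(keys, stratum)),
                    condition="car_minus_mock",
                    cytolysis_pct=lysis_by_condition["car"] - lysis_by_condition["mock"],
                    flagged_negative=False,
                )
            )
    table = pd.DataFrame(rows)

    # core - periphery contrast per (group[, patient], condition)
    diff_rows = []
    nonregion_keys = [k for k in keys if k != "region"]
    pivot_keys = nonregion_keys + ["condition"]
    for stratum, sub in table.groupby(pivot_keys, sort=False):
        stratum = stratum if isinstance(stratum, tuple) else (stratum,)
        by_region = sub.set_index("region")["cytolysis_pct"]
        if {"core", "periphery"} <= set(by_region.index):
            diff_rows.append(
                dict(
                    **dict(zip(pivot_keys, stratum)),
                    core_minus_periphery=float(by_region["core"] - by_region["periphery"]),
                )
            )
    region_difference = pd.DataFrame(diff_rows)
    return table, region_difference


def _summed_trace(trace: pd.DataFrame, size_threshold: float) -> pd.Series:
    required = {"time_min", "area_um2", "size_um"}
    if not required <= set(trace.columns):
        raise ConfigurationError(f"kinetic trace needs columns {sorted(required)}")
    kept = trace[trace["size_um"] > size_threshold]
    summed = kept.groupby("time_min", sort=True)["area_um2"].sum()
    # time points where every object was background still exist on the grid
    grid = np.sort(trace["time_min"].unique())
    return summed.reindex(grid, fill_value=0.0)


def kinetic_lysis_curve(
    trace: pd.DataFrame,
    basal: pd.DataFrame,
    max_reference="auto",
    size_threshold_um: float = SIZE_EXCLUSION_UM,
) -> pd.DataFrame:
    """Background-filtered, basal-corrected, normalized lysis curve.

    Objects with size <= ``size_threshold_um`` are excluded before areas
    are summed per frame. The time-matched basal sum is subtracted and the
    result floored at 0 (basal can transiently exceed the trace by noise).
    ``max_reference="auto"`` normalizes to the trace's own corrected
    maximum — appropriate when the trace is the assay's CAR trace; pass the
    CAR-derived reference explicitly for other conditions. Output columns:
    time_min, area_corrected_um2, percent_max_lysis.
    """
    t_sum = _summed_trace(trace, size_threshold_um)
    b_sum = _summed_trace(basal, size_threshold_um)
    if not np.array_equal(t_sum.index.to_numpy(), b_sum.index.to_numpy()):
        raise AlignmentError(
            f"trace grid ({len(t_sum)} frames) and basal grid ({len(b_sum)} frames) differ"
        )
    corrected = np.maximum(t_sum.to_numpy() - b_sum.to_numpy(), 0.0)
    if max_reference == "auto":
        max_reference = corrected.max()
    max_reference = float(max_reference)
    if max_reference <= 0:
        raise ConfigurationError(f"max_reference must be > 0; got {max_reference}")
    return pd.DataFrame(
        dict(
            time_min=t_sum.index.to_numpy(),
            area_corrected_um2=corrected,
            percent_max_lysis=corrected / max_reference * 100.0,
        )
    )


def normalize_assay_kinetics(
    kinetics: dict,
    basal_key: str = "target_alone",
    car_keys=("car",),
    size_threshold_um: float = SIZE_EXCLUSION_UM,
) -> dict:
    """Normalize every trace of an assay to the maximal CAR lysis signal.

    ``kinetics`` maps condition name to a per-object trace table; the
    reference is the maximum basal-corrected signal over the ``car_keys``
    traces, applied to all non-basal conditions.
    """
    if basal_key not in kinetics:
        raise ConfigurationError(f"no basal trace {basal_key!r} in assay")
    basal = kinetics[basal_key]
    reference = 0.0
    for key in car_keys:
        if key not in kinetics:
            raise ConfigurationError(f"no CAR trace {key!r} in assay")
        curve = kinetic_lysis_curve(kinetics[key], basal, max_reference="auto",
                                    size_threshold_um=size_threshold_um)
        reference = max(reference, float(curve["area_corrected_um2"].max()))
    return {
        key: kinetic_lysis_curve(trace, basal, max_reference=reference,
                                 size_threshold_um=size_threshold_um)
        for key, trace in kinetics.items()
        if key != basal_key
    }


def time_to_max(curve: pd.DataFrame) -> float:
    """Time (minutes) of the normalized curve's maximum."""
    idx = int(np.argmax(curve["percent_max_lysis"].to_numpy()))
    return float(curve["time_min"].iloc[idx])
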