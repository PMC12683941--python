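"""Per-mask marker quantification and FACS-anchored percentile classification.

This is the analytical core of the pipeline. For each segmented cell mask
the total pixel intensity of each marker channel is computed, min-max
normalized and log-transformed, pooling all of a patient's stacks into one
distribution per channel. A positivity threshold is then anchored to an
external modality: with ``f`` the mean externally measured positive
fraction (flow cytometry, in percent) for the disease group across the
experimental conditions, the threshold is the ``(100 - f)``-th percentile
of the patient's pooled distribution, so the called-positive fraction
matches the anchor by construction (a rank-based calibration identity).
Masks positive for both CD19 and CD3 are classified as co-localized.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, DegenerateDistributionError
from .stacks import ImageStack, LabelVolume

#: Classifier classes, from the (CD19 call, CD3 call) pair.
CLASS_OF_CALLS = {
    (False, False): "stromal",
    (True, False): "bcell_only",
    (False, True): "tcell_only",
    (True, True): "coloc",
}

LOG_EPS = 1e-6


def aggregate_mask_intensities(
    stack: ImageStack,
    labels: LabelVolume,
    channels=None,
    stack_id: str = "stack",
    patient_id: str = "P1",
    group: str = "G1",
    condition: str = "na",
) -> pd.DataFrame:
    """Per-mask geometry and total channel intensity table.

    One row per nonzero label id with its voxel volume, centroid, and
    ``total_<channel>`` columns (sum of the raw channel over the mask).
    An empty label volume yields an empty table with a warning.
    """
    if labels.shape != stack.shape:
        raise ConfigurationError(
            f"label shape {labels.shape} does not match stack shape {stack.shape}"
        )
    if channels is None:
        channels = [c for c in stack.channel_names if c != "nuclei"]
    for c in channels:
        if c not in stack.channel_names:
            raise ConfigurationError(f"requested channel {c!r} not in stack {stack.channel_names}")

    ids = labels.ids
    meta_cols = dict(stack_id=stack_id, patient_id=patient_id, group=group, condition=condition)
    base_cols = ["cell_id", "volume_voxels", "centroid_z", "centroid_y", "centroid_x"]
    if ids.size == 0:
        warnings.warn(f"empty label volume for stack {stack_id!r}")
        cols = list(meta_cols) + base_cols + [f"total_{c}" for c in channels]
        return pd.DataFrame(columns=cols)

    volume = ndimage.sum_labels(np.ones(labels.shape), labels.labels, index=ids)
    centroids = np.asarray(ndimage.center_of_mass(np.ones(labels.shape), labels.labels, index=ids))
    table = pd.DataFrame(meta_cols, index=range(ids.size))
    table["cell_id"] = ids.astype(int)
    table["volume_voxels"] = volume.astype(int)
    table[["centroid_z", "centroid_y", "centroid_x"]] = centroids
    for c in channels:
        table[f"total_{c}"] = ndimage.sum_labels(stack.channel(c), labels.labels, index=ids)
    return table


def normalize_log(values, eps: float = LOG_EPS) -> np.ndarray:
    """Min-max normalize to [0, 1], then take ``ln(v' + eps)``.

    The offset keeps the minimum finite; it does not change rank order, so
    the rank-based percentile thresholds downstream are unaffected by its
    value. Requires at least two distinct values; identical values raise
    :class:`DegenerateDistributionError` (thresholding would be undefined).
    """
    values = np.asarray(values, dtype=np.float64)
    vmin, vmax = values.min(), values.max()
    if values.size < 2 or vmax == vmin:
        raise DegenerateDistributionError(
            "need >= 2 distinct intensity values to normalize; all values identical"
        )
    return np.log((values - vmin) / (vmax - vmin) + eps)


def add_normalized_intensities(
    table: pd.DataFrame, channels=("CD19", "CD3"), patient_col: str = "patient_id"
) -> pd.DataFrame:
    """Add ``normlog_<channel>`` columns, pooling per patient across stacks.

    The pooling unit is the patient: all of a patient's stacks contribute to
    one min-max + log transform per channel.
    """
    out = table.copy()
    for c in channels:
        out[f"normlog_{c}"] = np.nan
        for _, idx in table.groupby(patient_col, sort=False).groups.items():
            out.loc[idx, f"normlog_{c}"] = normalize_log(table.loc[idx, f"total_{c}"].to_numpy())
    return out


@dataclass(frozen=True)
class ThresholdEntry:
    """One calibrated threshold for a (patient, channel) pair."""

    patient_id: str
    channel: str
    anchor_fraction_used: float  # percent, mean of anchor rows
    percentile_n: float  # 100 - anchor_fraction_used
    threshold_value: float  # on the normalized-log scale


def compute_percentile_threshold(
    values,
    anchors: pd.DataFrame,
    group: str,
    marker: str,
    patient_id: str = "P1",
    channel: str | None = None,
    conditions=None,
) -> ThresholdEntry:
    """Anchor a positivity threshold to external positive fractions.

    ``anchors`` has columns group/condition/marker/positive_fraction (in
    percent)/replicate_id. The anchor is the mean positive fraction over
    replicates and over the experimental conditions for the group; the
    threshold is the linear-interpolation ``(100 - anchor)``-th percentile
    of the pooled values.
    """
    rows = anchors[(anchors["group"] == group) & (anchors["marker"] == marker)]
    if conditions is not None:
        rows = rows[rows["condition"].isin(conditions)]
    if rows.empty:
        raise ConfigurationError(f"no anchor rows for group={group!r}, marker={marker!r}")
    anchor = float(rows["positive_fraction"].mean())
    if not 0.0 <= anchor <= 100.0:
        raise ConfigurationError(f"anchor fraction {anchor} outside [0, 100]")
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ConfigurationError("no intensity values to threshold")
    percentile_n = 100.0 - anchor
    threshold = float(np.percentile(values, percentile_n, method="linear"))
    return ThresholdEntry(
        patient_id=patient_id,
        channel=channel or marker,
        anchor_fraction_used=anchor,
        percentile_n=percentile_n,
        threshold_value=threshold,
    )


def compute_thresholds(
    table: pd.DataFrame,
    anchors: pd.DataFrame,
    channels=("CD19", "CD3"),
    marker_of_channel=None,
    conditions=None,
) -> pd.DataFrame:
    """Threshold set for every (patient, channel) in a normalized cell table.

    Each patient's pooled ``normlog_<channel>`` distribution is thresholded
    at the percentile set by its disease group's anchor fraction. Returns a
    DataFrame of :class:`ThresholdEntry` rows.
    """
    marker_of_channel = marker_of_channel or {}
    entries = []
    for (patient, group), idx in table.groupby(["patient_id", "group"], sort=False).groups.items():
        for c in channels:
            col = f"normlog_{c}"
            if col not in table.columns:
                raise ConfigurationError(f"table lacks {col}; run add_normalized_intensities first")
            entries.append(
                compute_percentile_threshold(
                    table.loc[idx, col].to_numpy(),
                    anchors,
                    group=group,
                    marker=marker_of_channel.get(c, c),
                    patient_id=patient,
                    channel=c,
                    conditions=conditions,
                )
            )
    return pd.DataFrame([vars(e) for e in entries])


def classify_cells(table: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Apply thresholds: per-channel calls and the four-way class.

    A mask is called positive iff its normalized-log intensity strictly
    exceeds the threshold (a value exactly at the threshold is negative, so
    a 0% anchor yields zero positives). Class: CD19+CD3+ -> coloc, CD19+
    only -> bcell_only, CD3+ only -> tcell_only, neither -> stromal.
    """
    out = table.copy()
    channels = sorted(thresholds["channel"].unique())
    lookup = {
        (r.patient_id, r.channel): r.threshold_value for r in thresholds.itertuples()
    }
    missing = sorted(
        {
            (p, c)
            for p in out["patient_id"].unique()
            for c in channels
            if (p, c) not in lookup
        }
    )
    if missing:
        raise ConfigurationError(f"missing thresholds for (patient, channel) keys: {missing}")
    for c in channels:
        thr = out["patient_id"].map({p: lookup[(p, c)] for p in out["patient_id"].unique()})
        out[f"call_{c}"] = out[f"normlog_{c}"] > thr
    if {"call_CD19", "call_CD3"} <= set(out.columns):
        out["cell_class"] = [
            CLASS_OF_CALLS[(bool(b), bool(t))]
            for b, t in zip(out["call_CD19"], out["call_CD3"])
        ]
    return out
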