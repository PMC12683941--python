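"""Composition and co-localization summaries with group statistics.

Summaries mirror the study's imaging readouts: per stack, patient, region
and disease group, the fractions of stromal, B-only, T-only and
co-localized (CD19+/CD3+) masks, plus ``coloc_of_b`` — the fraction of
CD19+ masks engaged by a T cell (double-positives over all CD19+ masks).
Patient values are unweighted means of their images; group level reports
mean +- SEM over patients. Hypothesis tests (paired t, Mann-Whitney U,
one-way ANOVA with Tukey or Sidak adjustment) are delegated to
scipy/statsmodels; this module owns only the design mapping and reporting.
"""
from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DesignError

CLASS_ORDER = ("stromal", "bcell_only", "tcell_only", "coloc")


def assign_region(table: pd.DataFrame, shape, core_radius_fraction: float = 0.5) -> pd.DataFrame:
    """Assign periphery/core from lateral centroid position.

    The core is the central lateral disc whose radius is
    ``core_radius_fraction`` of the lateral half-extent; every cell is
    assigned to exactly one region. (The study separates regions by
    dissection; this geometric rule is the simulation-side convention.)
    """
    out = table.copy()
    half_y = max((shape[1] - 1) / 2.0, 1e-9)
    half_x = max((shape[2] - 1) / 2.0, 1e-9)
    ry = (out["centroid_y"] - half_y) / half_y
    rx = (out["centroid_x"] - half_x) / half_x
    out["region"] = np.where(
        np.hypot(ry, rx) <= core_radius_fraction, "core", "periphery"
    )
    return out


def composition_summary(cells: pd.DataFrame, by=("stack_id",)) -> pd.DataFrame:
    """Class composition per stratum of ``by`` keys.

    Fractions are class counts over all cells in the stratum (they sum to
    1); ``coloc_of_b`` is double-positive masks over all CD19+ masks
    (coloc + bcell_only) and is reported as missing (NaN), not zero, when a
    stratum has no CD19+ masks.
    """
    if "cell_class" not in cells.columns:
        raise ConfigurationError("cells table has no cell_class column; classify first")
    by = list(by)
    rows = []
    for keys, sub in cells.groupby(by, sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n = len(sub)
        if n == 0:  # pragma: no cover - groupby does not emit empty groups
            warnings.warn(f"stratum {keys} has no cells; omitted")
            continue
        counts = sub["cell_class"].value_counts()
        row = dict(zip(by, keys))
        row["n_cells"] = n
        for cls in CLASS_ORDER:
            row[f"fraction_{cls}"] = counts.get(cls, 0) / n
        n_cd19 = counts.get("coloc", 0) + counts.get("bcell_only", 0)
        row["coloc_of_b"] = counts.get("coloc", 0) / n_cd19 if n_cd19 else np.nan
        if n_cd19 == 0:
            warnings.warn(f"stratum {keys} has no CD19+ masks; coloc_of_b is undefined")
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_per_patient(
    image_summaries: pd.DataFrame,
    patient_col: str = "patient_id",
    group_col: str = "group",
    extra_keys=(),
):
    """Patient-level means of per-image summaries, then group mean +- SEM.

    Each image is one observation; patients are averaged unweighted.
    Returns ``(patient_level, group_level)`` DataFrames.
    """
    value_cols = [c for c in image_summaries.columns if c.startswith("fraction_")] + ["coloc_of_b"]
    keys = [group_col, patient_col, *extra_keys]
    patient_level = (
        image_summaries.groupby(keys, sort=False)[value_cols].mean().reset_index()
    )
    group_keys = [group_col, *extra_keys]
    grouped = patient_level.groupby(group_keys, sort=False)[value_cols]
    group_level = grouped.agg(["mean", "sem", "count"])
    group_level.columns = [f"{v}_{s}" for v, s in group_level.columns]
    return patient_level, group_level.reset_index()


# ---------------------------------------------------------------------------
# hypothesis tests


def _two_levels(design, data, factor):
    levels = design.get("levels")
    if levels is None:
        levels = list(pd.unique(data[factor]))
    if len(levels) != 2:
        raise DesignError(f"test needs exactly 2 levels of {factor!r}; got {levels}")
    return levels


def paired_t_test(data, value, factor, pair, levels=None):
    """Paired t-test between two factor levels, paired on ``pair``."""
    levels = levels or list(pd.unique(data[factor]))
    if len(levels) != 2:
        raise DesignError(f"paired t-test needs 2 levels; got {levels}")
    wide = data.pivot_table(index=pair, columns=factor, values=value, aggfunc="mean")
    if not set(levels) <= set(wide.columns):
        raise DesignError(f"levels {levels} not all present")
    wide = wide[levels].dropna()
    if len(wide) < 2:
        raise DesignError("fewer than 2 complete pairs for the paired t-test")
    diffs = (wide[levels[0]] - wide[levels[1]]).to_numpy()
    if np.allclose(diffs, 0.0):
        # zero-variance differences: no effect, not an undefined statistic
        res = type("R", (), {"statistic": 0.0, "pvalue": 1.0})
    else:
        res = stats.ttest_rel(wide[levels[0]], wide[levels[1]])
    return dict(
        test="paired_t",
        comparison=f"{levels[0]} vs {levels[1]}",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        p_adjusted=float(res.pvalue),
        n=int(len(wide)),
    )


def mann_whitney(data, value, factor, levels=None, exact_max_n: int = 10):
    """Two-sided Mann-Whitney U; exact (full-permutation) at small n.

    The permutation method enumerates all group assignments when feasible,
    so tied inputs are handled exactly (two identical samples give p = 1).
    """
    if levels is None:
        levels = list(pd.unique(data[factor]))
    if len(levels) != 2:
        raise DesignError(f"Mann-Whitney needs 2 levels; got {levels}")
    x = data.loc[data[factor] == levels[0], value].dropna().to_numpy()
    y = data.loc[data[factor] == levels[1], value].dropna().to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise DesignError("both groups need at least one observation")
    if min(len(x), len(y)) <= exact_max_n:
        method = stats.PermutationMethod(n_resamples=100_000, rng=0)
    else:
        method = "auto"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return dict(
        test="mannwhitney",
        comparison=f"{levels[0]} vs {levels[1]}",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        p_adjusted=float(res.pvalue),
        n=int(len(x) + len(y)),
    )


def anova_posthoc(data, value, factor, adjust: str = "tukey"):
    """One-way ANOVA followed by all-pairs comparisons with adjustment.

    ``adjust``: ``tukey`` (Tukey HSD) or ``sidak`` (pairwise Welch t-tests
    with Sidak-adjusted p-values).
    """
    groups = {k: g[value].dropna().to_numpy() for k, g in data.groupby(factor, sort=False)}
    if len(groups) < 2:
        raise DesignError(f"ANOVA needs >= 2 levels of {factor!r}")
    f_res = stats.f_oneway(*groups.values())
    rows = [
        dict(
            test=f"anova_{adjust}",
            comparison="omnibus",
            statistic=float(f_res.statistic),
            p_value=float(f_res.pvalue),
            p_adjusted=float(f_res.pvalue),
            n=int(sum(len(v) for v in groups.values())),
        )
    ]
    names = list(groups)
    if adjust == "tukey":
        res = stats.tukey_hsd(*[groups[k] for k in names])
        for i, j in itertools.combinations(range(len(names)), 2):
            rows.append(
                dict(
                    test="anova_tukey",
                    comparison=f"{names[i]} vs {names[j]}",
                    statistic=float(res.statistic[i, j]),
                    p_value=float(res.pvalue[i, j]),
                    p_adjusted=float(res.pvalue[i, j]),
                    n=int(len(groups[names[i]]) + len(groups[names[j]])),
                )
            )
    elif adjust == "sidak":
        from statsmodels.stats.multitest import multipletests

        raw = []
        for i, j in itertools.combinations(range(len(names)), 2):
            t = stats.ttest_ind(groups[names[i]], groups[names[j]])
            raw.append((names[i], names[j], t))
        _, adj, _, _ = multipletests([t.pvalue for *_, t in raw], method="sidak")
        for (a, b, t), p_adj in zip(raw, adj):
            rows.append(
                dict(
                    test="anova_sidak",
                    comparison=f"{a} vs {b}",
                    statistic=float(t.statistic),
                    p_value=float(t.pvalue),
                    p_adjusted=float(p_adj),
                    n=int(len(groups[a]) + len(groups[b])),
                )
            )
    else:
        raise DesignError(f"unknown adjustment {adjust!r}; use tukey or sidak")
    return rows


def compare_conditions(data: pd.DataFrame, design: dict) -> pd.DataFrame:
    """Run the configured comparison and return a tidy test report.

    ``design`` keys: ``test`` (paired_t | mannwhitney | anova_tukey |
    anova_sidak), ``value`` (response column), ``factor`` (grouping
    column), ``pair`` (pairing column, paired_t only), optional ``levels``.
    """
    test = design.get("test")
    value, factor = design.get("value"), design.get("factor")
    if not test or not value or not factor:
        raise DesignError("design must name test, value, and factor")
    for col in filter(None, (value, factor, design.get("pair"))):
        if col not in data.columns:
            raise DesignError(f"design column {col!r} not in data")
    if test == "paired_t":
        pair = design.get("pair")
        if not pair:
            raise DesignError("paired_t requires a pair column")
        rows = [paired_t_test(data, value, factor, pair, design.get("levels"))]
    elif test == "mannwhitney":
        rows = [mann_whitney(data, value, factor, design.get("levels"))]
    elif test in ("anova_tukey", "anova_sidak"):
        rows = anova_posthoc(data, value, factor, adjust=test.split("_")[1])
    else:
        raise DesignError(f"unknown test {test!r}")
    return pd.DataFrame(rows)
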