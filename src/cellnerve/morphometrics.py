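"""Comparative tissue morphometrics on per-cell attribute tables.

Covers the cohort-level statistics used alongside the topological analysis:
coefficient of variation of cell volume (CVcv), stage-to-stage relative
growth estimated from cohort means, per-sample tissue proportions, the
staging-threshold extrapolation between reference and target cohorts, and
tabulation of classified mitotic divisions.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "cvcv",
    "relative_increase",
    "growth_table",
    "tissue_proportions",
    "stage_threshold_extrapolation",
    "division_summary",
]

GROWTH_MEASURES = ("tissue_volume", "cell_count")
PROPORTION_MEASURES = ("volume", "cell_count")


def cvcv(volumes: Sequence[float] | np.ndarray, ddof: int = 1) -> float:
    """Coefficient of variation of cell volume: sd / mean.

    Uses the sample standard deviation (n−1 denominator) by default.
    Dimensionless and invariant under rescaling of all volumes; inputs are
    expected to be pre-filtered for segmentation artifacts.
    """
    arr = np.asarray(volumes, dtype=float)
    if arr.size < 2:
        raise ValueError(f"CVcv needs at least two volumes, got {arr.size}")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError(f"mean volume must be positive, got {mean}")
    return float(arr.std(ddof=ddof) / mean)


def relative_increase(y_n: float, y_n1: float) -> float:
    """Relative change between consecutive stages: [y(n+1) − y(n)] / y(n)."""
    if y_n <= 0:
        raise ValueError(f"reference value must be positive, got {y_n}")
    return (y_n1 - y_n) / y_n


def _per_sample_measure(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    if measure not in GROWTH_MEASURES:
        raise ValueError(f"measure must be one of {GROWTH_MEASURES}, got {measure!r}")
    grouped = table.groupby(["stage", "tissue_id", "sample_id"], observed=True)
    if measure == "tissue_volume":
        agg = grouped["volume"].sum()
    else:
        agg = grouped["cell_id"].count()
    return agg.rename("value").reset_index()


def growth_table(table: pd.DataFrame, measure: str = "tissue_volume") -> pd.DataFrame:
    """Stage-wise relative growth per tissue, from cohort means.

    For each tissue and each consecutive pair of stages present in the
    table's stage order, computes the relative increase of the stage-wise
    mean of the per-sample measure (total tissue volume in µm³, or cell
    count).  Growth is estimated indirectly from independent stage cohorts;
    no sample pairing across stages is implied.  A tissue missing at either
    stage of a pair yields a row flagged ``missing`` with NaN values.
    """
    per_sample = _per_sample_measure(table, measure)
    stages = [s for s in table["stage"].cat.categories if s in set(table["stage"].dropna())]
    if len(stages) < 2:
        raise ValueError("growth needs at least two stages present")
    means = per_sample.groupby(["stage", "tissue_id"], observed=True)["value"].mean()
    rows = []
    for tissue in pd.unique(per_sample["tissue_id"]):
        for s0, s1 in zip(stages[:-1], stages[1:]):
            y0 = means.get((s0, tissue), np.nan)
            y1 = means.get((s1, tissue), np.nan)
            ok = np.isfinite(y0) and np.isfinite(y1)
            rel = relative_increase(y0, y1) if ok else np.nan
            rows.append({
                "tissue_id": tissue, "stage_from": s0, "stage_to": s1,
                "mean_from": y0, "mean_to": y1,
                "relative_increase": rel, "percent_change": 100.0 * rel,
                "missing": not ok,
            })
    return pd.DataFrame(rows)


def tissue_proportions(table: pd.DataFrame, measure: str = "volume") -> pd.DataFrame:
    """Per-sample share of each tissue in total volume or cell count.

    Shares sum to one within each sample.
    """
    if measure not in PROPORTION_MEASURES:
        raise ValueError(f"measure must be one of {PROPORTION_MEASURES}, got {measure!r}")
    if len(table) == 0:
        raise ValueError("empty cell table")
    grouped = table.groupby(["sample_id", "tissue_id"], observed=True)
    agg = grouped["volume"].sum() if measure == "volume" else grouped["cell_id"].count()
    agg = agg.rename("value").reset_index()
    totals = agg.groupby("sample_id")["value"].transform("sum")
    agg["share"] = agg["value"] / totals
    return agg


def stage_threshold_extrapolation(min_ref: float, max_ref: float, max_target: float) -> float:
    """Scale a reference cohort's stage threshold to a target cohort.

    The target's lower limit is estimated as
    ``(min_ref / max_ref) * max_target``: the reference minimum-to-maximum
    ratio applied to the target maximum, e.g. to delimit a stage by total
    volume or cell count where a direct marker is unavailable.
    """
    if max_ref <= 0:
        raise ValueError(f"reference maximum must be positive, got {max_ref}")
    return (min_ref / max_ref) * max_target


def division_summary(tally: pd.DataFrame, by: Sequence[str] | None = None) -> pd.DataFrame:
    """Tabulate classified mitotic divisions as counts and percentages.

    ``tally`` has one row per observed division with a ``division_class``
    column (e.g. periclinal / anticlinal) and optional grouping columns such
    as stage or layer.  Percentages are reported both exact and rounded to
    the nearest integer for display.  With ``by``, percentages are of the
    grand total within each group set.
    """
    if len(tally) == 0:
        raise ValueError("empty division tally")
    if "division_class" not in tally.columns:
        raise ValueError("tally must have a 'division_class' column")
    keys = list(by) if by else []
    counts = (
        tally.groupby(keys + ["division_class"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    counts["total"] = counts["count"].sum()
    counts["percent"] = 100.0 * counts["count"] / counts["total"]
    counts["percent_rounded"] = counts["percent"].round().astype(int)
    return counts
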