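"""Region-level aggregation and two-group comparisons.

Per image and region the scored cell table is reduced to the quantities
reported for tissue cytometry: cell counts, mean tetraspanin OD
(OD_mean), OD range, percentage of bright cells overall and within the
lineage-positive subset. OD distributions are binned per 0.05 and
normalized to % of the modal bin. Two-group comparisons use an unpaired
Student's t test when both groups pass a Shapiro–Wilk normality gate and
the Mann–Whitney U test otherwise (exact null distribution when sample
sizes permit and there are no ties); P ≤ 0.05 is called significant.
The statistical unit is one image, not one cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "RegionSummary",
    "ODHistogram",
    "StatResult",
    "summarize_region",
    "summarize_images",
    "bin_od_histogram",
    "compare_groups",
    "run_comparisons",
    "subsample_cells",
]


@dataclass
class RegionSummary:
    image_id: str
    region: str
    n_cells: int
    od_mean: float  # mean tetraspanin OD; NaN when the region is empty
    od_min: float
    od_max: float
    pct_bright: float  # of all cells in the region
    n_lineage_pos: int
    pct_bright_lineage_pos: float  # of lineage-positive cells; NaN if none
    pct_lineage_pos: float

    def to_row(self) -> dict:
        return self.__dict__.copy()


def summarize_region(records: pd.DataFrame, region: str, image_id: str = "") -> RegionSummary:
    """Aggregate one image's scored records for one region.

    Empty strata give ``n=0`` summaries with NaN means; a low-n warning
    is emitted when the lineage-positive subset has fewer than 20 cells.
    """
    if "phenotype" not in records.columns:
        raise ValueError("records must be scored first (missing 'phenotype')")
    sub = records[records["region"] == region]
    n = len(sub)
    if image_id == "" and n:
        image_id = str(sub["image_id"].iloc[0])
    if n == 0:
        return RegionSummary(image_id, region, 0, np.nan, np.nan, np.nan,
                             np.nan, 0, np.nan, np.nan)
    ods = sub["od_tet"].to_numpy(dtype=float)
    bright = sub["tet_bright"].to_numpy(dtype=bool)
    lin_pos = sub["lineage_positive"].to_numpy(dtype=bool)
    n_lin = int(lin_pos.sum())
    if 0 < n_lin < 20:
        warnings.warn(
            f"{image_id}/{region}: only {n_lin} lineage-positive cells", stacklevel=2
        )
    pct_bright_lin = 100.0 * bright[lin_pos].mean() if n_lin else np.nan
    return RegionSummary(
        image_id=image_id,
        region=region,
        n_cells=n,
        od_mean=float(ods.mean()),
        od_min=float(ods.min()),
        od_max=float(ods.max()),
        pct_bright=100.0 * float(bright.mean()),
        n_lineage_pos=n_lin,
        pct_bright_lineage_pos=float(pct_bright_lin) if n_lin else np.nan,
        pct_lineage_pos=100.0 * float(lin_pos.mean()),
    )


def summarize_images(records: pd.DataFrame, regions=None) -> pd.DataFrame:
    """Per image × region summary table across a scored record table."""
    if regions is None:
        regions = sorted(records["region"].unique())
    rows = []
    for image_id, group in records.groupby("image_id", sort=True):
        for region in regions:
            rows.append(summarize_region(group, region, image_id=str(image_id)).to_row())
    return pd.DataFrame(rows)


@dataclass
class ODHistogram:
    bin_width: float
    edges: np.ndarray  # left-closed right-open bins [e0, e1), ...
    counts: np.ndarray
    normalized: np.ndarray  # % of the modal bin (max = 100)


def bin_od_histogram(ods, bin_width: float = 0.05) -> ODHistogram:
    """Bin ODs per ``bin_width`` and normalize heights to % of max.

    Bins are left-closed right-open from 0 to ``ceil(max/width)·width``
    (a value exactly on an edge falls in the upper bin).
    """
    ods = np.asarray(ods, dtype=float)
    if ods.size == 0:
        raise ValueError("cannot bin an empty OD sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if ods.min() < 0:
        raise ValueError("ODs must be non-negative")
    # half-open bins by direct floor indexing (np.histogram would close
    # the last bin on the right); a value exactly on an edge opens the
    # upper bin
    idx = (ods / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.bincount(idx, minlength=n_bins)
    normalized = 100.0 * counts / counts.max()
    return ODHistogram(bin_width=bin_width, edges=edges, counts=counts, normalized=normalized)


@dataclass
class StatResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test: str  # t_test_unpaired | mann_whitney
    normality_p_a: float  # NaN when the gate was skipped
    normality_p_b: float
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05
    metric: str = ""

    def to_row(self) -> dict:
        return self.__dict__.copy()


def _normality_p(values: np.ndarray, alpha: float) -> tuple[bool, float]:
    """Shapiro–Wilk gate; n<3 or constant samples count as non-Gaussian."""
    if values.size < 3 or np.ptp(values) == 0:
        return False, np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(scipy.stats.shapiro(values).pvalue)
    return p > alpha, p


def compare_groups(
    values_a,
    values_b,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    welch: bool = False,
    labels: tuple[str, str] = ("a", "b"),
    metric: str = "",
) -> StatResult:
    """Normality-gated two-group comparison.

    Both groups Gaussian by Shapiro–Wilk → two-sided unpaired Student's
    t test (equal variance unless ``welch``); otherwise a two-sided
    Mann–Whitney U test, exact when ``n_a+n_b ≤ 20`` with no ties, else
    normal approximation with tie and continuity correction.
    Significance is declared at ``p ≤ alpha``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    gauss_a, p_a = _normality_p(a, normality_alpha)
    gauss_b, p_b = _normality_p(b, normality_alpha)
    if gauss_a and gauss_b and a.size >= 2 and b.size >= 2:
        res = scipy.stats.ttest_ind(a, b, equal_var=not welch)
        test = "t_test_unpaired"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        pooled = np.concatenate([a, b])
        exact = a.size + b.size <= 20 and np.unique(pooled).size == pooled.size
        method = "exact" if exact else "asymptotic"
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "mann_whitney"
        stat, p = float(res.statistic), float(res.pvalue)
    p = min(p, 1.0)
    return StatResult(
        group_a=labels[0],
        group_b=labels[1],
        n_a=int(a.size),
        n_b=int(b.size),
        test=test,
        normality_p_a=p_a,
        normality_p_b=p_b,
        statistic=stat,
        p_value=p,
        significant=bool(p <= alpha),
        alpha=alpha,
        metric=metric,
    )


#: default comparison plan: (metric column, region A, region B)
DEFAULT_PLAN = [
    ("pct_bright", "follicle", "stroma"),
    ("pct_bright_lineage_pos", "t_zone", "stroma"),
    ("od_mean", "follicle", "stroma"),
]


def run_comparisons(
    summaries: pd.DataFrame,
    plan=None,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> list[StatResult]:
    """Run planned region-vs-region comparisons over per-image values.

    Each plan entry is ``(metric, region_a, region_b)``; the groups are
    the metric's per-image values for each region. Groups with fewer
    than 2 images are skipped with a warning.
    """
    if plan is None:
        plan = DEFAULT_PLAN
    results = []
    for metric, region_a, region_b in plan:
        if metric not in summaries.columns:
            warnings.warn(f"metric {metric!r} not in summaries; skipped", stacklevel=2)
            continue
        vals = {}
        ok = True
        for region in (region_a, region_b):
            sub = summaries[summaries["region"] == region][metric].dropna()
            if len(sub) < 2:
                warnings.warn(
                    f"comparison {metric} {region_a} vs {region_b}: "
                    f"region {region!r} has {len(sub)} images (<2); skipped",
                    stacklevel=2,
                )
                ok = False
                break
            vals[region] = sub.to_numpy(dtype=float)
        if not ok:
            continue
        results.append(
            compare_groups(
                vals[region_a],
                vals[region_b],
                alpha=alpha,
                normality_alpha=normality_alpha,
                labels=(region_a, region_b),
                metric=metric,
            )
        )
    return results


def subsample_cells(
    records: pd.DataFrame, per_region: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """At most ``per_region`` cells per region, sampled without
    replacement with a fixed seed (scatter-plot export)."""
    rng = np.random.default_rng(seed)
    parts = []
    for region, group in records.groupby("region", sort=True):
        if len(group) > per_region:
            idx = rng.choice(len(group), size=per_region, replace=False)
            group = group.iloc[np.sort(idx)]
        parts.append(group)
    return pd.concat(parts, ignore_index=True) if parts else records.copy()
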