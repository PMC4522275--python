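"""Per-cell marker quantification, threshold derivation and scoring.

Each segmented cell gets a mean optical density per marker channel,
measured over its nucleus plus a thin expansion ring so membrane-bound
chromogen (lineage and tetraspanin markers deposit around the nucleus)
is captured. Positivity and dim/bright cutoffs are derived from
designated negative-control cells — non-immune cells in marker-negative
regions — as nearest-rank percentiles of their ODs, then every cell is
scored into one of four classes: lin−/dim, lin+/dim, lin+/bright,
lin−/bright. Images with less than 10% tissue are discarded before any
aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.segmentation import expand_labels
from sklearn.base import BaseEstimator

from .segmentation import CellLabelMap
from .synthetic import REGION_NAMES
from .unmixing import AbundanceMap

__all__ = [
    "PHENOTYPES",
    "ScoringThresholds",
    "ImageQC",
    "quantify_cells",
    "nearest_rank_percentile",
    "derive_thresholds",
    "score_cells",
    "qc_filter_images",
    "PhenotypeScorer",
    "DEFAULT_CHANNEL_MAP",
]

PHENOTYPES = ("lin_neg_dim", "lin_pos_dim", "lin_pos_bright", "lin_neg_bright")

DEFAULT_CHANNEL_MAP = {
    "lineage": "warp_red",
    "tetraspanin": "true_blue",
    "nuclear": "nuclear_red",
}

LOW_N_WARNING = 20  # strata smaller than this are flagged when reported


@dataclass
class ScoringThresholds:
    """OD cutoffs shared by all images of one staining batch."""

    lineage_positivity_od: float
    tet_dim_bright_od: float
    percentile_lineage: float = 99.0
    percentile_tet: float = 95.0
    n_control_cells: int = 0
    control_regions: tuple = ()

    def __post_init__(self) -> None:
        if self.lineage_positivity_od <= 0 or self.tet_dim_bright_od <= 0:
            raise ValueError("thresholds must be positive")

    def to_json(self) -> dict:
        return {
            "lineage_positivity_od": self.lineage_positivity_od,
            "tet_dim_bright_od": self.tet_dim_bright_od,
            "percentile_lineage": self.percentile_lineage,
            "percentile_tet": self.percentile_tet,
            "n_control_cells": self.n_control_cells,
            "control_regions": list(self.control_regions),
        }

    @classmethod
    def from_json(cls, d: dict) -> "ScoringThresholds":
        d = dict(d)
        d["control_regions"] = tuple(d.get("control_regions", ()))
        return cls(**d)


@dataclass
class ImageQC:
    image_id: str
    tissue_fraction: float
    passed: bool


def quantify_cells(
    cells: CellLabelMap,
    abundances: AbundanceMap,
    region_mask: np.ndarray,
    channel_map: dict | None = None,
    ring_px: float = 3.0,
    image_id: str = "",
) -> pd.DataFrame:
    """Mean OD per marker for every segmented cell.

    Membrane markers (lineage, tetraspanin) are averaged over the cell's
    membrane ring: the nucleus labels expanded by ``ring_px`` minus the
    nuclei themselves. ``expand_labels`` assigns contested pixels to the
    nearest cell, so neighboring rings never overlap. The nuclear
    counterstain is averaged over the nucleus pixels. A cell's region is
    the region-mask label at its centroid. Cells whose measurement mask
    is empty get OD 0, never NaN.
    """
    if channel_map is None:
        channel_map = DEFAULT_CHANNEL_MAP
    for role in ("lineage", "tetraspanin", "nuclear"):
        name = channel_map.get(role)
        if name not in abundances.endmember_names:
            raise KeyError(
                f"channel_map[{role!r}] = {name!r} not in library {abundances.endmember_names}"
            )
    columns = [
        "image_id", "cell_id", "y", "x", "area_px2", "region",
        "od_lineage", "od_tet", "od_nuclear",
    ]
    if cells.n_cells == 0:
        return pd.DataFrame(columns=columns)
    if region_mask.shape != abundances.data.shape[:2]:
        raise ValueError("region mask and abundance map shapes disagree")
    expanded = expand_labels(cells.labels, distance=ring_px)
    ring_labels = np.where(cells.labels == 0, expanded, 0)
    index = cells.table["cell_id"].to_numpy()
    ods = {}
    for role in ("lineage", "tetraspanin", "nuclear"):
        channel = abundances.channel(channel_map[role])
        labels = cells.labels if role == "nuclear" else ring_labels
        means = ndi.mean(channel, labels=labels, index=index)
        ods[role] = np.nan_to_num(np.asarray(means), nan=0.0)
    ys = cells.table["y"].to_numpy()
    xs = cells.table["x"].to_numpy()
    codes = region_mask[np.round(ys).astype(int), np.round(xs).astype(int)]
    return pd.DataFrame(
        {
            "image_id": image_id,
            "cell_id": index,
            "y": ys,
            "x": xs,
            "area_px2": cells.table["area_px2"].to_numpy(),
            "region": [REGION_NAMES[int(c)] for c in codes],
            "od_lineage": ods["lineage"],
            "od_tet": ods["tetraspanin"],
            "od_nuclear": ods["nuclear"],
        }
    )


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """k-th smallest value with k = ⌈p/100 · n⌉ (nearest-rank convention)."""
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if n == 0:
        raise ValueError("empty sample")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    k = int(np.ceil(percentile / 100.0 * n))
    return float(values[k - 1])


def derive_thresholds(
    records: pd.DataFrame,
    control_selector=("other",),
    percentile_tet: float = 95.0,
    percentile_lineage: float = 99.0,
    min_control_cells: int = 50,
) -> ScoringThresholds:
    """Derive batch thresholds from negative-control cells.

    ``control_selector`` is either a sequence of region names whose
    cells serve as controls (default the marker-negative ``other``
    region) or a callable ``records → boolean mask``. The dim/bright
    cutoff is the nearest-rank ``percentile_tet`` of control tetraspanin
    ODs; positivity is ``percentile_lineage`` of control lineage ODs.
    """
    if callable(control_selector):
        mask = np.asarray(control_selector(records), dtype=bool)
        regions: tuple = ("<callable>",)
    else:
        regions = tuple(control_selector)
        mask = records["region"].isin(regions).to_numpy()
    controls = records[mask]
    n = len(controls)
    if n < min_control_cells:
        raise ValueError(
            f"only {n} control cells; at least {min_control_cells} required"
        )
    return ScoringThresholds(
        lineage_positivity_od=nearest_rank_percentile(
            controls["od_lineage"].to_numpy(), percentile_lineage
        ),
        tet_dim_bright_od=nearest_rank_percentile(
            controls["od_tet"].to_numpy(), percentile_tet
        ),
        percentile_lineage=percentile_lineage,
        percentile_tet=percentile_tet,
        n_control_cells=n,
        control_regions=regions,
    )


def score_cells(records: pd.DataFrame, thresholds: ScoringThresholds) -> pd.DataFrame:
    """Assign the four-class phenotype; boundary equality counts as
    positive/bright (≥ convention)."""
    out = records.copy()
    lin_pos = out["od_lineage"].to_numpy() >= thresholds.lineage_positivity_od
    bright = out["od_tet"].to_numpy() >= thresholds.tet_dim_bright_od
    phenotype = np.where(
        lin_pos,
        np.where(bright, "lin_pos_bright", "lin_pos_dim"),
        np.where(bright, "lin_neg_bright", "lin_neg_dim"),
    )
    out["lineage_positive"] = lin_pos
    out["tet_bright"] = bright
    out["phenotype"] = phenotype
    return out


def qc_filter_images(
    tissue_fractions: dict[str, float], min_tissue_fraction: float = 0.10
) -> tuple[list[str], list[str], list[ImageQC]]:
    """Drop images with less than ``min_tissue_fraction`` tissue (strict <).

    Returns (kept ids, dropped ids, per-image QC records), input order
    preserved.
    """
    kept, dropped, qc = [], [], []
    for image_id, fraction in tissue_fractions.items():
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"{image_id}: tissue fraction {fraction} outside [0, 1]")
        passed = fraction >= min_tissue_fraction
        qc.append(ImageQC(image_id=image_id, tissue_fraction=fraction, passed=passed))
        (kept if passed else dropped).append(image_id)
    return kept, dropped, qc


class PhenotypeScorer(BaseEstimator):
    """Estimator-style four-class scorer.

    ``fit`` derives the batch thresholds from control cells in a record
    table; ``predict`` returns the phenotype per record (``transform``
    returns the scored table). One fitted scorer is shared across all
    images of a staining batch.
    """

    def __init__(
        self,
        control_selector=("other",),
        percentile_tet: float = 95.0,
        percentile_lineage: float = 99.0,
        min_control_cells: int = 50,
    ):
        self.control_selector = control_selector
        self.percentile_tet = percentile_tet
        self.percentile_lineage = percentile_lineage
        self.min_control_cells = min_control_cells

    def fit(self, X: pd.DataFrame, y=None) -> "PhenotypeScorer":
        self.thresholds_ = derive_thresholds(
            X,
            control_selector=self.control_selector,
            percentile_tet=self.percentile_tet,
            percentile_lineage=self.percentile_lineage,
            min_control_cells=self.min_control_cells,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("PhenotypeScorer is not fitted")
        return score_cells(X, self.thresholds_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.transform(X)["phenotype"].to_numpy()


def warn_low_n(records: pd.DataFrame, group_cols=("region",), minimum: int = LOW_N_WARNING):
    """Emit a warning for any stratum with fewer than ``minimum`` cells."""
    flagged = []
    for key, group in records.groupby(list(group_cols)):
        if len(group) < minimum:
            flagged.append((key, len(group)))
    if flagged:
        warnings.warn(f"low-n strata (<{minimum} cells): {flagged}", stacklevel=2)
    return flagged
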