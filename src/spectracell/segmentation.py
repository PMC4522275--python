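"""Cell segmentation and tissue-region classification.

Individual cells are segmented from the nuclear-counterstain abundance
map by the classic pipeline: Gaussian smoothing, Otsu threshold,
Euclidean distance transform, peak seeds, marker-controlled watershed,
and an area filter. Touching nuclei with distinct distance peaks are
split.

Tissue regions (B-cell follicle, T zone, stroma, other) are classified
per square tile from simple composition features — mean abundance per
endmember, nucleus density, mean nucleus area, tissue coverage — with a
Gaussian class-conditional model (per-feature variances with a shared
ridge floor, or a pooled covariance), trained on labeled tiles from a
handful of representative images and rasterized back to a pixel mask.
Tiles with too little tissue are labeled background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator, ClassifierMixin

from .synthetic import REGION_CODES, REGION_NAMES
from .unmixing import AbundanceMap

__all__ = [
    "CellLabelMap",
    "SegmentationParams",
    "segment_nuclei",
    "extract_tile_features",
    "TissueClassifier",
    "train_tissue_classifier",
    "classify_tissue",
    "compute_tissue_fraction",
    "tile_labels_from_region_mask",
    "FEATURE_BASE_NAMES",
]

#: priority order for posterior ties (earlier wins)
CLASS_PRIORITY = ["follicle", "t_zone", "stroma", "other"]

FEATURE_BASE_NAMES = ["cell_density_per_1000px2", "mean_cell_area_px2", "tissue_fraction"]


@dataclass
class SegmentationParams:
    smooth_sigma: float = 0.8
    threshold_method: str = "otsu"
    min_area: int = 12
    max_area: int = 400
    min_peak_distance: int = 3

    def __post_init__(self) -> None:
        if self.smooth_sigma < 0 or self.min_area <= 0 or self.max_area <= 0:
            raise ValueError("segmentation parameters must be positive")
        if self.min_peak_distance < 1:
            raise ValueError("min_peak_distance must be ≥ 1")
        if self.threshold_method not in ("otsu",):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")


@dataclass
class CellLabelMap:
    """Labeled cells: 0 = background, labels 1..N contiguous."""

    labels: np.ndarray  # H×W int32
    table: pd.DataFrame  # cell_id, y, x, area_px2, eq_radius_px

    @property
    def n_cells(self) -> int:
        return len(self.table)


def _empty_cells(shape) -> CellLabelMap:
    return CellLabelMap(
        labels=np.zeros(shape, dtype=np.int32),
        table=pd.DataFrame(columns=["cell_id", "y", "x", "area_px2", "eq_radius_px"]),
    )


def segment_nuclei(
    nuclear_abundance: np.ndarray, params: SegmentationParams | None = None
) -> CellLabelMap:
    """Watershed segmentation of nuclei from the nuclear abundance map."""
    if params is None:
        params = SegmentationParams()
    img = np.asarray(nuclear_abundance, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("nuclear abundance map must be 2-D")
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite values in nuclear abundance map")
    if img.max() <= 0:
        return _empty_cells(img.shape)
    smoothed = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
    if np.isclose(smoothed.max(), smoothed.min()):
        return _empty_cells(img.shape)
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    if not mask.any():
        return _empty_cells(img.shape)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=params.min_peak_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        return _empty_cells(img.shape)
    labels = watershed(-distance, markers=markers, mask=mask, connectivity=1)

    # area filter, then relabel contiguously
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[(counts >= params.min_area) & (counts <= params.max_area)]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1)
    labels = lut[labels]

    if labels.max() == 0:
        return _empty_cells(img.shape)
    index = np.arange(1, labels.max() + 1)
    centroids = ndi.center_of_mass(np.ones_like(labels), labels, index)
    areas = ndi.sum_labels(np.ones_like(labels), labels, index)
    table = pd.DataFrame(
        {
            "cell_id": index,
            "y": [c[0] for c in centroids],
            "x": [c[1] for c in centroids],
            "area_px2": areas.astype(int),
            "eq_radius_px": np.sqrt(areas / np.pi),
        }
    )
    return CellLabelMap(labels=labels.astype(np.int32), table=table)


def _tile_grid(shape: tuple[int, int], tile_size: int):
    h, w = shape
    for ty in range(0, h, tile_size):
        for tx in range(0, w, tile_size):
            yield ty, tx, min(ty + tile_size, h), min(tx + tile_size, w)


def extract_tile_features(
    abundances: AbundanceMap,
    cells: CellLabelMap | None,
    tile_size: int = 32,
    tissue_od_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-tile composition features over an edge-truncated tile grid.

    Columns: tile_y, tile_x (top-left corner), ``mean_<endmember>`` per
    library channel, nucleus density per 1000 px², mean nucleus area and
    fraction of pixels whose summed abundance exceeds the tissue
    threshold.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be ≥ 1")
    data = abundances.data
    total = abundances.total()
    h, w = total.shape
    cell_y = cell_x = cell_area = np.empty(0)
    if cells is not None and cells.n_cells:
        cell_y = cells.table["y"].to_numpy()
        cell_x = cells.table["x"].to_numpy()
        cell_area = cells.table["area_px2"].to_numpy(dtype=float)
    rows = []
    for ty, tx, ty1, tx1 in _tile_grid((h, w), tile_size):
        npix = (ty1 - ty) * (tx1 - tx)
        in_tile = np.empty(0, dtype=bool)
        if cell_y.size:
            in_tile = (cell_y >= ty) & (cell_y < ty1) & (cell_x >= tx) & (cell_x < tx1)
        n_cells = int(in_tile.sum()) if in_tile.size else 0
        row = {"tile_y": ty, "tile_x": tx}
        for ki, name in enumerate(abundances.endmember_names):
            row[f"mean_{name}"] = float(data[ty:ty1, tx:tx1, ki].mean())
        row["cell_density_per_1000px2"] = 1000.0 * n_cells / npix
        row["mean_cell_area_px2"] = float(cell_area[in_tile].mean()) if n_cells else 0.0
        row["tissue_fraction"] = float((total[ty:ty1, tx:tx1] > tissue_od_threshold).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def feature_columns(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns if c not in ("tile_y", "tile_x", "label")]


def tile_labels_from_region_mask(
    region_mask: np.ndarray, tile_size: int = 32, min_tissue_fraction: float = 0.5
) -> pd.DataFrame:
    """Majority ground-truth region label per tile (training-label helper).

    Tiles whose majority class is background, or with less than
    ``min_tissue_fraction`` tissue, get label ``"background"``.
    """
    rows = []
    for ty, tx, ty1, tx1 in _tile_grid(region_mask.shape, tile_size):
        patch = region_mask[ty:ty1, tx:tx1]
        tissue = patch[patch != REGION_CODES["background"]]
        if tissue.size < min_tissue_fraction * patch.size:
            label = "background"
        else:
            codes, counts = np.unique(tissue, return_counts=True)
            label = REGION_NAMES[int(codes[np.argmax(counts)])]
        rows.append({"tile_y": ty, "tile_x": tx, "label": label})
    return pd.DataFrame(rows)


class TissueClassifier(BaseEstimator, ClassifierMixin):
    """Gaussian class-conditional tissue classifier over tile features.

    Parameters
    ----------
    covariance:
        ``"diag"`` — per-class per-feature variances; ``"pooled"`` — one
        full covariance shared by all classes (linear-discriminant
        geometry). Both get a shared ridge floor for stability.
    var_ridge:
        Variance floor, as a fraction of the pooled per-feature variance.
    """

    def __init__(self, covariance: str = "diag", var_ridge: float = 1e-3):
        self.covariance = covariance
        self.var_ridge = var_ridge

    def fit(self, X, y) -> "TissueClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        classes = [c for c in CLASS_PRIORITY if c in set(y)]
        classes += sorted(set(y) - set(classes))
        if len(classes) < 2:
            raise ValueError(f"need ≥2 classes with training tiles, got {classes}")
        counts = {c: int((y == c).sum()) for c in classes}
        empty = [c for c, n in counts.items() if n == 0]
        if empty:
            raise ValueError(f"classes with zero training tiles: {empty}")
        pooled_var = X.var(axis=0) + 1e-12
        floor = self.var_ridge * pooled_var + 1e-12
        self.classes_ = np.array(classes, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.means_ = np.vstack([X[y == c].mean(axis=0) for c in classes])
        self.priors_ = np.array([counts[c] / len(y) for c in classes])
        if self.covariance == "diag":
            self.vars_ = np.vstack(
                [np.maximum(X[y == c].var(axis=0), floor) for c in classes]
            )
        elif self.covariance == "pooled":
            centered = X - self.means_[[classes.index(c) for c in y]]
            cov = centered.T @ centered / max(len(y) - len(classes), 1)
            cov[np.diag_indices_from(cov)] = np.maximum(np.diag(cov), floor)
            self.pooled_cov_inv_ = np.linalg.pinv(cov)
            self.pooled_cov_logdet_ = float(np.linalg.slogdet(cov + np.eye(len(cov)) * 1e-12)[1])
        else:
            raise ValueError(f"unknown covariance model {self.covariance!r}")
        return self

    def _log_likelihood(self, X: np.ndarray) -> np.ndarray:
        n_classes = len(self.classes_)
        ll = np.empty((len(X), n_classes))
        for i in range(n_classes):
            diff = X - self.means_[i]
            if self.covariance == "diag":
                ll[:, i] = -0.5 * np.sum(diff**2 / self.vars_[i] + np.log(self.vars_[i]), axis=1)
            else:
                ll[:, i] = -0.5 * (
                    np.einsum("ij,jk,ik->i", diff, self.pooled_cov_inv_, diff)
                    + self.pooled_cov_logdet_
                )
        return ll + np.log(self.priors_)[None, :]

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "classes_"):
            raise RuntimeError("TissueClassifier is not fitted")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature count {X.shape[1]} does not match training ({self.n_features_in_})"
            )
        scores = self._log_likelihood(X)
        # argmax returns the first maximum; classes_ is in priority order,
        # so ties break follicle > t_zone > stroma > other
        return self.classes_[np.argmax(scores, axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        scores = self._log_likelihood(np.asarray(X, dtype=float))
        scores -= scores.max(axis=1, keepdims=True)
        p = np.exp(scores)
        return p / p.sum(axis=1, keepdims=True)

    def to_json(self) -> dict:
        out = {
            "covariance": self.covariance,
            "var_ridge": self.var_ridge,
            "classes": self.classes_.tolist(),
            "means": self.means_.tolist(),
            "priors": self.priors_.tolist(),
        }
        if self.covariance == "diag":
            out["vars"] = self.vars_.tolist()
        else:
            out["pooled_cov_inv"] = self.pooled_cov_inv_.tolist()
            out["pooled_cov_logdet"] = self.pooled_cov_logdet_
        return out

    @classmethod
    def from_json(cls, d: dict) -> "TissueClassifier":
        model = cls(covariance=d["covariance"], var_ridge=d["var_ridge"])
        model.classes_ = np.array(d["classes"], dtype=object)
        model.means_ = np.asarray(d["means"], dtype=float)
        model.priors_ = np.asarray(d["priors"], dtype=float)
        model.n_features_in_ = model.means_.shape[1]
        if model.covariance == "diag":
            model.vars_ = np.asarray(d["vars"], dtype=float)
        else:
            model.pooled_cov_inv_ = np.asarray(d["pooled_cov_inv"], dtype=float)
            model.pooled_cov_logdet_ = float(d["pooled_cov_logdet"])
        return model


def train_tissue_classifier(
    labeled_tiles: pd.DataFrame, covariance: str = "diag"
) -> TissueClassifier:
    """Fit a :class:`TissueClassifier` from a labeled tile-feature table.

    ``labeled_tiles`` must carry feature columns plus a ``label`` column;
    background tiles are excluded from training.
    """
    if "label" not in labeled_tiles.columns:
        raise ValueError("labeled_tiles needs a 'label' column")
    tiles = labeled_tiles[labeled_tiles["label"] != "background"]
    cols = feature_columns(labeled_tiles)
    model = TissueClassifier(covariance=covariance)
    model.fit(tiles[cols].to_numpy(dtype=float), tiles["label"].to_numpy())
    model.feature_names_ = cols
    return model


def classify_tissue(
    model: TissueClassifier,
    features: pd.DataFrame,
    image_shape: tuple[int, int],
    tile_size: int = 32,
    background_tissue_cutoff: float = 0.2,
) -> np.ndarray:
    """Rasterize per-tile class predictions back to a pixel region mask.

    Tiles whose tissue-coverage feature is below
    ``background_tissue_cutoff`` are labeled background without
    consulting the model.
    """
    cols = getattr(model, "feature_names_", None) or feature_columns(features)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"features missing columns {missing}")
    X = features[cols].to_numpy(dtype=float)
    predictions = model.predict(X)
    mask = np.zeros(image_shape, dtype=np.uint8)
    tissue_frac = features["tissue_fraction"].to_numpy(dtype=float)
    for i, row in enumerate(features.itertuples(index=False)):
        ty, tx = int(row.tile_y), int(row.tile_x)
        if tissue_frac[i] < background_tissue_cutoff:
            code = REGION_CODES["background"]
        else:
            code = REGION_CODES.get(str(predictions[i]), REGION_CODES["other"])
        mask[ty : ty + tile_size, tx : tx + tile_size] = code
    return mask


def compute_tissue_fraction(abundances_or_od, tissue_od_threshold: float = 0.05) -> float:
    """Fraction of pixels whose summed signal exceeds the tissue threshold.

    Operationalizes the "at least 10% tissue" image-QC rule: the caller
    compares the returned fraction against the QC minimum.
    """
    if tissue_od_threshold <= 0:
        raise ValueError("tissue_od_threshold must be positive")
    if isinstance(abundances_or_od, AbundanceMap):
        total = abundances_or_od.total()
    else:
        data = abundances_or_od.data if hasattr(abundances_or_od, "data") else abundances_or_od
        total = np.asarray(data).sum(axis=2) if np.asarray(data).ndim == 3 else np.asarray(data)
    return float((total > tissue_od_threshold).mean())
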