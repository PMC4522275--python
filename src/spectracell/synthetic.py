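"""Synthetic multispectral lymphoid-tissue scenes with full ground truth.

The generator emulates a chromogenically triple-stained lymphoid section
imaged as a multispectral cube: a nuclear counterstain (Nuclear-Red-like)
confined to disk-shaped nuclei, plus a lineage marker (Warp-Red-like,
CD3/CD20 surrogate) and a tetraspanin marker (True-Blue-like, CD37/CD53
surrogate) deposited on membrane annuli around each nucleus. The tissue
is laid out as a B-cell-follicle disk, an optional surrounding T-zone
ring, a stromal remainder (red-pulp/lamina-propria surrogate) and a
marker-negative "other" band (vessels/collagen) that provides the
negative-control cells used for threshold derivation downstream.

Image formation is Beer–Lambert in brightfield mode,

    I(x, b) = I0 · 10^(−Σ_k a_k(x) · s_k(b)) + noise,

and additive in fluorescence mode (with an optional autofluorescence
term). Every cell's class, optical-density level and footprint are
recorded in a :class:`GroundTruth` so each downstream stage can be
scored against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cube import BRIGHTFIELD, FLUORESCENCE, MultispectralCube

__all__ = [
    "REGION_CODES",
    "REGION_NAMES",
    "EndmemberSet",
    "SceneConfig",
    "GroundTruth",
    "SceneError",
    "generate_endmember_set",
    "default_endmembers",
    "autofluorescence_spectrum",
    "generate_scene",
    "render_cube",
    "single_stain_cube",
]

REGION_CODES = {"background": 0, "follicle": 1, "t_zone": 2, "stroma": 3, "other": 4}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}

TISSUE_REGIONS = ("follicle", "t_zone", "stroma", "other")


class SceneError(ValueError):
    """Raised when a scene request is geometrically or spectrally infeasible."""


def spectral_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two spectra in degrees, arccos(⟨a,b⟩ / (‖a‖‖b‖))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("zero-norm spectrum has no defined angle")
    cosang = np.clip(np.dot(a, b) / denom, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class EndmemberSet:
    """K peak-normalized endmember spectra over B bands."""

    names: list[str]
    wavelengths_nm: np.ndarray
    spectra: np.ndarray  # K×B, each row max == 1
    mode: str = BRIGHTFIELD

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a K×B matrix")
        k, b = self.spectra.shape
        if k != len(self.names):
            raise ValueError("one name per spectrum required")
        if b != self.wavelengths_nm.size:
            raise ValueError("spectra band count must match wavelengths")
        if b < k:
            raise ValueError(f"need at least as many bands ({b}) as endmembers ({k})")
        if np.any(self.spectra < 0):
            raise ValueError("spectra must be non-negative")
        rowmax = self.spectra.max(axis=1)
        if np.any(np.abs(rowmax - 1.0) > 1e-12):
            raise ValueError("each spectrum must be peak-normalized to 1")

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def __len__(self) -> int:
        return self.spectra.shape[0]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown endmember {name!r}; have {self.names}") from None

    def pairwise_angles_deg(self) -> np.ndarray:
        k = len(self)
        angles = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                angles[i, j] = angles[j, i] = spectral_angle_deg(
                    self.spectra[i], self.spectra[j]
                )
        return angles


def _gaussian_bump(wavelengths: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wavelengths - center) / width) ** 2)


def _peak_normalize(spectra: np.ndarray) -> np.ndarray:
    rowmax = spectra.max(axis=1, keepdims=True)
    if np.any(rowmax <= 0):
        raise ValueError("cannot peak-normalize a non-positive spectrum")
    return spectra / rowmax


def _rotate_towards(anchor: np.ndarray, aux: np.ndarray, angle_deg: float) -> np.ndarray:
    """Unit vector at exactly ``angle_deg`` from ``anchor`` in span(anchor, aux)."""
    a = anchor / np.linalg.norm(anchor)
    u = aux - np.dot(aux, a) * a
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        raise ValueError("auxiliary direction is collinear with anchor")
    u = u / norm
    theta = np.radians(angle_deg)
    return np.cos(theta) * a + np.sin(theta) * u


def generate_endmember_set(
    n_bands: int,
    names: list[str],
    min_pair_angle_deg: float = 20.0,
    similar_pair: tuple[str, str, float] | None = None,
    mode: str = BRIGHTFIELD,
    wavelength_range: tuple[float, float] = (420.0, 720.0),
    seed: int = 0,
    max_tries: int = 300,
) -> EndmemberSet:
    """Generate smooth (sum-of-Gaussians) peak-normalized endmember spectra.

    All pairwise spectral angles are at least ``min_pair_angle_deg``
    except a designated ``similar_pair`` ``(name_a, name_b, angle_deg)``,
    whose achieved angle is within 0.5° of the request — emulating a
    chromogen pair with highly similar spectra (e.g. two red chromogens).

    Raises
    ------
    SceneError
        If no spectrum set satisfying the requested angles is found; the
        message reports the best achieved angles.
    """
    names = list(names)
    k = len(names)
    if k < 1:
        raise ValueError("need at least one endmember name")
    if n_bands < k:
        raise SceneError(f"n_bands={n_bands} < {k} endmembers")
    if not 0 < min_pair_angle_deg <= 90:
        raise ValueError("min_pair_angle_deg must be in (0, 90]")
    if similar_pair is not None:
        sa, sb, sangle = similar_pair
        if sa not in names or sb not in names or sa == sb:
            raise ValueError("similar_pair must name two distinct endmembers")
        if not 0 < sangle <= 90:
            raise ValueError("similar_pair angle must be in (0, 90]")

    wavelengths = np.linspace(*wavelength_range, n_bands)
    span = wavelength_range[1] - wavelength_range[0]
    rng = np.random.default_rng(seed)

    # names generated independently (the similar pair's second member is
    # constructed by rotation from its partner, not sampled)
    free_names = names if similar_pair is None else [n for n in names if n != similar_pair[1]]

    best_report: str = ""
    for _ in range(max_tries):
        base = dict(zip(free_names, _sample_smooth_spectra(rng, wavelengths, span, len(free_names))))
        spectra = {}
        ok = True
        for name in free_names:
            spectra[name] = base[name]
        if similar_pair is not None:
            sa, sb, sangle = similar_pair
            partner = spectra[sa]
            built = None
            for _aux in range(24):
                aux_center = rng.uniform(*wavelength_range)
                aux = _gaussian_bump(wavelengths, aux_center, rng.uniform(0.1, 0.3) * span)
                try:
                    cand = _rotate_towards(partner, aux, sangle)
                except ValueError:
                    continue
                cand = np.clip(cand, 0.0, None)
                if cand.max() <= 0:
                    continue
                if abs(spectral_angle_deg(partner, cand) - sangle) <= 0.5:
                    built = cand
                    break
            if built is None:
                ok = False
            else:
                spectra[sb] = built
        if not ok:
            continue
        mat = np.vstack([spectra[n] for n in names])
        mat = _peak_normalize(mat)
        angles = EndmemberSet(names, wavelengths, mat, mode=mode).pairwise_angles_deg()
        ok = True
        for i in range(k):
            for j in range(i + 1, k):
                pair = {names[i], names[j]}
                if similar_pair is not None and pair == {similar_pair[0], similar_pair[1]}:
                    if abs(angles[i, j] - similar_pair[2]) > 0.5:
                        ok = False
                elif angles[i, j] < min_pair_angle_deg:
                    ok = False
        if ok:
            return EndmemberSet(names, wavelengths, mat, mode=mode)
        best_report = np.array2string(angles, precision=2)
    raise SceneError(
        f"could not satisfy requested angles with n_bands={n_bands}; "
        f"last achieved pairwise angles (deg):\n{best_report}"
    )


def _sample_smooth_spectra(rng, wavelengths, span, n) -> list[np.ndarray]:
    lo, hi = wavelengths[0], wavelengths[-1]
    # spread primary peaks across the range, with jitter, in random order
    centers = np.linspace(lo + 0.1 * span, hi - 0.1 * span, max(n, 1))
    centers = rng.permutation(centers) + rng.uniform(-0.05 * span, 0.05 * span, size=max(n, 1))
    out = []
    for c in centers[:n]:
        width = rng.uniform(0.08, 0.18) * span
        spec = _gaussian_bump(wavelengths, c, width)
        # secondary shoulder keeps spectra realistic (chromogens are broad)
        spec = spec + rng.uniform(0.0, 0.3) * _gaussian_bump(
            wavelengths, c + rng.uniform(-0.3, 0.3) * span, rng.uniform(0.1, 0.2) * span
        )
        out.append(spec)
    return out


def default_endmembers(n_bands: int = 16, seed: int = 7, mode: str = BRIGHTFIELD) -> EndmemberSet:
    """The default 3-chromogen library: Nuclear-Red-, Warp-Red- and
    True-Blue-like spectra over 16 bands (420–720 nm), with the two red
    chromogens deliberately near-collinear at 8°."""
    return generate_endmember_set(
        n_bands=n_bands,
        names=["nuclear_red", "warp_red", "true_blue"],
        min_pair_angle_deg=25.0,
        similar_pair=("nuclear_red", "warp_red", 8.0),
        mode=mode,
        seed=seed,
    )


def autofluorescence_spectrum(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Broad, blue-weighted unit-peak autofluorescence shape."""
    w = np.asarray(wavelengths_nm, dtype=float)
    spec = np.exp(-(w - w[0]) / (0.45 * (w[-1] - w[0] + 1e-9)))
    return spec / spec.max()


@dataclass
class SceneConfig:
    """Parameters of one synthetic tissue scene.

    Defaults describe a 20×-field-like lymphoid section: one follicle
    with a surrounding T zone embedded in stroma, a marker-negative
    control band, ~1600 nuclei, dim/bright tetraspanin levels drawn from
    well-separated log-normal modes, and 1% Gaussian intensity noise.
    """

    image_shape: tuple[int, int] = (576, 576)
    margin_px: int = 32
    control_band_px: int = 64
    n_follicles: int = 1
    follicle_radius_px: float = 110.0
    include_t_zone: bool = True
    t_zone_width_px: float = 90.0

    mode: str = BRIGHTFIELD
    i0: float = 255.0
    noise_sd_frac: float = 0.01
    poisson_noise: bool = False
    af_amplitude: float = 0.0

    cell_density: dict = field(
        default_factory=lambda: {"follicle": 9.0, "t_zone": 8.5, "stroma": 4.0, "other": 2.5}
    )
    lineage_positive_fraction: dict = field(
        default_factory=lambda: {"follicle": 0.9, "t_zone": 0.1, "stroma": 0.45, "other": 0.0}
    )
    bright_fraction: dict = field(
        default_factory=lambda: {"follicle": 0.85, "t_zone": 0.55, "stroma": 0.45, "other": 0.0}
    )
    nucleus_radius_median: dict = field(
        default_factory=lambda: {"follicle": 3.8, "t_zone": 3.8, "stroma": 5.4, "other": 6.5}
    )
    nucleus_radius_sigma: float = 0.12
    membrane_width_px: float = 3.0
    max_overlap_frac: float = 0.10

    dim_od_median: float = 0.035
    dim_od_sigma: float = 0.25
    bright_od_median: float = 0.30
    bright_od_sigma: float = 0.30
    lineage_pos_od_median: float = 0.40
    lineage_pos_od_sigma: float = 0.30
    lineage_neg_od_median: float = 0.03
    lineage_neg_od_sigma: float = 0.25
    nuclear_od_median: float = 0.60
    nuclear_od_sigma: float = 0.15
    # background staining of non-immune cells in the marker-negative
    # control region sits slightly above the immune dim mode (stromal and
    # vascular structures bind chromogen nonspecifically), making the
    # control percentile a conservative upper bound of background
    control_tet_od_median: float = 0.06
    control_tet_od_sigma: float = 0.30
    control_lineage_od_median: float = 0.05
    control_lineage_od_sigma: float = 0.30

    nuclear_channel: str = "nuclear_red"
    lineage_channel: str = "warp_red"
    tetraspanin_channel: str = "true_blue"

    image_id: str = "scene"
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError("image_shape must be positive")
        if self.i0 <= 0:
            raise ValueError("i0 must be positive")
        for name in ("lineage_positive_fraction", "bright_fraction"):
            for region, frac in getattr(self, name).items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"{name}[{region}] = {frac} outside [0, 1]")
        for region, dens in self.cell_density.items():
            if dens < 0:
                raise ValueError(f"cell_density[{region}] must be ≥ 0")
        if self.mode not in (BRIGHTFIELD, FLUORESCENCE):
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(int(v) for v in d["image_shape"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Full per-scene truth: region layout, cell table and abundance maps.

    ``cells`` columns: id, y, x, radius, region, lineage_class (lin_pos /
    lin_neg), tet_class (dim / bright), od_lineage, od_tet, od_nuclear.
    """

    region_mask: np.ndarray  # H×W uint8, values in REGION_CODES
    cells: pd.DataFrame
    abundances: np.ndarray  # H×W×K true optical densities
    endmember_names: list[str]
    config: SceneConfig

    def __post_init__(self) -> None:
        h, w = self.region_mask.shape
        if len(self.cells):
            ys = self.cells["y"].to_numpy()
            xs = self.cells["x"].to_numpy()
            if ys.min() < 0 or ys.max() >= h or xs.min() < 0 or xs.max() >= w:
                raise ValueError("cell centroid outside image")
        if self.abundances.size and float(self.abundances.min()) < 0:
            raise ValueError("abundance maps must be non-negative")

    def region_name_at(self, y: float, x: float) -> str:
        return REGION_NAMES[int(self.region_mask[int(round(y)), int(round(x))])]

    def n_cells(self) -> int:
        return len(self.cells)


def _build_region_mask(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.image_shape
    m = config.margin_px
    mask = np.zeros((h, w), dtype=np.uint8)
    if h - 2 * m <= 0 or w - 2 * m <= 0:
        raise SceneError("margin leaves no tissue")
    mask[m : h - m, m : w - m] = REGION_CODES["stroma"]
    band = config.control_band_px
    if band > 0:
        mask[m : min(m + band, h - m), m : w - m] = REGION_CODES["other"]
    yy, xx = np.mgrid[0:h, 0:w]
    outer_extra = config.t_zone_width_px if config.include_t_zone else 0.0
    outer_r = config.follicle_radius_px + outer_extra
    y_lo, y_hi = m + band + outer_r, h - m - outer_r
    x_lo, x_hi = m + outer_r, w - m - outer_r
    if config.n_follicles > 0 and (y_hi < y_lo or x_hi < x_lo):
        raise SceneError("follicle (with T zone) does not fit inside the tissue area")
    centers: list[tuple[float, float]] = []
    for _ in range(config.n_follicles):
        placed = False
        for _attempt in range(400):
            cy = rng.uniform(y_lo, y_hi)
            cx = rng.uniform(x_lo, x_hi)
            if all(np.hypot(cy - py, cx - px) >= 2 * outer_r + 8 for py, px in centers):
                centers.append((cy, cx))
                placed = True
                break
        if not placed:
            raise SceneError(
                f"could not place {config.n_follicles} follicles of outer radius "
                f"{outer_r:.0f}px in a {h}×{w} scene"
            )
    for cy, cx in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        if config.include_t_zone:
            ring = (d2 <= outer_r**2) & (mask == REGION_CODES["stroma"])
            mask[ring] = REGION_CODES["t_zone"]
        disk = (d2 <= config.follicle_radius_px**2) & (mask != REGION_CODES["background"])
        mask[disk] = REGION_CODES["follicle"]
    return mask


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size: int) -> np.ndarray:
    return median * np.exp(sigma * rng.standard_normal(size))


def _place_cells(
    config: SceneConfig, region_mask: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    grid: dict[tuple[int, int], list[int]] = {}
    gsize = 16
    placed_y: list[float] = []
    placed_x: list[float] = []
    placed_r: list[float] = []
    min_gap = 1.0 - config.max_overlap_frac
    cell_id = 0
    for region in TISSUE_REGIONS:
        code = REGION_CODES[region]
        pix = np.argwhere(region_mask == code)
        if pix.size == 0:
            continue
        density = config.cell_density.get(region, 0.0)
        n_target = int(round(density * len(pix) / 1000.0))
        if n_target == 0:
            continue
        radii = _lognormal(
            rng, config.nucleus_radius_median[region], config.nucleus_radius_sigma, n_target
        )
        placed = 0
        attempts = 0
        max_attempts = 80 * n_target
        while placed < n_target and attempts < max_attempts:
            attempts += 1
            y, x = pix[rng.integers(len(pix))]
            y = float(y)
            x = float(x)
            r = float(radii[placed])
            gy, gx = int(y // gsize), int(x // gsize)
            ok = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for idx in grid.get((gy + dy, gx + dx), ()):
                        if np.hypot(y - placed_y[idx], x - placed_x[idx]) < min_gap * (
                            r + placed_r[idx]
                        ):
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                continue
            idx = len(placed_y)
            placed_y.append(y)
            placed_x.append(x)
            placed_r.append(r)
            grid.setdefault((gy, gx), []).append(idx)
            rows.append({"id": cell_id, "y": y, "x": x, "radius": r, "region": region})
            cell_id += 1
            placed += 1
        if placed < n_target:
            raise SceneError(
                f"cell density {density}/1000px² too high for region {region!r}: "
                f"placed {placed}/{n_target} nuclei"
            )
    return pd.DataFrame(rows, columns=["id", "y", "x", "radius", "region"])


def _assign_classes(
    config: SceneConfig, cells: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(cells)
    lin = np.empty(n, dtype=object)
    tet = np.empty(n, dtype=object)
    od_lineage = np.empty(n)
    od_tet = np.empty(n)
    od_nuclear = _lognormal(rng, config.nuclear_od_median, config.nuclear_od_sigma, n)
    for region in TISSUE_REGIONS:
        sel = (cells["region"] == region).to_numpy()
        k = int(sel.sum())
        if k == 0:
            continue
        lin_pos = rng.random(k) < config.lineage_positive_fraction.get(region, 0.0)
        bright = rng.random(k) < config.bright_fraction.get(region, 0.0)
        lin[sel] = np.where(lin_pos, "lin_pos", "lin_neg")
        tet[sel] = np.where(bright, "bright", "dim")
        if region == "other":
            neg_lin = _lognormal(
                rng, config.control_lineage_od_median, config.control_lineage_od_sigma, k
            )
            neg_tet = _lognormal(
                rng, config.control_tet_od_median, config.control_tet_od_sigma, k
            )
        else:
            neg_lin = _lognormal(
                rng, config.lineage_neg_od_median, config.lineage_neg_od_sigma, k
            )
            neg_tet = _lognormal(rng, config.dim_od_median, config.dim_od_sigma, k)
        od_lin = np.where(
            lin_pos,
            _lognormal(rng, config.lineage_pos_od_median, config.lineage_pos_od_sigma, k),
            neg_lin,
        )
        od_t = np.where(
            bright,
            _lognormal(rng, config.bright_od_median, config.bright_od_sigma, k),
            neg_tet,
        )
        od_lineage[sel] = od_lin
        od_tet[sel] = od_t
    out = cells.copy()
    out["lineage_class"] = lin
    out["tet_class"] = tet
    out["od_lineage"] = od_lineage
    out["od_tet"] = od_tet
    out["od_nuclear"] = od_nuclear
    return out


def _rasterize_abundances(
    config: SceneConfig, cells: pd.DataFrame, endmembers: EndmemberSet
) -> np.ndarray:
    """Paint nuclear OD on disks and membrane OD on each cell's exclusive
    membrane territory.

    The membrane ring is the band of pixels within ``membrane_width_px``
    of a cell's nucleus that are nearer to it than to any other nucleus
    (nearest-cell territory), so chromogen from one cell never bleeds
    into a neighbor's membrane compartment even in densely packed tissue.
    Lineage and tetraspanin OD add linearly on those shared ring pixels.
    """
    from skimage.segmentation import expand_labels

    h, w = config.image_shape
    k_nuc = endmembers.index(config.nuclear_channel)
    k_lin = endmembers.index(config.lineage_channel)
    k_tet = endmembers.index(config.tetraspanin_channel)
    a = np.zeros((h, w, len(endmembers)), dtype=np.float64)
    if not len(cells):
        return a
    nuclei = np.zeros((h, w), dtype=np.int32)
    for row in cells.itertuples(index=False):
        y0 = max(int(np.floor(row.y - row.radius)), 0)
        y1 = min(int(np.ceil(row.y + row.radius)) + 1, h)
        x0 = max(int(np.floor(row.x - row.radius)), 0)
        x1 = min(int(np.ceil(row.x + row.radius)) + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (yy - row.y) ** 2 + (xx - row.x) ** 2 <= row.radius**2
        a[y0:y1, x0:x1, k_nuc][disk] += row.od_nuclear
        nuclei[y0:y1, x0:x1][disk] = row.id + 1
    territory = expand_labels(nuclei, distance=config.membrane_width_px)
    ring = (territory > 0) & (nuclei == 0)
    owner = territory[ring] - 1
    od_lin = cells.set_index("id")["od_lineage"].reindex(range(len(cells))).to_numpy()
    od_tet = cells.set_index("id")["od_tet"].reindex(range(len(cells))).to_numpy()
    a[:, :, k_lin][ring] += od_lin[owner]
    a[:, :, k_tet][ring] += od_tet[owner]
    return a


def _render(
    abundances: np.ndarray,
    endmembers: EndmemberSet,
    config: SceneConfig,
    af_mask: np.ndarray | None,
    rng: np.random.Generator | None,
) -> MultispectralCube:
    if endmembers.mode != config.mode:
        raise ValueError(
            f"endmember mode {endmembers.mode!r} does not match scene mode {config.mode!r}"
        )
    h, w, k = abundances.shape
    if k != len(endmembers):
        raise ValueError("abundance maps and endmember set disagree on K")
    signal = abundances.reshape(-1, k) @ endmembers.spectra  # N×B
    signal = signal.reshape(h, w, endmembers.n_bands)
    if config.mode == BRIGHTFIELD:
        intensity = config.i0 * np.power(10.0, -signal)
    else:
        intensity = signal
        if config.af_amplitude > 0:
            af = config.af_amplitude * autofluorescence_spectrum(endmembers.wavelengths_nm)
            if af_mask is None:
                af_mask = np.ones((h, w), dtype=bool)
            intensity = intensity + af_mask[..., None] * af[None, None, :]
    if config.poisson_noise and rng is not None:
        intensity = rng.poisson(np.clip(intensity, 0, None)).astype(np.float64)
    if config.noise_sd_frac > 0 and rng is not None:
        intensity = intensity + rng.normal(0.0, config.noise_sd_frac * config.i0, intensity.shape)
    hi = config.i0 if config.mode == BRIGHTFIELD else None
    intensity = np.clip(intensity, 0.0, hi)
    return MultispectralCube(
        data=intensity.astype(np.float32),
        wavelengths_nm=endmembers.wavelengths_nm,
        mode=config.mode,
        i0=config.i0 if config.mode == BRIGHTFIELD else None,
        image_id=config.image_id,
        meta={"seed": config.seed},
    )


def render_cube(
    truth: GroundTruth,
    endmembers: EndmemberSet,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
) -> MultispectralCube:
    """Render a ground-truth scene through the forward optical model.

    Brightfield: ``I = I0·10^(−A·S) + noise`` clipped to [0, I0];
    fluorescence: ``I = A·S + AF·mask + noise`` clipped at 0. With
    ``rng=None`` the noise stream is derived from ``config.seed`` so the
    render is reproducible on its own.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    af_mask = truth.region_mask != REGION_CODES["background"]
    return _render(truth.abundances, endmembers, config, af_mask, rng)


def generate_scene(
    config: SceneConfig, endmembers: EndmemberSet
) -> tuple[GroundTruth, MultispectralCube]:
    """Generate one scene: layout → cells → classes → abundances → cube.

    All randomness derives from ``config.seed``; identical (config,
    endmembers) give bit-identical outputs.
    """
    for channel in (config.nuclear_channel, config.lineage_channel, config.tetraspanin_channel):
        endmembers.index(channel)  # raises KeyError if missing
    rng_layout = np.random.default_rng([config.seed, 0])
    rng_cells = np.random.default_rng([config.seed, 1])
    region_mask = _build_region_mask(config, rng_layout)
    cells = _place_cells(config, region_mask, rng_cells)
    cells = _assign_classes(config, cells, rng_cells)
    abundances = _rasterize_abundances(config, cells, endmembers)
    truth = GroundTruth(
        region_mask=region_mask,
        cells=cells,
        abundances=abundances,
        endmember_names=list(endmembers.names),
        config=config,
    )
    cube = render_cube(truth, endmembers, config)
    return truth, cube


def single_stain_cube(
    name: str,
    endmembers: EndmemberSet,
    config: SceneConfig | None = None,
    seed: int = 0,
    n_blobs: int = 80,
    shape: tuple[int, int] = (192, 192),
) -> MultispectralCube:
    """Render a cube stained with a single chromogen (library-building input).

    Random disk deposits of the named endmember only, passed through the
    same forward model as full scenes.
    """
    if config is None:
        config = SceneConfig(image_shape=shape, image_id=f"single_{name}", seed=seed)
    rng = np.random.default_rng([config.seed, 3])
    h, w = config.image_shape
    k = endmembers.index(name)
    a = np.zeros((h, w, len(endmembers)))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(4, 12)
        od = _lognormal(rng, 0.5, 0.3, 1)[0]
        a[:, :, k][(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] += od
    return _render(a, endmembers, config, af_mask=None, rng=rng)
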