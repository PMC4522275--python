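"""Multispectral image cubes and their TIFF serialization.

A cube is an H×W×B stack of non-negative intensities, one plane per
spectral band, acquired either in brightfield (transmitted light through
chromogens, with a white reference ``i0``) or in fluorescence mode
(emitted light, additive). Cubes are written as multi-page TIFFs with a
JSON header in the first page's description; a ``.json`` sidecar is
accepted as a fallback when the description is missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

BRIGHTFIELD = "brightfield"
FLUORESCENCE = "fluorescence"

#: intensity may exceed i0 by this relative tolerance (noise on blank pixels)
I0_TOLERANCE = 0.05


@dataclass
class MultispectralCube:
    """An H×W×B intensity stack with band wavelengths and acquisition mode.

    Parameters
    ----------
    data:
        Array of shape (H, W, B), non-negative intensities.
    wavelengths_nm:
        Strictly increasing band center wavelengths, length B.
    mode:
        ``"brightfield"`` or ``"fluorescence"``.
    i0:
        White reference (blank-field intensity) for brightfield cubes;
        scalar or per-band vector. ``None`` for fluorescence.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    mode: str
    i0: float | np.ndarray | None = None
    image_id: str = ""
    pixel_size_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be H×W×B, got shape {self.data.shape}")
        if self.data.shape[2] != self.wavelengths_nm.size:
            raise ValueError(
                f"{self.data.shape[2]} bands but {self.wavelengths_nm.size} wavelengths"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.mode not in (BRIGHTFIELD, FLUORESCENCE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("intensities must be non-negative")
        if self.mode == BRIGHTFIELD:
            if self.i0 is None:
                raise ValueError("brightfield cube requires a white reference i0")
            i0 = np.asarray(self.i0, dtype=float)
            if np.any(i0 <= 0):
                raise ValueError("i0 must be positive")
            if self.data.size and float(self.data.max()) > float(i0.max()) * (1 + I0_TOLERANCE):
                raise ValueError("brightfield intensities exceed i0 beyond tolerance")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


def _cube_header(cube: MultispectralCube) -> str:
    i0 = cube.i0
    if isinstance(i0, np.ndarray):
        i0 = i0.tolist()
    header = {
        "wavelengths_nm": cube.wavelengths_nm.tolist(),
        "mode": cube.mode,
        "i0": i0,
        "image_id": cube.image_id,
        "pixel_size_um": cube.pixel_size_um,
        "meta": cube.meta,
    }
    return json.dumps(header)


def write_cube(cube: MultispectralCube, path: str | Path) -> Path:
    """Write a cube as a multi-page float32 TIFF (one page per band)."""
    path = Path(path)
    pages = np.moveaxis(cube.data.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, description=_cube_header(cube), metadata=None,
                     photometric="minisblack")
    return path


def read_cube(path: str | Path) -> MultispectralCube:
    """Read a multi-page TIFF cube written by :func:`write_cube`.

    Wavelength/mode metadata come from the first page description; a
    sidecar ``<path>.json`` (or same stem ``.json``) is tried as fallback.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or ""
    header = None
    if desc:
        try:
            header = json.loads(desc)
        except json.JSONDecodeError:
            header = None
    if header is None or "wavelengths_nm" not in header:
        for sidecar in (path.with_suffix(path.suffix + ".json"), path.with_suffix(".json")):
            if sidecar.exists():
                header = json.loads(sidecar.read_text())
                break
    if header is None or "wavelengths_nm" not in header:
        raise ValueError(f"{path}: no wavelength metadata in TIFF description or sidecar")
    if pages.ndim == 2:
        pages = pages[None, :, :]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2-D pages, got shape {pages.shape}")
    wavelengths = np.asarray(header["wavelengths_nm"], dtype=float)
    if pages.shape[0] != wavelengths.size:
        raise ValueError(
            f"{path}: {pages.shape[0]} pages but {wavelengths.size} declared wavelengths"
        )
    i0 = header.get("i0")
    if isinstance(i0, list):
        i0 = np.asarray(i0, dtype=float)
    return MultispectralCube(
        data=np.moveaxis(pages, 0, 2),
        wavelengths_nm=wavelengths,
        mode=header.get("mode", BRIGHTFIELD),
        i0=i0,
        image_id=header.get("image_id", ""),
        pixel_size_um=header.get("pixel_size_um"),
        meta=header.get("meta", {}) or {},
    )


def write_abundance_map(amap, path: str | Path) -> Path:
    """Write an AbundanceMap as float32 TIFF: one page per endmember plus
    a final residual page; names and spectra in the description JSON."""
    path = Path(path)
    pages = np.concatenate(
        [np.moveaxis(amap.data, 2, 0), amap.residual[None, :, :]], axis=0
    ).astype(np.float32)
    header = {
        "endmember_names": list(amap.endmember_names),
        "wavelengths_nm": np.asarray(amap.wavelengths_nm).tolist(),
        "mode": amap.mode,
        "endmember_spectra": None
        if amap.endmember_spectra is None
        else np.asarray(amap.endmember_spectra).tolist(),
        "residual_page": pages.shape[0] - 1,
    }
    tifffile.imwrite(path, pages, description=json.dumps(header), metadata=None,
                     photometric="minisblack")
    return path


def read_abundance_map(path: str | Path):
    from .unmixing import AbundanceMap  # local import to avoid a cycle

    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or ""
    if not desc:
        raise ValueError(f"{path}: missing abundance metadata")
    header = json.loads(desc)
    names = header["endmember_names"]
    if pages.shape[0] != len(names) + 1:
        raise ValueError(f"{path}: expected {len(names)} abundance pages plus residual")
    spectra = header.get("endmember_spectra")
    return AbundanceMap(
        data=np.moveaxis(pages[:-1], 0, 2).astype(np.float64),
        residual=pages[-1].astype(np.float64),
        endmember_names=names,
        wavelengths_nm=np.asarray(header["wavelengths_nm"], dtype=float),
        endmember_spectra=None if spectra is None else np.asarray(spectra, dtype=float),
        mode=header.get("mode", BRIGHTFIELD),
    )


def write_label_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write an integer label image as a single-page uint16 TIFF."""
    path = Path(path)
    arr = np.asarray(mask)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label values exceed uint16 range")
    tifffile.imwrite(path, arr.astype(np.uint16), metadata=None, photometric="minisblack")
    return path


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)
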