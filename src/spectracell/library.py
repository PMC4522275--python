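"""Spectral library construction from single-stain cubes.

Each chromogen/fluorophore gets its endmember spectrum from an image of
tissue stained with that reagent alone: the brightest pixels (by total
OD in brightfield, total intensity in fluorescence) are averaged and the
mean spectrum peak-normalized. In fluorescence mode an autofluorescence
spectrum estimated from unstained tissue can be subtracted from each raw
endmember before normalization (it is kept in the library and may also
serve as an extra unmixing endmember).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cube import BRIGHTFIELD, FLUORESCENCE, MultispectralCube
from .synthetic import EndmemberSet, spectral_angle_deg
from .unmixing import DEFAULT_OD_MAX, to_optical_density

__all__ = [
    "SpectralLibrary",
    "build_library",
    "estimate_autofluorescence",
    "subtract_autofluorescence",
    "library_condition_report",
    "ConditionReport",
]


@dataclass
class SpectralLibrary:
    """Endmember spectra plus optional autofluorescence and provenance."""

    endmembers: EndmemberSet
    autofluorescence: np.ndarray | None = None
    raw_spectra: np.ndarray | None = None  # K×B pre-normalization means
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.autofluorescence is not None:
            af = np.asarray(self.autofluorescence, dtype=float)
            if af.size != self.endmembers.n_bands:
                raise ValueError("autofluorescence length must equal band count")
            if np.any(af < 0):
                raise ValueError("autofluorescence must be non-negative")
            self.autofluorescence = af

    @property
    def names(self) -> list[str]:
        return self.endmembers.names

    def to_csv(self, path: str | Path) -> Path:
        """Rows = endmembers (+ optional autofluorescence), columns = wavelengths.

        A ``.json`` sidecar stores mode and per-endmember provenance.
        """
        path = Path(path)
        cols = [f"{w:g}" for w in self.endmembers.wavelengths_nm]
        rows = {name: self.endmembers.spectra[i] for i, name in enumerate(self.names)}
        if self.autofluorescence is not None:
            rows["autofluorescence"] = self.autofluorescence
        pd.DataFrame.from_dict(rows, orient="index", columns=cols).to_csv(
            path, index_label="endmember"
        )
        sidecar = {
            "mode": self.endmembers.mode,
            "source_meta": self.source_meta,
            "raw_spectra": None if self.raw_spectra is None else self.raw_spectra.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralLibrary":
        path = Path(path)
        table = pd.read_csv(path, index_col="endmember")
        wavelengths = np.array([float(c) for c in table.columns])
        af = None
        if "autofluorescence" in table.index:
            af = table.loc["autofluorescence"].to_numpy(dtype=float)
            table = table.drop(index="autofluorescence")
        meta: dict = {}
        mode = BRIGHTFIELD
        raw = None
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            side = json.loads(sidecar.read_text())
            mode = side.get("mode", BRIGHTFIELD)
            meta = side.get("source_meta", {})
            if side.get("raw_spectra") is not None:
                raw = np.asarray(side["raw_spectra"], dtype=float)
        endmembers = EndmemberSet(
            names=list(table.index),
            wavelengths_nm=wavelengths,
            spectra=table.to_numpy(dtype=float),
            mode=mode,
        )
        return cls(endmembers=endmembers, autofluorescence=af, raw_spectra=raw, source_meta=meta)


def build_library(
    single_stain_cubes: list[tuple[str, MultispectralCube]],
    mode: str | None = None,
    foreground_quantile: float = 0.90,
    i0: float | np.ndarray | None = None,
    od_max: float = DEFAULT_OD_MAX,
) -> SpectralLibrary:
    """Build a library from one single-stain cube per endmember.

    For each cube, foreground pixels are those whose total signal
    (summed OD in brightfield, summed intensity in fluorescence) exceeds
    the ``foreground_quantile`` of that cube; the endmember is the mean
    foreground spectrum, peak-normalized to 1.
    """
    if not single_stain_cubes:
        raise ValueError("at least one single-stain cube is required")
    if mode is None:
        mode = single_stain_cubes[0][1].mode
    wavelengths = single_stain_cubes[0][1].wavelengths_nm
    names: list[str] = []
    raw_rows: list[np.ndarray] = []
    meta: dict = {}
    for name, cube in single_stain_cubes:
        if cube.mode != mode:
            raise ValueError(f"stain {name!r}: mode {cube.mode!r} differs from {mode!r}")
        if cube.wavelengths_nm.size != wavelengths.size or np.any(
            np.abs(cube.wavelengths_nm - wavelengths) > 1e-6
        ):
            raise ValueError(f"stain {name!r}: wavelengths differ between single-stain cubes")
        if mode == BRIGHTFIELD:
            signal = to_optical_density(cube, i0=i0, od_max=od_max).data
        else:
            signal = cube.data.astype(np.float64)
        total = signal.sum(axis=2)
        cutoff = float(np.quantile(total, foreground_quantile))
        foreground = total > cutoff
        if not foreground.any():
            raise ValueError(f"stain {name!r}: empty foreground after thresholding")
        mean_spec = signal[foreground].mean(axis=0)
        peak = float(mean_spec.max())
        if peak <= 0:
            raise ValueError(f"stain {name!r}: foreground spectrum is all zero")
        names.append(name)
        raw_rows.append(mean_spec)
        meta[name] = {
            "n_foreground_pixels": int(foreground.sum()),
            "foreground_threshold": cutoff,
            "foreground_quantile": foreground_quantile,
        }
    raw = np.vstack(raw_rows)
    spectra = raw / raw.max(axis=1, keepdims=True)
    endmembers = EndmemberSet(names=names, wavelengths_nm=wavelengths, spectra=spectra, mode=mode)
    return SpectralLibrary(endmembers=endmembers, raw_spectra=raw, source_meta=meta)


def estimate_autofluorescence(
    unstained_cube: MultispectralCube, tissue_mask: np.ndarray
) -> np.ndarray:
    """Per-band mean intensity of unstained tissue pixels."""
    if unstained_cube.mode != FLUORESCENCE:
        raise ValueError("autofluorescence is estimated from fluorescence cubes")
    mask = np.asarray(tissue_mask, dtype=bool)
    if mask.shape != unstained_cube.data.shape[:2]:
        raise ValueError("tissue mask shape does not match cube")
    if not mask.any():
        raise ValueError("tissue mask covers zero pixels")
    return unstained_cube.data[mask].mean(axis=0).astype(np.float64)


def subtract_autofluorescence(library: SpectralLibrary, af: np.ndarray) -> SpectralLibrary:
    """Subtract an autofluorescence spectrum from each raw endmember.

    Each pre-normalization endmember spectrum has ``af`` subtracted,
    negative bands clamped to zero, and is re-peak-normalized. The AF
    spectrum is retained in the returned library.
    """
    if library.endmembers.mode != FLUORESCENCE:
        raise ValueError("autofluorescence subtraction applies to fluorescence libraries")
    af = np.asarray(af, dtype=float)
    if af.size != library.endmembers.n_bands:
        raise ValueError("autofluorescence length must equal band count")
    if np.any(af < 0):
        raise ValueError("autofluorescence must be non-negative")
    raw = library.raw_spectra
    if raw is None:
        raw = library.endmembers.spectra
    corrected = np.clip(raw - af[None, :], 0.0, None)
    peaks = corrected.max(axis=1)
    dead = np.where(peaks <= 0)[0]
    if dead.size:
        names = [library.names[i] for i in dead]
        raise ValueError(f"autofluorescence subtraction annihilates spectrum of {names}")
    endmembers = EndmemberSet(
        names=list(library.names),
        wavelengths_nm=library.endmembers.wavelengths_nm,
        spectra=corrected / peaks[:, None],
        mode=library.endmembers.mode,
    )
    return SpectralLibrary(
        endmembers=endmembers,
        autofluorescence=af,
        raw_spectra=corrected,
        source_meta={**library.source_meta, "af_subtracted": True},
    )


@dataclass
class ConditionReport:
    names: list[str]
    angles_deg: np.ndarray  # K×K, symmetric, zero diagonal
    condition_number: float
    flagged_pairs: list[tuple[str, str, float]]  # pairs below the warn threshold
    warn_angle_deg: float


def library_condition_report(library, warn_angle_deg: float = 3.0) -> ConditionReport:
    """Pairwise spectral angles and condition number of the endmember matrix.

    Flags endmember pairs closer than ``warn_angle_deg`` — a separability
    diagnostic for near-collinear chromogen pairs.
    """
    endmembers = library.endmembers if isinstance(library, SpectralLibrary) else library
    angles = endmembers.pairwise_angles_deg()
    k = len(endmembers)
    if k == 0:
        raise ValueError("empty library")
    cond = float(np.linalg.cond(endmembers.spectra.T)) if k > 1 else 1.0
    if k == 1:
        cond = 1.0
    flagged = [
        (endmembers.names[i], endmembers.names[j], float(angles[i, j]))
        for i in range(k)
        for j in range(i + 1, k)
        if angles[i, j] < warn_angle_deg
    ]
    return ConditionReport(
        names=list(endmembers.names),
        angles_deg=angles,
        condition_number=cond,
        flagged_pairs=flagged,
        warn_angle_deg=warn_angle_deg,
    )
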