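"""Optical-density conversion and per-pixel non-negative linear unmixing.

Brightfield cubes are first converted to optical density (Beer–Lambert:
``OD = −log10(I/I0)``), in which chromogen contributions add linearly.
Each pixel's OD spectrum is then decomposed against the peak-normalized
library endmembers by non-negative least squares,

    a(x) = argmin_{a ≥ 0} ‖Sᵀ a − y(x)‖₂ ,

so a brightfield coefficient equals the chromogen's OD contribution at
its peak band — the per-cell "optical density" used downstream.
Fluorescence cubes are unmixed in raw (autofluorescence-corrected)
intensity space.

For small libraries (K ≤ 12) the cube solver enumerates all active sets
and solves each support in closed form for every pixel at once, which is
exactly the NNLS optimum and orders of magnitude faster than a per-pixel
iterative solve; :func:`unmix_pixel` wraps the classic Lawson–Hanson
routine and the two agree to solver tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.optimize

from .cube import BRIGHTFIELD, FLUORESCENCE, MultispectralCube

__all__ = [
    "ODCube",
    "AbundanceMap",
    "to_optical_density",
    "unmix_pixel",
    "unmix_cube",
    "reconstruction_residual",
    "SpectralUnmixer",
]

DEFAULT_OD_MAX = 3.0


@dataclass
class ODCube:
    """H×W×B optical densities (dimensionless absorbance)."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    i0: float | np.ndarray
    od_max: float = DEFAULT_OD_MAX

    @property
    def shape(self):
        return self.data.shape


@dataclass
class AbundanceMap:
    """H×W×K non-negative endmember coefficients plus per-pixel residual.

    Brightfield coefficients are OD at each endmember's peak band;
    fluorescence coefficients are intensity units.
    """

    data: np.ndarray  # H×W×K
    residual: np.ndarray  # H×W, ‖Sᵀa − y‖₂
    endmember_names: list[str]
    wavelengths_nm: np.ndarray
    endmember_spectra: np.ndarray | None = None  # K×B library reference
    mode: str = BRIGHTFIELD

    @property
    def shape(self):
        return self.data.shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[:, :, self.endmember_names.index(name)]
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.endmember_names}") from None

    def total(self) -> np.ndarray:
        return self.data.sum(axis=2)


def to_optical_density(
    cube: MultispectralCube,
    i0: float | np.ndarray | None = None,
    od_max: float = DEFAULT_OD_MAX,
) -> ODCube:
    """Convert a brightfield cube to optical density.

    ``OD(x,b) = −log10(max(I(x,b), ε) / I0_b)`` clamped to [0, od_max],
    with ``ε = I0·10^(−od_max)`` so saturated (zero-intensity) pixels
    land exactly on the clamp.
    """
    if cube.mode != BRIGHTFIELD:
        raise ValueError("optical density is defined for brightfield cubes only")
    if i0 is None:
        i0 = cube.i0
    i0 = np.asarray(i0, dtype=float)
    if np.any(i0 <= 0):
        raise ValueError("i0 must be positive")
    eps = i0 * 10.0 ** (-od_max)
    od = -np.log10(np.maximum(cube.data, eps) / i0)
    od = np.clip(od, 0.0, od_max)
    return ODCube(data=od, wavelengths_nm=cube.wavelengths_nm, i0=i0, od_max=od_max)


def unmix_pixel(spectrum: np.ndarray, endmembers: np.ndarray) -> np.ndarray:
    """NNLS decomposition of one spectrum against K×B endmembers.

    Returns the K-vector ``argmin_{a ≥ 0} ‖Sᵀ a − spectrum‖₂`` via the
    Lawson–Hanson active-set algorithm.
    """
    y = np.asarray(spectrum, dtype=float)
    s = np.asarray(endmembers, dtype=float)
    if s.ndim == 1:
        s = s[None, :]
    if y.ndim != 1 or y.size != s.shape[1]:
        raise ValueError(f"spectrum length {y.size} does not match {s.shape[1]} bands")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(s))):
        raise ValueError("non-finite values in spectrum or endmembers")
    coeffs, _ = scipy.optimize.nnls(s.T, y)
    return coeffs


def _nnls_supports(k: int):
    """All supports in deterministic order: by size, then lexicographic."""
    for size in range(1, k + 1):
        yield from combinations(range(k), size)


def nnls_batch(S: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact NNLS for many spectra at once, small K.

    Enumerates every support, solves the unconstrained least squares
    restricted to it in closed form for all N rows of ``Y`` (N×B)
    simultaneously, and keeps the feasible candidate with the smallest
    SSE. The optimal NNLS support is among the candidates, so the
    minimum equals the true NNLS optimum; ties go to the earliest
    support in (size, lexicographic) order.
    """
    k, b = S.shape
    n = Y.shape[0]
    best_sse = np.einsum("ij,ij->i", Y, Y)  # a = 0 candidate
    best_a = np.zeros((n, k))
    for support in _nnls_supports(k):
        idx = list(support)
        Ssub = S[idx]  # m×B
        gram = Ssub @ Ssub.T
        try:
            solver = np.linalg.inv(gram) @ Ssub  # m×B
        except np.linalg.LinAlgError:
            continue
        coeffs = Y @ solver.T  # N×m
        feasible = np.all(coeffs >= 0, axis=1)
        if not feasible.any():
            continue
        recon = coeffs @ Ssub  # N×B
        diff = recon - Y
        sse = np.einsum("ij,ij->i", diff, diff)
        better = feasible & (sse < best_sse - 1e-12)
        if better.any():
            best_sse[better] = sse[better]
            best_a[better] = 0.0
            best_a[np.ix_(better, idx)] = coeffs[better]
    return best_a, np.sqrt(np.maximum(best_sse, 0.0))


def unmix_cube(od_or_cube, library, warn_angle_deg: float = 3.0) -> AbundanceMap:
    """Unmix every pixel of an OD cube (brightfield) or intensity cube
    (fluorescence) against a spectral library.

    Warns when the library contains endmember pairs closer than
    ``warn_angle_deg`` (near-collinear chromogens inflate abundance
    noise). Returns coefficients and per-pixel residual norms.
    """
    from .library import SpectralLibrary, library_condition_report

    if isinstance(library, SpectralLibrary):
        endmembers = library.endmembers
        report = library_condition_report(library, warn_angle_deg=warn_angle_deg)
        if report.flagged_pairs:
            warnings.warn(
                f"near-collinear endmembers (<{warn_angle_deg}°): {report.flagged_pairs}",
                stacklevel=2,
            )
    else:
        endmembers = library

    if isinstance(od_or_cube, ODCube):
        data = od_or_cube.data
        wavelengths = od_or_cube.wavelengths_nm
        mode = BRIGHTFIELD
    elif isinstance(od_or_cube, MultispectralCube):
        if od_or_cube.mode == BRIGHTFIELD:
            raise ValueError(
                "brightfield cubes must be OD-converted first (to_optical_density)"
            )
        data = od_or_cube.data
        wavelengths = od_or_cube.wavelengths_nm
        mode = FLUORESCENCE
    else:
        raise TypeError(f"cannot unmix {type(od_or_cube).__name__}")

    if wavelengths.size != endmembers.n_bands or np.any(
        np.abs(wavelengths - endmembers.wavelengths_nm) > 1e-6
    ):
        raise ValueError("cube wavelengths do not match library wavelengths")

    h, w, b = data.shape
    S = endmembers.spectra
    Y = data.reshape(-1, b).astype(np.float64)
    if len(endmembers) <= 12:
        coeffs, resid = nnls_batch(S, Y)
    else:  # pragma: no cover - large libraries are out of normal scope
        coeffs = np.empty((Y.shape[0], len(endmembers)))
        resid = np.empty(Y.shape[0])
        for i, y in enumerate(Y):
            coeffs[i], rnorm = scipy.optimize.nnls(S.T, y)
            resid[i] = rnorm
    return AbundanceMap(
        data=coeffs.reshape(h, w, len(endmembers)),
        residual=resid.reshape(h, w),
        endmember_names=list(endmembers.names),
        wavelengths_nm=np.asarray(wavelengths, dtype=float),
        endmember_spectra=S.copy(),
        mode=mode,
    )


@dataclass
class ResidualSummary:
    mean: float
    p95: float
    n_pixels: int


def reconstruction_residual(
    abundances: AbundanceMap,
    od_or_cube,
    tissue_threshold: float = 0.05,
) -> ResidualSummary:
    """Recompute ‖Sᵀa − y‖₂ per pixel and summarize over tissue pixels.

    Tissue pixels are those whose summed abundance exceeds
    ``tissue_threshold``; when none qualify all pixels are summarized.
    """
    data = od_or_cube.data if hasattr(od_or_cube, "data") else np.asarray(od_or_cube)
    h, w, b = data.shape
    if abundances.data.shape[:2] != (h, w):
        raise ValueError("abundance map and cube shapes disagree")
    S = abundances.endmember_spectra
    if S is None:
        raise ValueError("AbundanceMap carries no endmember spectra")
    recon = abundances.data.reshape(-1, abundances.data.shape[2]) @ S
    diff = recon - data.reshape(-1, b)
    resid = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    mask = abundances.total().reshape(-1) > tissue_threshold
    if not mask.any():
        mask = np.ones_like(mask)
    sel = resid[mask]
    return ResidualSummary(
        mean=float(sel.mean()), p95=float(np.percentile(sel, 95)), n_pixels=int(mask.sum())
    )


class SpectralUnmixer:
    """Estimator-style wrapper: fit a spectral library, transform cubes.

    Parameters
    ----------
    library:
        A prebuilt :class:`~spectracell.library.SpectralLibrary` or
        ``EndmemberSet``; if ``None``, :meth:`fit` must be given
        single-stain cubes to build one.
    i0, od_max:
        Brightfield white reference and OD clamp for the conversion step.
    """

    def __init__(self, library=None, i0: float | None = None, od_max: float = DEFAULT_OD_MAX,
                 foreground_quantile: float = 0.90):
        self.library = library
        self.i0 = i0
        self.od_max = od_max
        self.foreground_quantile = foreground_quantile

    # -- sklearn plumbing ------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "library": self.library,
            "i0": self.i0,
            "od_max": self.od_max,
            "foreground_quantile": self.foreground_quantile,
        }

    def set_params(self, **params) -> "SpectralUnmixer":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    # --------------------------------------------------------------------
    def fit(self, X=None, y=None) -> "SpectralUnmixer":
        """Build (or adopt) the library.

        ``X`` is a list of ``(name, MultispectralCube)`` single-stain
        cubes when ``library`` was not given at construction.
        """
        from .library import SpectralLibrary, build_library

        if self.library is not None:
            lib = self.library
            if not isinstance(lib, SpectralLibrary):
                lib = SpectralLibrary(endmembers=lib)
            self.library_ = lib
        else:
            if not X:
                raise ValueError("no library given and no single-stain cubes to build one")
            self.library_ = build_library(X, foreground_quantile=self.foreground_quantile,
                                          i0=self.i0, od_max=self.od_max)
        return self

    def transform(self, cube: MultispectralCube) -> AbundanceMap:
        if not hasattr(self, "library_"):
            raise RuntimeError("SpectralUnmixer is not fitted; call fit() first")
        if cube.mode == BRIGHTFIELD:
            od = to_optical_density(cube, i0=self.i0, od_max=self.od_max)
            return unmix_cube(od, self.library_)
        return unmix_cube(cube, self.library_)

    def fit_transform(self, cube: MultispectralCube, X=None) -> AbundanceMap:
        return self.fit(X).transform(cube)
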