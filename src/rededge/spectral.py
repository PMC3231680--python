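"""Core spectral data model: axes, spectra, cubes, band sets and SRF resampling.

A :class:`ReflectanceCube` is the substrate of the whole pipeline: a
``(rows, cols, n_wavelengths)`` reflectance array with a shared, strictly
increasing wavelength axis in nanometres and a per-pixel nodata mask.
Spectral resampling convolves the cube with a sensor's spectral response
functions (SRF) to simulate a coarser instrument such as the Sentinel-2 MSI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import BandLookupError, CoverageError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "ReflectanceCube",
    "BandDefinition",
    "BandSet",
    "SRFModel",
    "validate_axis",
    "s2_bandset",
    "subset_bands",
    "srf_weights",
    "resample_cube",
    "resample_spectrum",
]


def validate_axis(wavelengths, min_length: int = 1) -> np.ndarray:
    """Return wavelengths as a validated float array (nm).

    The axis must be strictly increasing with all values positive; operations
    that interpolate or integrate additionally require at least two samples.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < min_length:
        raise UsageError(f"spectral axis needs >= {min_length} samples, got shape {wl.shape}")
    if wl.size and not np.all(wl > 0):
        raise UsageError("wavelengths must be positive (nm)")
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise UsageError("wavelengths must be strictly increasing")
    return wl


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum on a wavelength axis (nm).

    Reflectance is unitless; values outside [0, 1] are legal (atmospheric
    correction routinely produces slight negatives) but are counted and
    logged rather than clipped. Only NaN marks missing data.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        wl = validate_axis(self.wavelengths)
        refl = np.asarray(self.reflectance, dtype=float)
        if refl.shape != wl.shape:
            raise UsageError(
                f"reflectance length {refl.shape} does not match axis {wl.shape}"
            )
        if np.any(np.isinf(refl)):
            raise UsageError("reflectance contains non-finite (inf) values")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)
        n_out = int(np.sum((refl < 0) | (refl > 1)))
        if n_out:
            logger.warning("spectrum has %d reflectance values outside [0, 1]", n_out)

    def value_at(self, wavelength: float, tolerance: float = 5.0) -> float:
        """Reflectance at the sample nearest `wavelength` (within tolerance)."""
        i = nearest_band_index(self.wavelengths, wavelength, tolerance)
        return float(self.reflectance[i])


def nearest_band_index(axis: np.ndarray, wavelength: float, tolerance: float) -> int:
    """Index of the axis sample nearest `wavelength`, or raise BandLookupError."""
    i = int(np.argmin(np.abs(axis - wavelength)))
    if abs(axis[i] - wavelength) > tolerance:
        raise BandLookupError(
            f"no band within {tolerance} nm of {wavelength} nm "
            f"(nearest is {axis[i]} nm)"
        )
    return i


@dataclass
class ReflectanceCube:
    """Wavelength-indexed reflectance raster.

    data : float array, shape (n_rows, n_cols, n_bands)
    wavelengths : shared axis, nm, strictly increasing
    mask : bool array (n_rows, n_cols); True marks nodata pixels
    """

    wavelengths: np.ndarray
    data: np.ndarray
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = validate_axis(self.wavelengths)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != self.wavelengths.size:
            raise UsageError(
                f"cube data shape {self.data.shape} inconsistent with "
                f"{self.wavelengths.size} wavelengths"
            )
        nan_pixels = np.any(np.isnan(self.data), axis=2)
        if self.mask is None:
            self.mask = nan_pixels
        else:
            self.mask = np.asarray(self.mask, dtype=bool) | nan_pixels
        if self.mask.shape != self.data.shape[:2]:
            raise UsageError("mask shape does not match pixel grid")
        valid = self.data[~self.mask]
        n_out = int(np.sum((valid < 0) | (valid > 1)))
        if n_out:
            logger.warning("cube has %d reflectance values outside [0, 1]", n_out)

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def spectrum(self, row: int, col: int) -> Spectrum:
        """The spectrum at pixel (row, col); raises on a masked pixel."""
        if self.mask[row, col]:
            raise UsageError(f"pixel ({row}, {col}) is masked")
        return Spectrum(self.wavelengths, self.data[row, col])

    @classmethod
    def from_spectra(cls, spectra, n_rows: int, n_cols: int, **meta) -> "ReflectanceCube":
        """Build a cube from a flat, row-major list of equal-axis spectra."""
        if len(spectra) != n_rows * n_cols:
            raise UsageError("spectrum count does not match grid size")
        wl = spectra[0].wavelengths
        for s in spectra[1:]:
            if not np.array_equal(s.wavelengths, wl):
                raise UsageError("spectra do not share a wavelength axis")
        data = np.stack([s.reflectance for s in spectra]).reshape(n_rows, n_cols, -1)
        return cls(wl, data, meta=dict(meta))


@dataclass(frozen=True)
class BandDefinition:
    """One sensor band: centre and full width in nm (spatial resolution is
    carried as metadata only — the pipeline never resamples spatially)."""

    band_id: str
    center: float
    width: float
    spatial_resolution: float | None = None

    def __post_init__(self):
        if self.width <= 0:
            raise UsageError(f"band {self.band_id}: width must be > 0")
        if self.center - self.width / 2 <= 0:
            raise UsageError(f"band {self.band_id}: support extends below 0 nm")

    @property
    def support(self) -> tuple[float, float]:
        return (self.center - self.width / 2, self.center + self.width / 2)


@dataclass(frozen=True)
class BandSet:
    """Ordered band definitions describing a sensor configuration."""

    bands: tuple[BandDefinition, ...]
    name: str = ""

    def __post_init__(self):
        bands = tuple(self.bands)
        object.__setattr__(self, "bands", bands)
        ids = [b.band_id for b in bands]
        if len(set(ids)) != len(ids):
            raise UsageError("band ids must be unique")
        centers = [b.center for b in bands]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise UsageError("band centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, band_id: str) -> BandDefinition:
        for b in self.bands:
            if b.band_id == band_id:
                return b
        raise BandLookupError(f"unknown band id {band_id!r} in band set {self.name!r}")

    @property
    def band_ids(self) -> list[str]:
        return [b.band_id for b in self.bands]

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])


# Sentinel-2 MSI spectral configuration: (id, centre nm, width nm, resolution m).
_S2_MSI = [
    ("B1", 443, 20, 60),
    ("B2", 490, 65, 10),
    ("B3", 560, 35, 10),
    ("B4", 665, 30, 10),
    ("B5", 705, 15, 20),
    ("B6", 740, 15, 20),
    ("B7", 783, 20, 20),
    ("B8", 842, 115, 10),
    ("B8a", 865, 20, 20),
    ("B9", 945, 20, 60),
    ("B10", 1375, 30, 60),
    ("B11", 1610, 90, 20),
    ("B12", 2190, 180, 20),
]


def s2_bandset() -> BandSet:
    """The 13-band Sentinel-2 MSI configuration.

    B5 (705 nm), B6 (740 nm) and B7 (783 nm) are the red-edge bands this
    package exists to exercise; B4–B7 are the bands whose centres fall inside
    the 643–795 nm NAOC integration window.
    """
    return BandSet(
        tuple(BandDefinition(i, c, w, r) for i, c, w, r in _S2_MSI),
        name="Sentinel-2 MSI",
    )


def subset_bands(bandset: BandSet, band_ids) -> BandSet:
    """Restrict a band set to the listed ids, preserving the original order."""
    keep = set(band_ids)
    unknown = keep - set(bandset.band_ids)
    if unknown:
        raise BandLookupError(f"unknown band id(s) {sorted(unknown)} in {bandset.name!r}")
    return replace(
        bandset,
        bands=tuple(b for b in bandset.bands if b.band_id in keep),
    )


@dataclass(frozen=True)
class SRFModel:
    """Spectral response function shape used to synthesise broad bands.

    boxcar : uniform weight over [centre - width/2, centre + width/2]
    gaussian : FWHM = band width, truncated at +/- 2 FWHM around the centre

    Weights are normalised to sum to 1 over the source samples that fall
    inside the support, so each resampled value is a convex combination of
    source reflectances (a constant spectrum resamples to itself exactly).
    """

    shape: str = "boxcar"

    def __post_init__(self):
        if self.shape not in ("boxcar", "gaussian"):
            raise UsageError(f"unknown SRF shape {self.shape!r}")


def srf_weights(band: BandDefinition, axis: np.ndarray, srf: SRFModel) -> np.ndarray:
    """Normalised SRF weights of `band` on the source `axis` (0 outside support).

    Raises CoverageError when fewer than two source samples fall inside the
    support — a single sample cannot represent a band average credibly.
    """
    if srf.shape == "boxcar":
        lo, hi = band.support
        inside = (axis >= lo) & (axis <= hi)
        w = inside.astype(float)
    else:  # gaussian, FWHM = width, truncated at +/- 2 FWHM
        fwhm = band.width
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        inside = np.abs(axis - band.center) <= 2.0 * fwhm
        w = np.where(inside, np.exp(-0.5 * ((axis - band.center) / sigma) ** 2), 0.0)
    n_inside = int(np.count_nonzero(w))
    if n_inside < 2:
        raise CoverageError(
            f"band {band.band_id} ({band.center} nm): only {n_inside} source "
            f"sample(s) inside the SRF support"
        )
    return w / w.sum()


def covered_bands(
    bandset: BandSet, axis: np.ndarray, srf: SRFModel | None = None
) -> BandSet:
    """Subset of `bandset` whose SRF support holds >= 2 samples of `axis`.

    Convenience for resampling a cube onto the portion of a sensor that its
    spectral range actually covers (e.g., a VNIR cube onto S2 B1-B9).
    """
    srf = srf or SRFModel()
    keep = []
    for band in bandset:
        try:
            srf_weights(band, axis, srf)
        except CoverageError:
            continue
        keep.append(band.band_id)
    if not keep:
        raise CoverageError(f"no band of {bandset.name!r} is covered by the axis")
    return subset_bands(bandset, keep)


def resample_cube(
    cube: ReflectanceCube, bandset: BandSet, srf: SRFModel | None = None
) -> ReflectanceCube:
    """SRF-convolve a cube onto a coarser band set (e.g., hyperspectral -> S2).

    The output axis is the band centres of `bandset`; each output value is the
    SRF-weighted mean of source reflectance within that band's support.
    Masked pixels stay masked.
    """
    srf = srf or SRFModel()
    weights = np.stack([srf_weights(b, cube.wavelengths, srf) for b in bandset])
    out = cube.data @ weights.T  # (rows, cols, n_bands_out)
    meta = dict(cube.meta)
    meta.update(bandset=bandset.name, band_ids=bandset.band_ids, srf=srf.shape)
    return ReflectanceCube(bandset.centers, out, mask=cube.mask.copy(), meta=meta)


def resample_spectrum(
    spectrum: Spectrum, bandset: BandSet, srf: SRFModel | None = None
) -> Spectrum:
    """Single-spectrum convenience wrapper around :func:`resample_cube`."""
    srf = srf or SRFModel()
    weights = np.stack([srf_weights(b, spectrum.wavelengths, srf) for b in bandset])
    return Spectrum(bandset.centers, weights @ spectrum.reflectance)
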