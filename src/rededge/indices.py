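"""Spectral indices: the generic normalized difference index (NDI), its
exhaustive band-pair optimization, and the Normalized Area Over the
reflectance Curve (NAOC).

NDI(a, b) = (R_b - R_a) / (R_b + R_a); NDVI is the (670, 800 nm) special
case. NAOC integrates the reflectance curve over a window [a, b] spanning
the chlorophyll absorption (~670 nm) and the red edge:

    NAOC = 1 - (integral_a^b R dlambda) / (R(b) * (b - a))

with defaults a = 643 nm, b = 795 nm, so the normalization constant
(b - a) is 152 nm. Deeper chlorophyll absorption leaves more area *over*
the curve, hence larger NAOC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, DegenerateDataError, UsageError
from .spectral import ReflectanceCube, Spectrum, nearest_band_index, validate_axis

logger = logging.getLogger(__name__)

__all__ = [
    "IndexMap",
    "NAOCConfig",
    "OptimizationSurface",
    "ndi",
    "ndi_value",
    "naoc",
    "naoc_spectrum",
    "naoc_bandset_variants",
    "optimize_ndi",
]

#: default nearest-band matching tolerance (nm); CHRIS bands at 664/706 nm sit
#: about 1 nm from the S2 B4/B5 centres, so small tolerances must succeed.
DEFAULT_TOLERANCE = 5.0


@dataclass
class IndexMap:
    """Per-pixel values of one spectral index (or a parameter derived from it).

    `values` holds NaN on masked pixels; `meta` records the provenance needed
    to recompute the map (index name, wavelengths/bands, integration limits,
    calibration coefficients ...).
    """

    values: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool) | np.isnan(self.values)
        if self.mask.shape != self.values.shape or self.values.ndim != 2:
            raise UsageError("IndexMap needs matching 2-D values and mask")
        self.values = np.where(self.mask, np.nan, self.values)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def to_dataframe(self) -> pd.DataFrame:
        """Unmasked pixels as (pixel_row, pixel_col, value) rows."""
        rows, cols = np.nonzero(~self.mask)
        return pd.DataFrame(
            {"pixel_row": rows, "pixel_col": cols, "value": self.values[rows, cols]}
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_geotiff(self, path) -> None:
        """Single-band float32 GeoTIFF; masked pixels become NaN and the
        provenance metadata is stored in the page description as JSON."""
        import json

        import tifffile

        data = self.values.astype(np.float32)
        tifffile.imwrite(path, data, description=json.dumps(self.meta, default=str))

    def plot(self, ax=None, **imshow_kwargs):
        """Render the map with masked pixels transparent."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        shown = np.ma.masked_where(self.mask, self.values)
        im = ax.imshow(shown, **imshow_kwargs)
        label = self.meta.get("parameter") or self.meta.get("index") or "value"
        units = self.meta.get("units")
        ax.figure.colorbar(im, ax=ax, label=f"{label} [{units}]" if units else label)
        return ax


def ndi(
    cube: ReflectanceCube,
    wl_a: float,
    wl_b: float,
    tolerance: float = DEFAULT_TOLERANCE,
) -> IndexMap:
    """Normalized difference index (R_b - R_a)/(R_b + R_a) per pixel.

    Band matching is nearest-within-tolerance; the actual wavelengths used
    are recorded in the map metadata. Pixels with a zero denominator are
    masked (0/0 carries no information) and counted in the log.
    """
    if wl_a == wl_b:
        raise UsageError("wl_a and wl_b must differ")
    ia = nearest_band_index(cube.wavelengths, wl_a, tolerance)
    ib = nearest_band_index(cube.wavelengths, wl_b, tolerance)
    if ia == ib:
        raise UsageError(
            f"{wl_a} nm and {wl_b} nm both resolve to the band at "
            f"{cube.wavelengths[ia]} nm"
        )
    ra, rb = cube.data[:, :, ia], cube.data[:, :, ib]
    denom = rb + ra
    zero = (denom == 0) & ~cube.mask
    n_zero = int(zero.sum())
    if n_zero:
        logger.warning("NDI: %d pixel(s) masked for zero denominator", n_zero)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom != 0, (rb - ra) / denom, np.nan)
    meta = {
        "index": "NDI",
        "wl_a_requested": float(wl_a),
        "wl_b_requested": float(wl_b),
        "wl_a": float(cube.wavelengths[ia]),
        "wl_b": float(cube.wavelengths[ib]),
        "n_zero_denominator": n_zero,
    }
    return IndexMap(values, cube.mask | zero, meta)


def ndi_value(spectrum: Spectrum, wl_a: float, wl_b: float,
              tolerance: float = DEFAULT_TOLERANCE) -> float:
    """NDI of a single spectrum (scalar convenience wrapper)."""
    ra = spectrum.value_at(wl_a, tolerance)
    rb = spectrum.value_at(wl_b, tolerance)
    if ra + rb == 0:
        raise UsageError("zero denominator: R_a + R_b = 0")
    return (rb - ra) / (rb + ra)


@dataclass(frozen=True)
class NAOCConfig:
    """Integration window and quadrature step for NAOC (all nm).

    Defaults bracket the chlorophyll absorption feature: a = 643, b = 795.
    The composite trapezoid rule is applied on a uniform grid of
    `sample_step` spacing; 1 nm is exact for a piecewise-linear curve whose
    nodes sit on the grid.
    """

    a: float = 643.0
    b: float = 795.0
    sample_step: float = 1.0

    def __post_init__(self):
        if not self.a < self.b:
            raise UsageError("NAOC limits must satisfy a < b")
        if not (0 < self.sample_step <= (self.b - self.a) / 10):
            raise UsageError("sample_step must be in (0, (b - a)/10]")

    @property
    def grid(self) -> np.ndarray:
        n = int(np.ceil((self.b - self.a) / self.sample_step))
        return np.linspace(self.a, self.b, n + 1)


def _naoc_nodes(axis: np.ndarray, config: NAOCConfig) -> np.ndarray:
    """Indices of the axis samples usable as curve nodes (centres in [a, b])."""
    inside = np.nonzero((axis >= config.a) & (axis <= config.b))[0]
    if inside.size < 2:
        raise CoverageError(
            f"NAOC needs >= 2 bands with centres inside [{config.a}, {config.b}] nm; "
            f"found {inside.size}"
        )
    return inside


def _interp_matrix(grid: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Matrix W with W @ values = piecewise-linear interpolation of
    (nodes, values) onto grid, constant-extrapolated beyond the outer nodes.

    Interpolation is linear in the node values, so W is built by
    interpolating the canonical basis vectors.
    """
    eye = np.eye(nodes.size)
    return np.stack([np.interp(grid, nodes, eye[k]) for k in range(nodes.size)], axis=1)


def naoc_spectrum(spectrum: Spectrum, config: NAOCConfig | None = None) -> float:
    """NAOC of a single spectrum; NaN when R(b) <= 0."""
    config = config or NAOCConfig()
    idx = _naoc_nodes(spectrum.wavelengths, config)
    nodes = spectrum.wavelengths[idx]
    vals = spectrum.reflectance[idx]
    grid = config.grid
    curve = np.interp(grid, nodes, vals)
    rb = float(np.interp(config.b, nodes, vals))
    if rb <= 0:
        logger.warning("NAOC: R(b) <= 0, result undefined")
        return float("nan")
    integral = float(np.trapezoid(curve, grid))
    return 1.0 - integral / (rb * (config.b - config.a))


def naoc(
    cube_or_spectrum: ReflectanceCube | Spectrum, config: NAOCConfig | None = None
) -> IndexMap | float:
    """NAOC per pixel (cube input) or as a scalar (spectrum input).

    The reflectance curve is reconstructed by linear interpolation between
    the band-centre nodes lying inside [a, b] and held constant from the
    outermost nodes to the integration limits; the integral uses the
    composite trapezoid rule on the config's uniform grid.
    """
    config = config or NAOCConfig()
    if isinstance(cube_or_spectrum, Spectrum):
        return naoc_spectrum(cube_or_spectrum, config)
    cube = cube_or_spectrum
    idx = _naoc_nodes(cube.wavelengths, config)
    nodes = cube.wavelengths[idx]
    node_vals = cube.data[:, :, idx]  # (rows, cols, n_nodes)
    grid = config.grid
    W = _interp_matrix(grid, nodes)
    curves = node_vals @ W.T  # (rows, cols, n_grid)
    wb = _interp_matrix(np.array([config.b]), nodes)[0]
    rb = node_vals @ wb
    integral = np.trapezoid(curves, grid, axis=2)
    nonpos = (rb <= 0) & ~cube.mask
    n_nonpos = int(nonpos.sum())
    if n_nonpos:
        logger.warning("NAOC: %d pixel(s) masked for R(b) <= 0", n_nonpos)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(rb > 0, 1.0 - integral / (rb * (config.b - config.a)), np.nan)
    meta = {
        "index": "NAOC",
        "a_nm": config.a,
        "b_nm": config.b,
        "sample_step_nm": config.sample_step,
        "node_wavelengths_nm": [float(w) for w in nodes],
        "n_rb_nonpositive": n_nonpos,
    }
    return IndexMap(values, cube.mask | nonpos, meta)


#: S2 band centres required for the red-edge ablation (B4, B5, B6, B7).
NAOC_S2_CENTERS = (665.0, 705.0, 740.0, 783.0)


def naoc_bandset_variants(
    cube: ReflectanceCube,
    config: NAOCConfig | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[IndexMap, IndexMap]:
    """NAOC with and without the red-edge bands, on an S2-resampled cube.

    The first map reconstructs the curve from all four S2 bands inside the
    integration window (B4 665, B5 705, B6 740, B7 783 nm); the second uses
    B4 and B7 only — the red-edge ablation. Both integrate over the same
    window with the same constant-extrapolation rule.
    """
    config = config or NAOCConfig()
    try:
        idx4 = [nearest_band_index(cube.wavelengths, c, tolerance) for c in NAOC_S2_CENTERS]
    except Exception as exc:
        raise CoverageError(f"cube lacks a required S2 band: {exc}") from exc
    if len(set(idx4)) != 4:
        raise CoverageError("S2 band centres resolve to fewer than 4 distinct bands")

    def _subcube(indices):
        return ReflectanceCube(
            cube.wavelengths[indices],
            cube.data[:, :, indices],
            mask=cube.mask.copy(),
            meta=dict(cube.meta),
        )

    with_re = naoc(_subcube(idx4), config)
    without_re = naoc(_subcube([idx4[0], idx4[3]]), config)
    with_re.meta["variant"] = "with_red_edge (B4,B5,B6,B7)"
    without_re.meta["variant"] = "without_red_edge (B4,B7)"
    return with_re, without_re


@dataclass
class OptimizationSurface:
    """Result of the exhaustive NDI band-pair search.

    r_matrix[i, j] is the Pearson correlation between NDI(a=wavelengths[i],
    b=wavelengths[j]) and the target; it is antisymmetric because
    NDI(b, a) = -NDI(a, b). Cells with zero NDI variance are NaN and are
    excluded from the argmax. `best_pair` is reported in the r > 0
    orientation, ties broken by smallest a then smallest b.
    """

    wavelengths: np.ndarray
    r_matrix: np.ndarray
    best_pair: tuple[float, float]
    best_r: float

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (wl_a, wl_b, r) table of the defined cells."""
        ii, jj = np.nonzero(~np.isnan(self.r_matrix))
        return pd.DataFrame(
            {
                "wl_a": self.wavelengths[ii],
                "wl_b": self.wavelengths[jj],
                "r": self.r_matrix[ii, jj],
            }
        )


def optimize_ndi(
    spectra: list[Spectrum],
    target,
    wl_min: float,
    wl_max: float,
) -> OptimizationSurface:
    """Exhaustive search for the NDI band pair best correlated with a target.

    For every ordered pair (a, b) of candidate bands in [wl_min, wl_max],
    computes Pearson r between NDI(a, b) over the spectra and the target
    values (e.g., LAI in m2/m2 or Ch in ug/cm2) and returns the full
    correlation surface plus the pair maximizing |r|.
    """
    if len(spectra) < 3:
        raise UsageError("optimize_ndi needs at least 3 spectra")
    target = np.asarray(target, dtype=float)
    if target.size != len(spectra):
        raise UsageError("target length must match the number of spectra")
    if np.ptp(target) == 0:
        raise DegenerateDataError("target is constant; correlation undefined")
    axis = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, axis):
            raise UsageError("all spectra must share one wavelength axis")
    validate_axis(axis, min_length=2)
    cand = np.nonzero((axis >= wl_min) & (axis <= wl_max))[0]
    if cand.size < 2:
        raise CoverageError(
            f"need >= 2 candidate bands in [{wl_min}, {wl_max}] nm, found {cand.size}"
        )
    R = np.stack([s.reflectance for s in spectra])[:, cand]  # (n_spec, n_cand)
    n_cand = cand.size
    t = target - target.mean()
    t_norm = np.sqrt((t**2).sum())

    r_matrix = np.full((n_cand, n_cand), np.nan)
    for i in range(n_cand):
        ra = R[:, i : i + 1]  # noqa: E203
        with np.errstate(invalid="ignore", divide="ignore"):
            x = (R - ra) / (R + ra)  # NDI(a=i, b=j) for all j
        xc = x - x.mean(axis=0)
        x_norm = np.sqrt((xc**2).sum(axis=0))
        ok = np.isfinite(x_norm) & (x_norm > 0) & np.all(np.isfinite(x), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * t[:, None]).sum(axis=0) / (x_norm * t_norm)
        r_matrix[i, ok] = r[ok]
        r_matrix[i, i] = np.nan  # NDI(a, a) = 0 identically

    abs_r = np.where(np.isnan(r_matrix), -np.inf, np.abs(r_matrix))
    best = abs_r.max()
    if not np.isfinite(best):
        raise DegenerateDataError("no band pair yields a defined correlation")
    # orient every tied argmax cell to r > 0, then take smallest (a, b)
    ties = np.argwhere(abs_r == best)
    oriented = []
    for i, j in ties:
        a_idx, b_idx = (i, j) if r_matrix[i, j] >= 0 else (j, i)
        oriented.append((axis[cand[a_idx]], axis[cand[b_idx]]))
    best_pair = min(oriented)
    return OptimizationSurface(
        wavelengths=axis[cand],
        r_matrix=r_matrix,
        best_pair=(float(best_pair[0]), float(best_pair[1])),
        best_r=float(best),
    )
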