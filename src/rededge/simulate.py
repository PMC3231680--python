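"""Seeded forward simulator for canopy reflectance scenes with known truth.

The generator emulates the statistical structure of agricultural campaign
data: a pixel grid partitioned into rectangular crop "fields", each with a
field-level green LAI (m2/m2) and leaf chlorophyll Ch (ug/cm2), a fraction
of bare-soil fields, small within-field variability, and additive sensor
noise. Spectra come from a three-part closed-form model:

leaf      R_leaf(l) = R_inf + (R_max - R_inf) * exp(-Ch * eps(l)),
          R_max = 0.5, R_inf = 0.05, and specific absorption
          eps(l) = 0.06*G(l; 670, 40) + 0.03*G(l; 500, 30) (unit-height
          Gaussians), so eps ~ 0 above ~780 nm: an NIR plateau and a
          chlorophyll-driven red edge.
soil      linear ramp R_soil(l) = 0.10 + 0.00025*(l - 400), clipped to
          [0, 0.45].
canopy    gap-fraction mixing with extinction coefficient 0.5:
          f = 1 - exp(-0.5*LAI); R = f*R_leaf + (1-f)*R_soil.

This is deliberately not a radiative-transfer model: it provides a 670 nm
chlorophyll absorption, a red-edge transition and exactly known per-pixel
truth, which is what the index/calibration pipeline needs for testing.

All randomness flows from one seed through a fixed draw order (field LAI,
field Ch, soil-field selection, per-pixel LAI jitter, per-pixel Ch jitter,
band noise), so scenes are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UsageError
from .spectral import ReflectanceCube, Spectrum, validate_axis

__all__ = [
    "SceneParams",
    "SceneTruth",
    "leaf_reflectance",
    "soil_spectrum",
    "canopy_reflectance",
    "simulate_scene",
]

#: leaf model constants
R_MAX = 0.5
R_INF = 0.05
#: gap-fraction extinction coefficient
K_EXT = 0.5
#: Ch (ug/cm2) * LAI (m2/m2) -> canopy chlorophyll in g/m2
UG_CM2_TO_G_M2 = 0.01


def _default_axis() -> np.ndarray:
    return np.arange(400.0, 1001.0, 1.0)


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def specific_absorption(wavelengths) -> np.ndarray:
    """Chlorophyll specific absorption eps(lambda), cm2/ug (model units)."""
    wl = np.asarray(wavelengths, dtype=float)
    return 0.06 * _gauss(wl, 670.0, 40.0) + 0.03 * _gauss(wl, 500.0, 30.0)


def leaf_reflectance(ch: float, axis) -> Spectrum:
    """Leaf-level reflectance for chlorophyll content `ch` (ug/cm2)."""
    if ch < 0:
        raise UsageError(f"chlorophyll content must be >= 0, got {ch}")
    wl = validate_axis(axis)
    refl = R_INF + (R_MAX - R_INF) * np.exp(-ch * specific_absorption(wl))
    return Spectrum(wl, refl)


def soil_spectrum(axis) -> Spectrum:
    """Bare-soil reflectance: a gentle brightening ramp with wavelength."""
    wl = validate_axis(axis)
    return Spectrum(wl, np.clip(0.10 + 0.00025 * (wl - 400.0), 0.0, 0.45))


def canopy_reflectance(leaf: Spectrum, soil: Spectrum, lai: float) -> Spectrum:
    """Mix leaf and soil by gap-fraction cover f = 1 - exp(-0.5*LAI)."""
    if lai < 0:
        raise UsageError(f"LAI must be >= 0, got {lai}")
    if not np.array_equal(leaf.wavelengths, soil.wavelengths):
        raise UsageError("leaf and soil spectra must share a wavelength axis")
    f = 1.0 - np.exp(-K_EXT * lai)
    return Spectrum(leaf.wavelengths, f * leaf.reflectance + (1.0 - f) * soil.reflectance)


@dataclass
class SceneParams:
    """Scene configuration; the defaults span the conditions the calibrations
    target: crops with LAI in [0, 6] and Ch in [10, 60] ug/cm2, 15% bare-soil
    fields, and 0.005 additive reflectance noise per band."""

    n_rows: int = 40
    n_cols: int = 50
    n_fields: int = 40
    lai_range: tuple[float, float] = (0.0, 6.0)
    ch_range: tuple[float, float] = (10.0, 60.0)
    soil_fraction: float = 0.15
    noise_sd_additive: float = 0.005
    axis: np.ndarray = field(default_factory=_default_axis)
    seed: int = 0
    jitter: float = 0.10  # within-field +/- fractional variability

    def __post_init__(self):
        self.axis = validate_axis(self.axis, min_length=2)
        if self.lai_range[0] > self.lai_range[1] or self.lai_range[0] < 0:
            raise UsageError("lai_range must be ordered and non-negative")
        if self.ch_range[0] > self.ch_range[1] or self.ch_range[0] < 0:
            raise UsageError("ch_range must be ordered and non-negative")
        if not 0 <= self.soil_fraction <= 1:
            raise UsageError("soil_fraction must be in [0, 1]")
        if self.noise_sd_additive < 0:
            raise UsageError("noise_sd_additive must be >= 0")
        if self.n_fields < 1 or self.n_rows < 1 or self.n_cols < 1:
            raise UsageError("grid and field counts must be positive")


@dataclass
class SceneTruth:
    """Per-pixel ground truth paired with a simulated cube.

    ch_lai = ch * lai * 0.01 (ug/cm2 * m2/m2 -> g/m2) at every pixel;
    class_label is the field id (soil fields keep LAI = 0).
    """

    lai: np.ndarray
    ch: np.ndarray
    ch_lai: np.ndarray
    class_label: np.ndarray

    def to_dataframe(self, value: str = "lai") -> pd.DataFrame:
        """All pixels as a truth table (row, col, value, class_label)."""
        if value not in ("lai", "ch", "ch_lai"):
            raise UsageError("value must be one of lai, ch, ch_lai")
        rows, cols = np.indices(self.lai.shape)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "value": getattr(self, value).ravel(),
                "class_label": self.class_label.ravel(),
            }
        )

    def write_csv(self, path) -> None:
        rows, cols = np.indices(self.lai.shape)
        pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "lai": self.lai.ravel(),
                "ch": self.ch.ravel(),
                "ch_lai": self.ch_lai.ravel(),
                "class_label": self.class_label.ravel(),
            }
        ).to_csv(path, index=False)


def _field_grid(n_rows: int, n_cols: int, n_fields: int) -> np.ndarray:
    """Partition the grid into exactly n_fields rectangles (field-id labels).

    Uses the divisor pair (nr, nc) of n_fields whose block aspect best
    matches the grid aspect; errors if no pair fits inside the grid.
    """
    best = None
    target = np.log(n_rows / n_cols)
    for nr in range(1, n_fields + 1):
        if n_fields % nr:
            continue
        nc = n_fields // nr
        if nr > n_rows or nc > n_cols:
            continue
        score = abs(np.log(nr / nc) - target)
        if best is None or score < best[0]:
            best = (score, nr, nc)
    if best is None:
        raise UsageError(
            f"cannot place {n_fields} rectangular fields on a "
            f"{n_rows}x{n_cols} grid"
        )
    _, nr, nc = best
    labels = np.empty((n_rows, n_cols), dtype=int)
    row_chunks = np.array_split(np.arange(n_rows), nr)
    col_chunks = np.array_split(np.arange(n_cols), nc)
    fid = 0
    for rch in row_chunks:
        for cch in col_chunks:
            labels[np.ix_(rch, cch)] = fid
            fid += 1
    return labels


def simulate_scene(params: SceneParams) -> tuple[ReflectanceCube, SceneTruth]:
    """Simulate one scene: a reflectance cube plus exact per-pixel truth."""
    labels = _field_grid(params.n_rows, params.n_cols, params.n_fields)
    rng = np.random.default_rng(params.seed)

    # field-level draws (fixed order; see module docstring)
    field_lai = rng.uniform(*params.lai_range, params.n_fields)
    field_ch = rng.uniform(*params.ch_range, params.n_fields)
    n_soil = int(round(params.soil_fraction * params.n_fields))
    soil_fields = rng.choice(params.n_fields, size=n_soil, replace=False)
    field_lai[soil_fields] = 0.0

    lai = field_lai[labels]
    ch = field_ch[labels]
    shape = labels.shape
    lai = np.clip(lai * (1.0 + rng.uniform(-params.jitter, params.jitter, shape)), 0.0, None)
    ch = np.clip(ch * (1.0 + rng.uniform(-params.jitter, params.jitter, shape)), 0.0, None)
    lai[np.isin(labels, soil_fields)] = 0.0

    wl = params.axis
    eps = specific_absorption(wl)
    soil = np.clip(0.10 + 0.00025 * (wl - 400.0), 0.0, 0.45)
    leaf = R_INF + (R_MAX - R_INF) * np.exp(-ch[..., None] * eps)
    f = (1.0 - np.exp(-K_EXT * lai))[..., None]
    data = f * leaf + (1.0 - f) * soil
    if params.noise_sd_additive > 0:
        data = data + rng.normal(0.0, params.noise_sd_additive, data.shape)

    meta = {
        "simulator": "rededge.simulate.simulate_scene",
        "seed": params.seed,
        "n_fields": params.n_fields,
        "lai_range": list(params.lai_range),
        "ch_range": list(params.ch_range),
        "soil_fraction": params.soil_fraction,
        "noise_sd_additive": params.noise_sd_additive,
    }
    cube = ReflectanceCube(wl, data, meta=meta)
    truth = SceneTruth(
        lai=lai, ch=ch, ch_lai=ch * lai * UG_CM2_TO_G_M2, class_label=labels
    )
    return cube, truth
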