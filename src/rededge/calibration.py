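"""Empirical index-to-parameter calibration and validation statistics.

Three calibration forms are supported, matching how red-edge indices are
used operationally:

proportional  y = s * x            (LAI from NDI; bare soil anchors the origin)
linear        y = c + s * x        (leaf chlorophyll Ch from NAOC)
exponential   y = A * exp(k * x)   (canopy chlorophyll Ch*LAI from NAOC)

The modelling interface follows the statsmodels convention: an
:class:`IndexCalibration` model is built from data and ``fit()`` returns a
:class:`CalibrationResults` carrying the coefficients, their standard
errors, the fit correlation, ``predict``, ``summary`` and plotting.
Module-level ``fit_proportional`` / ``fit_linear`` / ``fit_exponential``
are thin wrappers. The exponential form is fitted by ordinary least squares
on ln(y) — closed form and deterministic — so its reported r is the Pearson
correlation between the index and ln(y).

Widely used published coefficient sets ship as presets (see
:data:`PRESETS`) so maps can be produced without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, UsageError
from .indices import IndexMap

__all__ = [
    "IndexCalibration",
    "CalibrationResults",
    "ValidationReport",
    "fit_proportional",
    "fit_linear",
    "fit_exponential",
    "validate",
    "map_agreement",
    "preset",
    "PRESETS",
]

KINDS = ("proportional", "linear", "exponential")

#: conversion applied at the Ch*LAI boundary: ug/cm2 * (m2/m2) -> g/m2
UG_CM2_TO_G_M2 = 0.01


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN (undefined marker) when either side has zero variance."""
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CalibrationResults:
    """A fitted (or preset) index-to-parameter calibration.

    coefficients : mapping by role — {"slope"}, {"intercept", "slope"} or
        {"amplitude", "rate"} depending on `kind`.
    r : Pearson correlation of the fit (index vs response; index vs ln
        response for the exponential form). NaN marks an undefined r.
    n : number of samples the fit used (0 for presets).
    """

    kind: str
    coefficients: dict
    r: float
    n: int
    bse: dict = field(default_factory=dict)
    x_name: str = "index"
    y_name: str = "parameter"
    y_units: str = ""
    expected_index: str | None = None
    _x: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise UsageError(f"unknown calibration kind {self.kind!r}")
        if self.kind == "exponential" and self.coefficients["amplitude"] <= 0:
            raise UsageError("exponential amplitude A must be > 0")

    # -- application ----------------------------------------------------

    def _apply(self, x: np.ndarray) -> np.ndarray:
        c = self.coefficients
        if self.kind == "proportional":
            return c["slope"] * x
        if self.kind == "linear":
            return c["intercept"] + c["slope"] * x
        return c["amplitude"] * np.exp(c["rate"] * x)

    def predict(self, x):
        """Apply the calibration elementwise.

        Accepts a scalar, an array, or an :class:`IndexMap` (mask propagates
        and the output map's metadata records the calibration). An IndexMap
        whose metadata names a different index family than the calibration
        expects is rejected.
        """
        if isinstance(x, IndexMap):
            if (
                self.expected_index is not None
                and x.meta.get("index") not in (None, self.expected_index)
            ):
                raise UsageError(
                    f"calibration expects a {self.expected_index} map, got "
                    f"{x.meta.get('index')!r}"
                )
            meta = dict(x.meta)
            meta.update(
                parameter=self.y_name,
                units=self.y_units,
                calibration_kind=self.kind,
                calibration_coefficients=dict(self.coefficients),
            )
            with np.errstate(invalid="ignore"):
                return IndexMap(self._apply(x.values), x.mask.copy(), meta)
        return self._apply(np.asarray(x, dtype=float)) if np.ndim(x) else float(
            self._apply(np.asarray(x, dtype=float))
        )

    # -- reporting ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text fit summary in the statsmodels spirit."""
        c = self.coefficients
        form = {
            "proportional": f"{self.y_name} = {c.get('slope', float('nan')):.6g} * {self.x_name}",
            "linear": (
                f"{self.y_name} = {c.get('intercept', float('nan')):.6g} + "
                f"{c.get('slope', float('nan')):.6g} * {self.x_name}"
            ),
            "exponential": (
                f"{self.y_name} = {c.get('amplitude', float('nan')):.6g} * "
                f"exp({c.get('rate', float('nan')):.6g} * {self.x_name})"
            ),
        }[self.kind]
        lines = [
            "Index calibration results",
            "=" * 52,
            f"kind:        {self.kind}",
            f"form:        {form}",
            f"units:       {self.y_units or '-'}",
            f"n:           {self.n}",
            f"r:           {self.r:.4f}" if np.isfinite(self.r) else "r:           undefined",
        ]
        for name, value in self.coefficients.items():
            se = self.bse.get(name)
            se_txt = f"  (se {se:.4g})" if se is not None and np.isfinite(se) else ""
            lines.append(f"  {name:<10s} {value:.6g}{se_txt}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "kind": self.kind,
                "coefficients": self.coefficients,
                "r": None if not np.isfinite(self.r) else self.r,
                "n": self.n,
                "x_name": self.x_name,
                "y_name": self.y_name,
                "y_units": self.y_units,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "CalibrationResults":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            coefficients=d["coefficients"],
            r=float("nan") if d.get("r") is None else float(d["r"]),
            n=int(d.get("n", 0)),
            x_name=d.get("x_name", "index"),
            y_name=d.get("y_name", "parameter"),
            y_units=d.get("y_units", ""),
        )

    def plot_fit(self, ax=None):
        """Scatter of the training data with the fitted curve overlaid."""
        import matplotlib.pyplot as plt

        if self._x is None or self._y is None:
            raise UsageError("no training data stored (preset or deserialized model)")
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self._x, self._y, s=8, alpha=0.5, label="data")
        grid = np.linspace(self._x.min(), self._x.max(), 200)
        ax.plot(grid, self._apply(grid), color="C1", label=f"{self.kind} fit")
        ax.set_xlabel(self.x_name)
        ax.set_ylabel(f"{self.y_name} [{self.y_units}]" if self.y_units else self.y_name)
        ax.legend()
        return ax


class IndexCalibration:
    """Calibration model relating a spectral index to a biophysical parameter.

    Parameters
    ----------
    x : 1-D index values (NDI, NAOC, ...)
    y : target parameter values, same length
    kind : "proportional", "linear" or "exponential"
    """

    def __init__(self, x, y, kind: str, *, x_name="index", y_name="parameter",
                 y_units="", expected_index=None):
        if kind not in KINDS:
            raise UsageError(f"unknown calibration kind {kind!r}")
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        n_min = 3 if kind == "exponential" else 2
        if x.size < n_min:
            raise UsageError(f"{kind} fit needs >= {n_min} finite samples, got {x.size}")
        if kind == "proportional" and np.all(x == 0):
            raise DegenerateDataError("all index values are zero; slope undefined")
        if kind in ("linear", "exponential") and np.ptp(x) == 0:
            raise DegenerateDataError("index values are constant; fit undefined")
        if kind == "exponential" and np.any(y <= 0):
            bad = np.nonzero(y <= 0)[0]
            raise UsageError(
                f"exponential fit needs y > 0; offending sample indices {bad.tolist()[:10]}"
            )
        self.x, self.y, self.kind = x, y, kind
        self.x_name, self.y_name, self.y_units = x_name, y_name, y_units
        self.expected_index = expected_index

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str, y: str, kind: str, **kw):
        return cls(df[x].to_numpy(), df[y].to_numpy(), kind,
                   x_name=kw.pop("x_name", x), y_name=kw.pop("y_name", y), **kw)

    def fit(self) -> CalibrationResults:
        x, y, n = self.x, self.y, self.x.size
        if self.kind == "proportional":
            slope = float(np.sum(x * y) / np.sum(x * x))
            resid = y - slope * x
            se = float(np.sqrt(np.sum(resid**2) / max(n - 1, 1) / np.sum(x * x)))
            coefficients, bse = {"slope": slope}, {"slope": se}
            r = _pearson(x, y)
        elif self.kind == "linear":
            res = stats.linregress(x, y)
            coefficients = {"intercept": float(res.intercept), "slope": float(res.slope)}
            bse = {"intercept": float(res.intercept_stderr), "slope": float(res.stderr)}
            r = _pearson(x, y)
        else:  # exponential: OLS on ln(y)
            ln_y = np.log(y)
            res = stats.linregress(x, ln_y)
            coefficients = {"amplitude": float(np.exp(res.intercept)), "rate": float(res.slope)}
            bse = {"amplitude": float(np.exp(res.intercept) * res.intercept_stderr),
                   "rate": float(res.stderr)}
            r = _pearson(x, ln_y)
        return CalibrationResults(
            kind=self.kind, coefficients=coefficients, r=r, n=n, bse=bse,
            x_name=self.x_name, y_name=self.y_name, y_units=self.y_units,
            expected_index=self.expected_index, _x=x, _y=y,
        )


def fit_proportional(x, y, **kw) -> CalibrationResults:
    """Least-squares line through the origin: slope = sum(xy)/sum(x^2)."""
    return IndexCalibration(x, y, "proportional", **kw).fit()


def fit_linear(x, y, **kw) -> CalibrationResults:
    """Ordinary least squares with intercept."""
    return IndexCalibration(x, y, "linear", **kw).fit()


def fit_exponential(x, y, **kw) -> CalibrationResults:
    """y = A*exp(k*x), fitted as OLS on ln(y); requires y > 0."""
    return IndexCalibration(x, y, "exponential", **kw).fit()


# -- published coefficient presets --------------------------------------

def _presets() -> dict[str, CalibrationResults]:
    return {
        # green LAI from NDI(674, 712) on fine (CHRIS-like) bands
        "chris_lai_ndi": CalibrationResults(
            "proportional", {"slope": 6.753}, r=0.908, n=0,
            x_name="NDI(674,712)", y_name="green LAI", y_units="m2/m2",
            expected_index="NDI",
        ),
        # green LAI from NDI(665, 705), i.e. S2 bands B4 and B5
        "s2_lai_ndi": CalibrationResults(
            "proportional", {"slope": 8.452}, r=0.903, n=0,
            x_name="NDI(665,705)", y_name="green LAI", y_units="m2/m2",
            expected_index="NDI",
        ),
        # leaf chlorophyll from NAOC
        "naoc_ch_linear": CalibrationResults(
            "linear", {"intercept": -3.8868, "slope": 101.94}, r=0.909, n=0,
            x_name="NAOC", y_name="Ch", y_units="ug/cm2",
            expected_index="NAOC",
        ),
        # canopy chlorophyll (Ch*LAI) from NAOC
        "naoc_chlai_exponential": CalibrationResults(
            "exponential", {"amplitude": 0.0219, "rate": 10.02}, r=0.795, n=0,
            x_name="NAOC", y_name="Ch*LAI", y_units="g/m2",
            expected_index="NAOC",
        ),
    }


PRESETS = _presets()


def preset(name: str) -> CalibrationResults:
    """A fresh copy of a named published calibration preset."""
    try:
        return _presets()[name]
    except KeyError:
        raise UsageError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


# -- validation statistics ----------------------------------------------

@dataclass
class ValidationReport:
    """Agreement statistics between predictions and reference values.

    rmse and bias are in the units of the target variable; r is Pearson
    (NaN when fewer than 3 points or zero variance).
    """

    rmse: float
    r: float
    n: int
    bias: float
    per_class: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "rmse": self.rmse,
            "r": None if not np.isfinite(self.r) else self.r,
            "n": self.n,
            "bias": self.bias,
        }
        if self.per_class is not None:
            d["per_class"] = self.per_class.to_dict(orient="records")
        return d

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def __str__(self) -> str:
        r_txt = f"{self.r:.4f}" if np.isfinite(self.r) else "undefined"
        return (
            f"ValidationReport(n={self.n}, rmse={self.rmse:.4g}, "
            f"bias={self.bias:.4g}, r={r_txt})"
        )


def _stats_block(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float, float]:
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    r = _pearson(pred, obs) if pred.size >= 3 else float("nan")
    return rmse, bias, r


def validate(pred: IndexMap, truth) -> ValidationReport:
    """Validate a parameter map against ground-truth points.

    `truth` is a DataFrame with columns row, col, value and optionally
    class_label (or an iterable of (row, col, value[, class_label]) tuples).
    Points falling on masked pixels are dropped; at least one usable point
    is required.
    """
    if not isinstance(truth, pd.DataFrame):
        records = [tuple(t) for t in truth]
        names = ["row", "col", "value", "class_label"]
        width = len(records[0]) if records else 3
        truth = pd.DataFrame(records, columns=names[:width])
    truth = truth.rename(columns={"pixel_row": "row", "pixel_col": "col"})
    required = {"row", "col", "value"}
    if not required <= set(truth.columns):
        raise UsageError(f"truth table needs columns {sorted(required)}")
    rows = truth["row"].to_numpy(int)
    cols = truth["col"].to_numpy(int)
    in_grid = (rows >= 0) & (rows < pred.n_rows) & (cols >= 0) & (cols < pred.n_cols)
    usable = in_grid.copy()
    usable[in_grid] &= ~pred.mask[rows[in_grid], cols[in_grid]]
    if not usable.any():
        raise UsageError("no truth point falls on an unmasked pixel")
    sub = truth.loc[usable].copy()
    p = pred.values[sub["row"].to_numpy(int), sub["col"].to_numpy(int)]
    o = sub["value"].to_numpy(float)
    rmse, bias, r = _stats_block(p, o)
    per_class = None
    if "class_label" in sub.columns:
        records = []
        for label, grp in sub.assign(_pred=p).groupby("class_label"):
            c_rmse, c_bias, c_r = _stats_block(
                grp["_pred"].to_numpy(), grp["value"].to_numpy()
            )
            records.append(
                {"class_label": label, "n": len(grp), "rmse": c_rmse,
                 "bias": c_bias, "r": c_r}
            )
        per_class = pd.DataFrame(records)
    return ValidationReport(rmse=rmse, r=r, n=int(usable.sum()), bias=bias,
                            per_class=per_class)


def map_agreement(map_a: IndexMap, map_b: IndexMap) -> tuple[ValidationReport, pd.DataFrame]:
    """Map-vs-map agreement over jointly unmasked pixels.

    Returns the report plus the paired values (for a scatter plot); map_a
    plays the prediction role in rmse/bias.
    """
    if map_a.values.shape != map_b.values.shape:
        raise UsageError(
            f"grid mismatch: {map_a.values.shape} vs {map_b.values.shape}"
        )
    joint = ~(map_a.mask | map_b.mask)
    if joint.sum() < 3:
        raise UsageError("need >= 3 jointly unmasked pixels")
    rows, cols = np.nonzero(joint)
    a, b = map_a.values[joint], map_b.values[joint]
    rmse, bias, r = _stats_block(a, b)
    pairs = pd.DataFrame(
        {"pixel_row": rows, "pixel_col": cols, "value_a": a, "value_b": b}
    )
    return ValidationReport(rmse=rmse, r=r, n=int(joint.sum()), bias=bias), pairs
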