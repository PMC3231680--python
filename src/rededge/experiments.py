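"""End-to-end experiment orchestration.

Two canonical experiments are provided:

``run_lai_experiment``
    Green LAI retrieval twice over — NDI(674, 712) on the fine-band source
    cube and NDI(665, 705) on its S2-resampled counterpart (B4/B5) — with a
    proportional calibration either fitted from ground truth or taken from
    the published presets (slopes 6.753 and 8.452). Reports map-vs-map
    agreement and validation against the truth points.

``run_naoc_ablation``
    The red-edge ablation: NAOC on the fine-band cube (reference), on the
    S2 cube with B4-B7, and on the S2 cube with B4+B7 only; an exponential
    Ch*LAI calibration (fitted, or the 0.0219*exp(10.02*NAOC) preset) turns
    each NAOC map into a canopy-chlorophyll map, and every S2 variant is
    scored against the reference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cube_io
from .calibration import (
    CalibrationResults,
    ValidationReport,
    fit_exponential,
    fit_proportional,
    map_agreement,
    preset,
    validate,
)
from .errors import UsageError
from .indices import IndexMap, NAOCConfig, naoc, naoc_bandset_variants, ndi
from .simulate import SceneParams, SceneTruth, simulate_scene
from .spectral import (
    BandSet,
    ReflectanceCube,
    SRFModel,
    covered_bands,
    resample_cube,
    s2_bandset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "LAIExperimentResult",
    "AblationResult",
    "run_lai_experiment",
    "run_naoc_ablation",
]

#: band pairings: fine-band (CHRIS-like) NDI and its S2 B4/B5 counterpart
NDI_PAIR_FINE = (674.0, 712.0)
NDI_PAIR_S2 = (665.0, 705.0)


@dataclass
class ExperimentConfig:
    """Configuration shared by both experiments.

    Exactly one of `input_path` and `scene_params` must be supplied; in the
    latter case the scene is simulated and its exact truth is used wherever
    a truth table would be. `calibration` is either "fit" (calibrate on the
    truth), a preset name, or a ready :class:`CalibrationResults`.
    """

    input_path: str | None = None
    input_format: str = "envi"
    scene_params: SceneParams | None = None
    bandset: BandSet = field(default_factory=s2_bandset)
    srf: SRFModel = field(default_factory=SRFModel)
    naoc: NAOCConfig = field(default_factory=NAOCConfig)
    calibration: str | CalibrationResults = "fit"
    truth: pd.DataFrame | str | None = None
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.scene_params is None):
            raise UsageError("supply exactly one of input_path and scene_params")

    def load(self) -> tuple[ReflectanceCube, SceneTruth | None]:
        if self.scene_params is not None:
            return simulate_scene(self.scene_params)
        return cube_io.load_cube(self.input_path, self.input_format), None

    def truth_table(self, scene_truth: SceneTruth | None, value: str) -> pd.DataFrame | None:
        """Resolve the truth table: explicit table > simulated truth > None."""
        if self.truth is not None:
            df = (
                pd.read_csv(self.truth)
                if isinstance(self.truth, (str, Path))
                else self.truth.copy()
            )
            return df.rename(columns={"pixel_row": "row", "pixel_col": "col"})
        if scene_truth is not None:
            return scene_truth.to_dataframe(value=value)
        return None


def _truth_xy(index_map: IndexMap, truth: pd.DataFrame):
    rows = truth["row"].to_numpy(int)
    cols = truth["col"].to_numpy(int)
    ok = ~index_map.mask[rows, cols]
    return index_map.values[rows[ok], cols[ok]], truth["value"].to_numpy(float)[ok]


@dataclass
class LAIExperimentResult:
    lai_map_fine: IndexMap
    lai_map_s2: IndexMap
    ndi_map_fine: IndexMap
    ndi_map_s2: IndexMap
    calibration_fine: CalibrationResults
    calibration_s2: CalibrationResults
    agreement: ValidationReport
    agreement_pairs: pd.DataFrame
    validation_fine: ValidationReport | None
    validation_s2: ValidationReport | None

    def report_dict(self) -> dict:
        d = {
            "calibration_fine": json.loads(self.calibration_fine.to_json()),
            "calibration_s2": json.loads(self.calibration_s2.to_json()),
            "map_agreement": self.agreement.to_dict(),
        }
        if self.validation_fine is not None:
            d["validation_fine"] = self.validation_fine.to_dict()
        if self.validation_s2 is not None:
            d["validation_s2"] = self.validation_s2.to_dict()
        return d


def run_lai_experiment(config: ExperimentConfig) -> LAIExperimentResult:
    """LAI retrieval on fine bands and on S2-resampled bands; see module doc."""
    cube, scene_truth = config.load()
    truth = config.truth_table(scene_truth, value="lai")

    logger.info("stage ndi: fine-band pair %s", NDI_PAIR_FINE)
    ndi_fine = ndi(cube, *NDI_PAIR_FINE)
    bands = covered_bands(config.bandset, cube.wavelengths, config.srf)
    logger.info("stage resample: %s (%s SRF), %d covered bands",
                config.bandset.name, config.srf.shape, len(bands))
    s2_cube = resample_cube(cube, bands, config.srf)
    ndi_s2 = ndi(s2_cube, *NDI_PAIR_S2)

    if isinstance(config.calibration, CalibrationResults):
        cal_fine = cal_s2 = config.calibration
    elif config.calibration == "fit":
        if truth is None:
            raise UsageError("calibration='fit' needs a truth table or simulated scene")
        cal_fine = fit_proportional(
            *_truth_xy(ndi_fine, truth),
            x_name=f"NDI{NDI_PAIR_FINE}", y_name="green LAI", y_units="m2/m2",
        )
        cal_s2 = fit_proportional(
            *_truth_xy(ndi_s2, truth),
            x_name=f"NDI{NDI_PAIR_S2}", y_name="green LAI", y_units="m2/m2",
        )
    else:  # preset names: fine-band and S2 slopes
        cal_fine = preset("chris_lai_ndi") if config.calibration == "preset" else preset(config.calibration)
        cal_s2 = preset("s2_lai_ndi") if config.calibration == "preset" else preset(config.calibration)

    lai_fine = cal_fine.predict(ndi_fine)
    lai_s2 = cal_s2.predict(ndi_s2)
    agreement, pairs = map_agreement(lai_s2, lai_fine)
    val_fine = validate(lai_fine, truth) if truth is not None else None
    val_s2 = validate(lai_s2, truth) if truth is not None else None
    return LAIExperimentResult(
        lai_map_fine=lai_fine, lai_map_s2=lai_s2,
        ndi_map_fine=ndi_fine, ndi_map_s2=ndi_s2,
        calibration_fine=cal_fine, calibration_s2=cal_s2,
        agreement=agreement, agreement_pairs=pairs,
        validation_fine=val_fine, validation_s2=val_s2,
    )


@dataclass
class AblationResult:
    naoc_reference: IndexMap
    naoc_with_rededge: IndexMap
    naoc_without_rededge: IndexMap | None
    chlai_reference: IndexMap
    chlai_with_rededge: IndexMap
    chlai_without_rededge: IndexMap | None
    calibration: CalibrationResults
    naoc_agreement_with: ValidationReport
    naoc_agreement_without: ValidationReport | None
    chlai_agreement_with: ValidationReport
    chlai_agreement_without: ValidationReport | None
    ablation_error: str | None = None

    def report_dict(self) -> dict:
        d = {
            "calibration": json.loads(self.calibration.to_json()),
            "naoc_agreement_with_rededge": self.naoc_agreement_with.to_dict(),
            "chlai_agreement_with_rededge": self.chlai_agreement_with.to_dict(),
        }
        if self.naoc_agreement_without is not None:
            d["naoc_agreement_without_rededge"] = self.naoc_agreement_without.to_dict()
            d["chlai_agreement_without_rededge"] = self.chlai_agreement_without.to_dict()
        if self.ablation_error:
            d["ablation_error"] = self.ablation_error
        return d


def run_naoc_ablation(config: ExperimentConfig) -> AblationResult:
    """Red-edge ablation for canopy chlorophyll; see module doc.

    A failure in the without-red-edge branch is recorded but does not abort
    the full-band branch.
    """
    cube, scene_truth = config.load()
    truth = config.truth_table(scene_truth, value="ch_lai")

    logger.info("stage naoc: reference on %d source bands", cube.n_bands)
    naoc_ref = naoc(cube, config.naoc)
    bands = covered_bands(config.bandset, cube.wavelengths, config.srf)
    s2_cube = resample_cube(cube, bands, config.srf)
    ablation_error = None
    naoc4, naoc2 = naoc_bandset_variants(s2_cube, config.naoc)

    if isinstance(config.calibration, CalibrationResults):
        cal = config.calibration
    elif config.calibration == "fit":
        if truth is None:
            raise UsageError("calibration='fit' needs a truth table or simulated scene")
        x, y = _truth_xy(naoc_ref, truth)
        keep = y > 0  # exponential fit domain
        cal = fit_exponential(
            x[keep], y[keep], x_name="NAOC", y_name="Ch*LAI", y_units="g/m2"
        )
    else:
        cal = preset("naoc_chlai_exponential" if config.calibration == "preset" else config.calibration)

    chlai_ref = cal.predict(naoc_ref)
    chlai4 = cal.predict(naoc4)
    naoc_agree4, _ = map_agreement(naoc4, naoc_ref)
    chlai_agree4, _ = map_agreement(chlai4, chlai_ref)

    chlai2 = naoc_agree2 = chlai_agree2 = None
    try:
        chlai2 = cal.predict(naoc2)
        naoc_agree2, _ = map_agreement(naoc2, naoc_ref)
        chlai_agree2, _ = map_agreement(chlai2, chlai_ref)
    except Exception as exc:  # ablation branch must not sink the full-band one
        ablation_error = f"{type(exc).__name__}: {exc}"
        logger.warning("without-red-edge branch failed: %s", ablation_error)
        naoc2 = None

    return AblationResult(
        naoc_reference=naoc_ref,
        naoc_with_rededge=naoc4,
        naoc_without_rededge=naoc2,
        chlai_reference=chlai_ref,
        chlai_with_rededge=chlai4,
        chlai_without_rededge=chlai2,
        calibration=cal,
        naoc_agreement_with=naoc_agree4,
        naoc_agreement_without=naoc_agree2,
        chlai_agreement_with=chlai_agree4,
        chlai_agreement_without=chlai_agree2,
        ablation_error=ablation_error,
    )
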