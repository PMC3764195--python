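"""Bulk c-di-GMP amounts to average intracellular concentrations.

LC-MS/MS quantification yields a total c-di-GMP amount (pmol) per culture
sample.  To express that as an intracellular concentration the amount is
normalized to the total bacterial cytoplasmic volume of the sample:

    cells      = (CFU per OD unit) * OD660 * culture volume
    volume (L) = cells * median single-cell volume (1 um^3 = 1e-15 L)
    [c-di-GMP] = amount / volume        (reported in nM)

The CFU-per-OD slope comes from a through-origin linear regression of a
CFU-vs-OD calibration table (no cells at zero OD), and the single-cell
volume from the median of per-cell volumes computed from measured lengths
and widths under a spherocylinder (rod with hemispherical caps) model; a
plain cylinder model is available as an option.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ParseError

__all__ = [
    "CellGeometrySample",
    "CultureCalibration",
    "BulkMeasurement",
    "spherocylinder_volume",
    "cylinder_volume",
    "median_cell_volume",
    "cfu_per_od",
    "intracellular_concentration",
    "conversion_report",
]

#: 1 cubic micrometre in litres.
UM3_TO_L = 1e-15
#: 1 picomole in moles.
PMOL_TO_MOL = 1e-12
#: moles per litre -> nanomolar.
M_TO_NM = 1e9


@dataclasses.dataclass
class CellGeometrySample:
    """Paired per-cell lengths and widths in micrometres."""

    lengths: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.lengths.shape != self.widths.shape or self.lengths.ndim != 1:
            raise ParameterError("lengths and widths must be equal-length 1-d")
        if self.lengths.size and (
            np.any(self.lengths <= 0) or np.any(self.widths <= 0)
        ):
            raise ParameterError("cell dimensions must be positive")
        if np.any(self.widths > self.lengths):
            raise ParameterError("cell width cannot exceed cell length")

    def __len__(self) -> int:
        return int(self.lengths.size)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"length_um": self.lengths, "width_um": self.widths}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CellGeometrySample":
        df = pd.read_csv(path)
        for col in ("length_um", "width_um"):
            if col not in df.columns:
                raise ParseError(f"{path}: missing required column '{col}'")
        return cls(
            lengths=df["length_um"].to_numpy(float),
            widths=df["width_um"].to_numpy(float),
        )


@dataclasses.dataclass
class CultureCalibration:
    """Paired OD660 and CFU/mL calibration points."""

    od_values: np.ndarray
    cfu_values: np.ndarray

    def __post_init__(self) -> None:
        self.od_values = np.asarray(self.od_values, dtype=float)
        self.cfu_values = np.asarray(self.cfu_values, dtype=float)
        if self.od_values.shape != self.cfu_values.shape or self.od_values.ndim != 1:
            raise ParameterError("od and cfu must be equal-length 1-d arrays")
        if np.any(self.od_values < 0) or np.any(self.cfu_values < 0):
            raise ParameterError("calibration values must be non-negative")

    def __len__(self) -> int:
        return int(self.od_values.size)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"od660": self.od_values, "cfu_per_ml": self.cfu_values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CultureCalibration":
        df = pd.read_csv(path)
        for col in ("od660", "cfu_per_ml"):
            if col not in df.columns:
                raise ParseError(f"{path}: missing required column '{col}'")
        return cls(
            od_values=df["od660"].to_numpy(float),
            cfu_values=df["cfu_per_ml"].to_numpy(float),
        )


@dataclasses.dataclass(frozen=True)
class BulkMeasurement:
    """One bulk LC-MS/MS sample: amount (pmol), culture OD660 and volume (mL)."""

    total_amount_pmol: float
    culture_od: float
    culture_volume_ml: float

    def __post_init__(self) -> None:
        if (
            self.total_amount_pmol < 0
            or self.culture_od < 0
            or self.culture_volume_ml < 0
        ):
            raise ParameterError("bulk measurement values must be non-negative")


def spherocylinder_volume(length, width):
    """Volume (um^3) of a rod with hemispherical caps.

    V = pi (w/2)^2 (L - w) + (4/3) pi (w/2)^3; L = w degenerates to a sphere.
    Accepts scalars or arrays.
    """
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ParameterError("length and width must be positive")
    if np.any(width > length):
        raise ParameterError("width cannot exceed length")
    r = width / 2.0
    v = math.pi * r**2 * (length - width) + (4.0 / 3.0) * math.pi * r**3
    return float(v) if v.ndim == 0 else v


def cylinder_volume(length, width):
    """Volume (um^3) of a plain cylinder of the same length and diameter."""
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ParameterError("length and width must be positive")
    if np.any(width > length):
        raise ParameterError("width cannot exceed length")
    v = math.pi * (width / 2.0) ** 2 * length
    return float(v) if v.ndim == 0 else v


_VOLUME_MODELS = {
    "spherocylinder": spherocylinder_volume,
    "cylinder": cylinder_volume,
}


def median_cell_volume(
    sample: CellGeometrySample, model: str = "spherocylinder"
) -> float:
    """Median per-cell volume (um^3) of a geometry sample.

    For an even number of cells the mean of the central pair is used
    (ordinary median).
    """
    if len(sample) == 0:
        raise ParameterError("geometry sample is empty")
    try:
        volume = _VOLUME_MODELS[model]
    except KeyError:
        raise ParameterError(
            f"unknown volume model '{model}'; choose from {sorted(_VOLUME_MODELS)}"
        ) from None
    return float(np.median(volume(sample.lengths, sample.widths)))


def cfu_per_od(cal: CultureCalibration, through_origin: bool = True) -> float:
    """CFU/mL per OD660 unit from a calibration table.

    Default is the through-origin least-squares slope sum(od*cfu)/sum(od^2)
    (a culture at zero OD contains no cells); an ordinary regression with
    intercept is available with ``through_origin=False`` (slope only is
    returned).
    """
    if len(cal) < 2:
        raise ParameterError("calibration needs at least 2 points")
    od, cfu = cal.od_values, cal.cfu_values
    if through_origin:
        denom = float(np.sum(od**2))
        if denom == 0.0:
            raise ParameterError("all OD values are zero; slope undefined")
        return float(np.sum(od * cfu) / denom)
    if np.ptp(od) == 0.0:
        raise ParameterError("OD values are constant; slope undefined")
    slope, _ = np.polyfit(od, cfu, deg=1)
    return float(slope)


def intracellular_concentration(
    bulk: BulkMeasurement, slope: float, cell_volume: float
) -> float:
    """Average intracellular concentration (nM) of one bulk sample.

    ``slope`` is CFU/mL per OD unit and ``cell_volume`` the median
    single-cell volume in um^3.  A zero amount gives 0 nM; a nonzero amount
    with zero estimated cells is an error.
    """
    if slope <= 0:
        raise ParameterError("CFU/OD slope must be positive")
    if cell_volume <= 0:
        raise ParameterError("cell volume must be positive")
    if bulk.total_amount_pmol == 0.0:
        return 0.0
    n_cells = slope * bulk.culture_od * bulk.culture_volume_ml
    if n_cells == 0.0:
        raise ParameterError(
            "sample reports c-di-GMP but zero cells (OD or volume is zero)"
        )
    total_volume_l = n_cells * cell_volume * UM3_TO_L
    molar = bulk.total_amount_pmol * PMOL_TO_MOL / total_volume_l
    return molar * M_TO_NM


def conversion_report(
    sample: CellGeometrySample,
    cal: CultureCalibration,
    bulks: list[BulkMeasurement],
    volume_model: str = "spherocylinder",
    through_origin: bool = True,
) -> dict:
    """Full unit-conversion summary for a batch of bulk samples."""
    volume = median_cell_volume(sample, model=volume_model)
    slope = cfu_per_od(cal, through_origin=through_origin)
    return {
        "volume_model": volume_model,
        "median_cell_volume_um3": volume,
        "cfu_per_od_per_ml": slope,
        "n_geometry_cells": len(sample),
        "n_calibration_points": len(cal),
        "samples": [
            {
                "total_amount_pmol": b.total_amount_pmol,
                "culture_od": b.culture_od,
                "culture_volume_ml": b.culture_volume_ml,
                "intracellular_nM": intracellular_concentration(b, slope, volume),
            }
            for b in bulks
        ],
    }
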