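"""Band-ratio spectral lipidomics and the two linear calibrations.

Seven semiquantitative metrics are computed as ratios of locally baselined
band areas (numerator / denominator sums):

====================  ========  =================================
metric                modality  bands (cm^-1)
====================  ========  =================================
tags                  FTIR      1743 / 1465
ces                   FTIR      1178 / 1465
total_lipids          FTIR      (2852 + 2954) / 1465
pls                   Raman     1129 / 1451
ufas                  Raman     1660 / 1451
chain_length          FTIR      2852 / 2954
cytochromes           Raman     (1585 + 1316 + 750) / 1451
====================  ========  =================================

Two linear calibrations convert ratios into chemistry: the CH2/CH3
(2852/2954) ratio versus total acyl carbon count, trained on a series of
saturated triacylglycerol standards where the ratio is exactly N/3 - 2, and
the C=C/CH2-deformation (1660/1451) ratio versus C=C bonds per acyl chain,
trained on the C18 fatty-acid series (stearic through alpha-linolenic).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BandWindow, Modality, Spectrum, ValidationError, integrate_band
from .library import (
    FATTY_ACID_SERIES,
    SATURATED_TAG_STANDARDS,
    build_component_spectrum,
    fatty_acid,
    saturated_tag,
)
from .phantom import default_ftir_axis, default_raman_axis

__all__ = [
    "MetricDefinition",
    "default_metrics",
    "compute_ratio",
    "CalibrationModel",
    "fit_linear_calibration",
    "ideal_tag_spectrum",
    "ideal_fatty_acid_spectrum",
    "build_chain_length_calibration",
    "build_unsaturation_calibration",
    "chain_length_from_spectrum",
    "unsaturation_from_spectrum",
    "metric_table",
]

# default integration half-widths around named band centers
HALF_WIDTH = {Modality.RAMAN: 8.0, Modality.FTIR: 10.0}


@dataclass(frozen=True)
class MetricDefinition:
    """A band-ratio metric: sums of numerator and denominator band areas."""

    name: str
    modality: Modality
    numerator: tuple[float, ...]
    denominator: tuple[float, ...]
    half_width: float | None = None
    baseline_mode: str = "linear_endpoints"

    def __post_init__(self) -> None:
        if not self.denominator:
            raise ValidationError("metric denominator must be nonempty")
        object.__setattr__(self, "modality", Modality.coerce(self.modality))
        object.__setattr__(self, "numerator", tuple(self.numerator))
        object.__setattr__(self, "denominator", tuple(self.denominator))

    def windows(self, centers: tuple[float, ...]) -> list[BandWindow]:
        hw = self.half_width or HALF_WIDTH[self.modality]
        return [
            BandWindow.around(c, hw, baseline_mode=self.baseline_mode)
            for c in centers
        ]


def default_metrics() -> dict[str, MetricDefinition]:
    """The seven built-in box-diagram metrics."""
    R, I = Modality.RAMAN, Modality.FTIR
    defs = [
        MetricDefinition("tags", I, (1743.0,), (1465.0,)),
        MetricDefinition("ces", I, (1178.0,), (1465.0,)),
        MetricDefinition("total_lipids", I, (2852.0, 2954.0), (1465.0,)),
        MetricDefinition("pls", R, (1129.0,), (1451.0,)),
        MetricDefinition("ufas", R, (1660.0,), (1451.0,)),
        MetricDefinition("chain_length", I, (2852.0,), (2954.0,)),
        MetricDefinition("cytochromes", R, (1585.0, 1316.0, 750.0), (1451.0,)),
    ]
    return {d.name: d for d in defs}


def compute_ratio(spectrum: Spectrum, metric: MetricDefinition) -> float:
    """Sum of numerator band areas over sum of denominator band areas.

    A nonpositive denominator yields NaN (an undefined-value flag) rather
    than an exception, since empty compartments legitimately lack bands.
    Windows use exact (interpolated) bounds so equal-width numerator and
    denominator windows capture identical fractions of equal-shape bands.
    """
    num = sum(integrate_band(spectrum, w, snap=False)
              for w in metric.windows(metric.numerator))
    den = sum(integrate_band(spectrum, w, snap=False)
              for w in metric.windows(metric.denominator))
    if den <= 0:
        return float("nan")
    return float(num / den)


@dataclass
class CalibrationModel:
    """Linear map ratio = slope * property + intercept, inverted to predict."""

    kind: str  # "chain_length" | "unsaturation"
    slope: float
    intercept: float
    r_squared: float
    training_points: list[tuple[float, float]]  # (property, ratio)
    valid_range: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.training_points) < 2:
            raise ValidationError("calibration needs at least two points")
        if self.slope == 0:
            raise ValidationError("zero-slope calibration is unusable")

    def predict_property(self, ratio: float) -> tuple[float, bool]:
        """Inverse-calibrated property and an extrapolation flag.

        The flag is set when the predicted property falls outside the
        training range widened by 10% of its span.
        """
        value = (ratio - self.intercept) / self.slope
        low, high = self.valid_range
        margin = 0.1 * (high - low)
        return value, not (low - margin <= value <= high + margin)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "slope": self.slope,
                "intercept": self.intercept,
                "r_squared": self.r_squared,
                "training_points": self.training_points,
                "valid_range": self.valid_range,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        payload = json.loads(text)
        payload["training_points"] = [
            tuple(p) for p in payload["training_points"]
        ]
        payload["valid_range"] = tuple(payload["valid_range"])
        return cls(**payload)


def fit_linear_calibration(
    points: Sequence[tuple[float, float]], kind: str = "chain_length"
) -> CalibrationModel:
    """Ordinary least squares of ratio on property."""
    props = np.array([p for p, _ in points], dtype=float)
    ratios = np.array([r for _, r in points], dtype=float)
    if np.unique(props).size < 2:
        raise ValidationError("need at least two distinct property values")
    fit = stats.linregress(props, ratios)
    if fit.slope == 0:
        raise ValidationError("zero-slope calibration is unusable")
    return CalibrationModel(
        kind=kind,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        training_points=[(float(p), float(r)) for p, r in zip(props, ratios)],
        valid_range=(float(props.min()), float(props.max())),
    )


# -------------------------------------------------- ideal calibration series

def ideal_tag_spectrum(total_carbons: int, axis=None) -> Spectrum:
    """Ideal FTIR spectrum of a saturated TAG standard (Gaussian bands)."""
    axis = axis or default_ftir_axis()
    return build_component_spectrum(saturated_tag(total_carbons), axis,
                                    Modality.FTIR)


def ideal_fatty_acid_spectrum(
    double_bonds: int, carbons: int = 18, axis=None
) -> Spectrum:
    """Ideal Raman spectrum of a C18 fatty acid with ``double_bonds`` C=C."""
    axis = axis or default_raman_axis()
    return build_component_spectrum(fatty_acid(carbons, double_bonds), axis,
                                    Modality.RAMAN)


def build_chain_length_calibration(
    exclude: Sequence[str] = (), axis=None
) -> CalibrationModel:
    """Fit the CH2/CH3 chain-length calibration on the eight TAG standards.

    ``exclude`` names standards held out of the fit (e.g. ``['trilaurin']``
    for a held-out prediction check).
    """
    metric = default_metrics()["chain_length"]
    points = []
    for name, n in SATURATED_TAG_STANDARDS.items():
        if name in exclude:
            continue
        points.append((float(n), compute_ratio(ideal_tag_spectrum(n, axis), metric)))
    return fit_linear_calibration(points, kind="chain_length")


def build_unsaturation_calibration(
    exclude: Sequence[str] = (), axis=None
) -> CalibrationModel:
    """Fit the 1660/1451 unsaturation calibration on the fatty-acid series."""
    metric = default_metrics()["ufas"]
    points = []
    for name, (carbons, db) in FATTY_ACID_SERIES.items():
        if name in exclude:
            continue
        spectrum = ideal_fatty_acid_spectrum(db, carbons, axis)
        points.append((float(db), compute_ratio(spectrum, metric)))
    return fit_linear_calibration(points, kind="unsaturation")


@dataclass
class Prediction:
    value: float
    ratio: float
    extrapolated: bool
    nearest_standard: str | None = None


def chain_length_from_spectrum(
    spectrum: Spectrum, model: CalibrationModel
) -> Prediction:
    """Total acyl carbon count from the 2852/2954 ratio of an IR spectrum."""
    if model.kind != "chain_length":
        raise ValidationError("model is not a chain-length calibration")
    ratio = compute_ratio(spectrum, default_metrics()["chain_length"])
    value, extrapolated = model.predict_property(ratio)
    nearest = min(
        SATURATED_TAG_STANDARDS, key=lambda k: abs(SATURATED_TAG_STANDARDS[k] - value)
    )
    return Prediction(value, ratio, extrapolated, nearest)


def unsaturation_from_spectrum(
    spectrum: Spectrum, model: CalibrationModel
) -> Prediction:
    """Mean C=C bonds per acyl chain from the 1660/1451 Raman ratio."""
    if model.kind != "unsaturation":
        raise ValidationError("model is not an unsaturation calibration")
    ratio = compute_ratio(spectrum, default_metrics()["ufas"])
    value, extrapolated = model.predict_property(ratio)
    return Prediction(value, ratio, extrapolated)


# ------------------------------------------------------------- metric table

def metric_table(
    class_spectra: Mapping[str, Mapping[str, Spectrum | Sequence[Spectrum]]],
    metrics: Mapping[str, MetricDefinition] | None = None,
) -> pd.DataFrame:
    """Long-format table of every (sample, compartment, metric) value.

    ``class_spectra`` maps sample id -> compartment -> one Spectrum or a
    sequence of spectra of different modalities.  Metrics whose modality has
    no matching spectrum are skipped with a warning; undefined ratios (zero
    denominator) are kept as NaN rows flagged ``defined=False``.
    """
    metrics = metrics or default_metrics()
    rows = []
    for sample, compartments in class_spectra.items():
        for compartment, spectra in compartments.items():
            if isinstance(spectra, Spectrum):
                spectra = [spectra]
            by_modality = {s.modality: s for s in spectra}
            for metric in metrics.values():
                spectrum = by_modality.get(metric.modality)
                if spectrum is None:
                    warnings.warn(
                        f"no {metric.modality.value} spectrum for "
                        f"({sample}, {compartment}); metric "
                        f"{metric.name!r} skipped"
                    )
                    continue
                value = compute_ratio(spectrum, metric)
                rows.append(
                    {
                        "sample": sample,
                        "compartment": compartment,
                        "metric": metric.name,
                        "value": value,
                        "defined": bool(np.isfinite(value)),
                    }
                )
    return pd.DataFrame(
        rows, columns=["sample", "compartment", "metric", "value", "defined"]
    )
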