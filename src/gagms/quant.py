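"""Internal-standard quantification: calibration, inversion, total HS.

Targeted (MRM/PRM) assays report analyte peak area over internal-standard
peak area; a weighted linear calibration of that response against known
concentration converts sample responses to concentrations.  For the
heparan sulfate disaccharide assay, eight heparin-lyase digestion
products are quantified on separate transition channels and summed to a
total-HS value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = [
    "TransitionChannel",
    "CalibrationCurve",
    "QuantResult",
    "HS_CHANNELS",
    "DEFAULT_TRANSITIONS",
    "normalize_response",
    "fit_calibration",
    "quantify_analyte",
    "total_hs",
]

#: The eight disaccharide channels of the heparan sulfate assay.
HS_CHANNELS: tuple[str, ...] = tuple(f"H100{i}" for i in range(1, 9))


@dataclass(frozen=True)
class TransitionChannel:
    """One MRM transition: analyte code, precursor and product m/z."""

    code: str
    precursor_mz: float
    product_mz: float

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("transition m/z must be positive")


#: Published transition tables.  The HILIC disaccharide method monitors
#: the eight lyase products (H1005 doubles as the internal standard when
#: spiked); the biomarker method monitors the trisaccharide's SO3 loss.
DEFAULT_TRANSITIONS: dict[str, TransitionChannel] = {
    c.code: c
    for c in (
        TransitionChannel("H1001", 287.5, 247.6),
        TransitionChannel("H1002", 496.2, 416.0),
        TransitionChannel("H1003", 496.3, 416.0),
        TransitionChannel("H1004", 416.0, 137.8),
        TransitionChannel("H1005", 538.1, 458.0),
        TransitionChannel("H1006", 458.4, 174.9),
        TransitionChannel("H1007", 458.4, 157.0),
        TransitionChannel("H1008", 378.0, 175.0),
        TransitionChannel("BM652", 652.3, 572.1),
    )
}


def normalize_response(analyte_area: float, is_area: float) -> float:
    """Analyte peak area over internal-standard peak area."""
    if is_area <= 0:
        raise ValueError(
            "internal-standard area must be positive (zero IS area flags a "
            "failed injection)"
        )
    return analyte_area / is_area


@dataclass
class CalibrationCurve:
    """A fitted weighted-least-squares response line.

    ``points`` are (concentration, response) pairs; response is the
    IS-normalized area ratio.  Weighting 1/x or 1/x² down-weights the
    top of a calibration range spanning decades; LLOQ is the lowest
    calibrator concentration.
    """

    analyte: str
    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    weighting: str
    r_squared: float

    @property
    def lloq(self) -> float:
        return min(x for x, _ in self.points)

    @property
    def lloq_response(self) -> float:
        return self.predict(self.lloq)

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def residuals(self) -> np.ndarray:
        x = np.array([p[0] for p in self.points])
        y = np.array([p[1] for p in self.points])
        return y - self.predict(x)


def fit_calibration(
    points,
    weighting: str = "1/x",
    analyte: str = "",
) -> CalibrationCurve:
    """Weighted least-squares line through (concentration, response) points.

    ``weighting`` ∈ {"none", "1/x", "1/x²"} (also accepts "1/x^2"/"1/x2").
    """
    pts = tuple((float(x), float(y)) for x, y in points)
    if len(pts) < 2 or len({x for x, _ in pts}) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if weighting == "none":
        w = np.ones_like(x)
    elif weighting == "1/x":
        w = 1.0 / x
    elif weighting in ("1/x²", "1/x^2", "1/x2"):
        w = 1.0 / x**2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = model.params
    return CalibrationCurve(
        analyte=analyte,
        points=pts,
        slope=float(slope),
        intercept=float(intercept),
        weighting=weighting,
        r_squared=float(model.rsquared),
    )


@dataclass(frozen=True)
class QuantResult:
    """A quantified analyte in one sample."""

    analyte: str
    response: float
    concentration: float
    below_lloq: bool = False
    units: str = "ng/ml"


def quantify_analyte(
    response: float,
    curve: CalibrationCurve,
    units: str = "ng/ml",
) -> QuantResult:
    """Invert the calibration line: (response − intercept) / slope.

    Responses below the lowest calibrator's response are flagged
    below-LLOQ (their back-calculated concentration is still reported).
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    conc = (response - curve.intercept) / curve.slope
    return QuantResult(
        analyte=curve.analyte,
        response=response,
        concentration=conc,
        below_lloq=response < curve.lloq_response,
        units=units,
    )


def total_hs(per_channel: dict[str, QuantResult]) -> float:
    """Total heparan sulfate: the sum over all eight disaccharide channels.

    Below-LLOQ channels contribute zero, with a warning.  A missing
    channel is an error naming the channel.
    """
    missing = [c for c in HS_CHANNELS if c not in per_channel]
    if missing:
        raise ValueError(f"missing HS channel(s): {', '.join(missing)}")
    total = 0.0
    for code in HS_CHANNELS:
        r = per_channel[code]
        if r.below_lloq:
            warnings.warn(
                f"channel {code} below LLOQ; contributing 0 to total HS",
                stacklevel=2,
            )
        else:
            total += r.concentration
    return total
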