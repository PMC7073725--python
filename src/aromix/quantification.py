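"""Internal-standard calibration and back-calculation of concentrations.

Quantification follows the classical internal-standard scheme: for each
analyte a standard series is measured at several concentration levels, and
the peak-area ratio y (analyte area / internal-standard area) is regressed
on the concentration ratio x (analyte concentration / internal-standard
concentration), giving a line y = a*x + b.  An unknown sample's area ratio
is then inverted through the line and rescaled by the internal-standard
concentration (and any dilution applied to the sample) to give µg/L.

Back-calculated values that fall below the calibration range are *flagged*,
never silently clamped: a negative concentration is physically meaningless
but records that the measurement sat below the line's x-intercept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateDesignError,
    InsufficientDataError,
    InvalidCurveError,
)

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "concentration_from_area_ratio",
    "fit_calibration",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted internal-standard calibration line y = slope*x + intercept.

    Parameters
    ----------
    compound_id
        Analyte identifier.
    quant_ion
        Quantifier ion (m/z) used for peak integration, if known.
    slope, intercept
        Line coefficients on the (concentration-ratio, area-ratio) plane.
    r_squared
        Coefficient of determination of the fit, in [0, 1].
    is_concentration
        Concentration of the internal standard in the prepared vial (µg/L).
        Needed to map the dimensionless concentration ratio back to µg/L.
    """

    compound_id: str
    slope: float
    intercept: float
    r_squared: float | None = None
    is_concentration: float | None = None
    quant_ion: int | None = None

    def __post_init__(self) -> None:
        # A zero slope is representable (it is the OLS answer for a flat
        # response) but unusable: inversion refuses it with InvalidCurveError.
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise InvalidCurveError(
                f"{self.compound_id}: r_squared {self.r_squared} outside [0, 1]"
            )


@dataclass(frozen=True)
class QuantResult:
    """A back-calculated concentration for one compound in one sample."""

    compound_id: str
    sample_id: str
    concentration: float  # µg/L; may be negative when below_range
    below_range: bool = False
    rsd: float | None = None  # percent, over replicates


def concentration_from_area_ratio(
    curve: CalibrationCurve,
    area_ratio: float,
    dilution_factor: float = 1.0,
    sample_id: str = "",
) -> QuantResult:
    """Invert a calibration line to get a concentration in µg/L.

    The concentration ratio is x = (area_ratio - intercept) / slope; the
    analyte concentration in the original sample is then
    x * is_concentration * dilution_factor.

    Raises
    ------
    ConfigurationError
        If the curve has no internal-standard concentration attached.
    ValidationError
        If ``dilution_factor`` is not positive.
    """
    if curve.slope == 0:
        raise InvalidCurveError(
            f"{curve.compound_id}: zero slope, curve cannot be inverted"
        )
    if curve.is_concentration is None:
        raise ConfigurationError(
            f"{curve.compound_id}: internal-standard concentration not set"
        )
    if dilution_factor <= 0:
        from .errors import ValidationError

        raise ValidationError(f"dilution_factor must be > 0, got {dilution_factor}")
    x = (area_ratio - curve.intercept) / curve.slope
    conc = x * curve.is_concentration * dilution_factor
    return QuantResult(
        compound_id=curve.compound_id,
        sample_id=sample_id,
        concentration=conc,
        below_range=conc < 0,
    )


def fit_calibration(
    points: Sequence[tuple[float, float]],
    is_concentration: float | None = None,
    compound_id: str = "",
    quant_ion: int | None = None,
) -> CalibrationCurve:
    """Ordinary least-squares fit of area ratio on concentration ratio.

    ``points`` is a sequence of (concentration_ratio, area_ratio) pairs;
    at least three distinct concentration levels are required (standard
    series in routine use carry six).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InsufficientDataError("points must be (x, y) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct concentration levels, got {len(np.unique(x))}"
        )
    if np.ptp(x) == 0:
        raise DegenerateDesignError("zero variance in concentration ratios")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if math.isnan(r2):  # all y identical: define r² = 0, slope is 0 too
        r2 = 0.0
    return CalibrationCurve(
        compound_id=compound_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        is_concentration=is_concentration,
        quant_ion=quant_ion,
    )


def aggregate_replicates(results: Sequence[QuantResult]) -> QuantResult:
    """Collapse replicate measurements to mean concentration and RSD (%).

    RSD = 100 * sd / mean with the sample (ddof=1) standard deviation.
    All replicates must share compound and sample identifiers.
    """
    if not results:
        raise InsufficientDataError("no replicates to aggregate")
    ids = {(r.compound_id, r.sample_id) for r in results}
    if len(ids) > 1:
        from .errors import ValidationError

        raise ValidationError(f"replicates span multiple compound/sample ids: {ids}")
    conc = np.array([r.concentration for r in results], dtype=float)
    mean = float(conc.mean())
    if len(conc) > 1 and mean != 0:
        rsd = float(100.0 * conc.std(ddof=1) / abs(mean))
    else:
        rsd = None
    return QuantResult(
        compound_id=results[0].compound_id,
        sample_id=results[0].sample_id,
        concentration=mean,
        below_range=mean < 0,
        rsd=rsd,
    )
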