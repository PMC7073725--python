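"""Vector (parallelogram) model of perceived binary-mixture intensity.

Two odours are represented as vectors whose lengths are the perceived
intensities OIa and OIb of the unmixed components; the mixture's perceived
intensity is the length of the resultant,

    OIab^2 = OIa^2 + OIb^2 + 2 cos(alpha) OIa OIb,

where alpha is the angle between the vectors and cos(alpha) quantifies the
perceptual interaction.  When the two components are matched to equal
intensity (the usual design) the resultant simplifies via the half-angle
identity to

    OIab = (OIa + OIb) * cos(alpha/2),

so cos(alpha/2) is the slope of OIab against the unmixed intensity sum —
estimated here by least squares through the origin.

Intensities are rated against the 1-butanol odour intensity referencing
scale (OIRS): twelve aqueous standards doubling from 10 ppm (level 1) to
20,480 ppm (level 12).  Panel means of OIRS levels are treated as
continuous intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDesignError, DesignViolationError, ValidationError

__all__ = [
    "OIRS_LEVELS",
    "oirs_concentration",
    "vector_intensity",
    "cos_half_alpha_point",
    "fit_cos_half_alpha",
    "VectorFit",
]

#: Number of levels on the 1-butanol referencing scale.
OIRS_LEVELS = 12


def oirs_concentration(level: int) -> float:
    """1-butanol concentration (ppm) of an OIRS level: 10 * 2**(level-1).

    Level 1 is 10 ppm; each level doubles, up to 20,480 ppm at level 12.
    """
    if not (1 <= level <= OIRS_LEVELS) or int(level) != level:
        raise ValidationError(f"OIRS level must be an integer in 1..{OIRS_LEVELS}")
    return 10.0 * 2.0 ** (int(level) - 1)


def vector_intensity(oi_a: float, oi_b: float, cos_alpha: float) -> float:
    """Resultant intensity of two odour vectors at interaction cos(alpha).

    cos_alpha = 1 gives complete addition (OIa + OIb); cos_alpha = -1 full
    cancellation of equal components; 0 the orthogonal (Pythagorean) case.
    """
    if oi_a < 0 or oi_b < 0:
        raise ValidationError("intensities must be >= 0")
    if not (-1.0 <= cos_alpha <= 1.0):
        raise ValidationError("cos_alpha must lie in [-1, 1]")
    sq = oi_a**2 + oi_b**2 + 2.0 * cos_alpha * oi_a * oi_b
    return math.sqrt(max(sq, 0.0))  # guards tiny negative round-off at cos=-1


def cos_half_alpha_point(oi_ab: float, oi_a: float, oi_b: float, rtol: float = 0.05) -> float:
    """cos(alpha/2) from one equal-intensity mixture determination.

    Valid only for the equal-intensity design (OIa = OIb within ``rtol``
    relative tolerance); then cos(alpha/2) = OIab / (OIa + OIb).
    """
    if oi_ab < 0:
        raise ValidationError("mixture intensity must be >= 0")
    if oi_a + oi_b <= 0:
        raise ValidationError("component intensities must sum to > 0")
    if not math.isclose(oi_a, oi_b, rel_tol=rtol, abs_tol=1e-12):
        raise DesignViolationError(
            f"equal-intensity design violated: OIa={oi_a}, OIb={oi_b}"
        )
    return oi_ab / (oi_a + oi_b)


@dataclass
class VectorFit:
    """Estimated interaction of a binary pair under the vector model."""

    pair_id: str
    cos_half_alpha: float
    n_points: int
    r_squared: float
    intercept: float = 0.0  # non-zero only for the diagnostic unconstrained fit

    @property
    def cos_alpha(self) -> float:
        """Full-angle interaction via the half-angle identity."""
        return 2.0 * self.cos_half_alpha**2 - 1.0

    def predict(self, oi_sum):
        return self.intercept + self.cos_half_alpha * np.asarray(oi_sum, dtype=float)


def fit_cos_half_alpha(
    points: Sequence[tuple[float, float]],
    pair_id: str = "",
    through_origin: bool = True,
) -> VectorFit:
    """Estimate cos(alpha/2) as the slope of OIab on (OIa + OIb).

    ``points`` are (oi_sum, oi_ab) pairs from equal-intensity mixture
    determinations.  The model has no intercept, so the default estimator is
    least squares through the origin, slope = sum(x*y) / sum(x^2); an
    unconstrained line is available behind ``through_origin=False`` as a
    diagnostic for intercept drift.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, -1)
    if pts.size == 0 or pts.shape[1] != 2:
        raise ValidationError("points must be (oi_sum, oi_ab) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("intensities must be >= 0")
    if np.all(x == 0):
        raise DegenerateDesignError("all unmixed intensity sums are zero")
    if through_origin:
        slope = float(np.sum(x * y) / np.sum(x * x))
        intercept = 0.0
    else:
        if len(x) < 2 or np.ptp(x) == 0:
            raise DegenerateDesignError("unconstrained fit needs >= 2 distinct x")
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return VectorFit(
        pair_id=pair_id,
        cos_half_alpha=slope,
        n_points=len(x),
        r_squared=r2,
        intercept=intercept,
    )
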