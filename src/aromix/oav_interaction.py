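"""OAV additivity analysis of binary odour mixtures: the X-statistic.

If odour activity values were perfectly additive, a mixture containing
components at concentrations Ci with individual thresholds Ti would sit
above its own threshold Tm by exactly the sum of the component OAVs.  The
ratio

    X = (sum_i Ci/Ti) / OAVmix,       OAVmix = (sum_i Ci) / Tm,

measures the departure from that additivity: X = 1 is additive, X < 1
means the mixture is detected more easily than the components predict
(synergy), and X > 1 means antagonism.  Because panel thresholds are noisy,
an ``additive_band`` around 1 (default ±0.2) separates "close enough to
additive" from a real departure; the band is configurable and always
reported with the classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError

__all__ = [
    "MixtureOAV",
    "sum_oav",
    "x_statistic",
    "classify_x",
    "combine_classifications",
    "mixture_oav_from_measurements",
]


@dataclass
class MixtureOAV:
    """X-statistic record for one binary (or n-ary) mixture."""

    mixture_id: str
    component_oavs: list[float]
    oav_mix: float
    sum_oav: float
    x: float
    classification: str  # "additive" | "synergy" | "antagonism"
    additive_band: float = 0.2

    @property
    def x_display(self) -> str:
        return f"{self.x:.2f}"


def sum_oav(component_oavs: Sequence[float]) -> float:
    """Arithmetic sum of component odour activity values."""
    vals = list(component_oavs)
    if not vals:
        raise ValidationError("component OAV list is empty")
    if any(v <= 0 for v in vals):
        raise ValidationError("component OAVs must be positive")
    return float(sum(vals))


def x_statistic(sum_oav_value: float, oav_mix: float) -> float:
    """X = sum of component OAVs / mixture OAV; 1 means perfect additivity."""
    if oav_mix <= 0:
        raise ValidationError(f"OAVmix must be > 0, got {oav_mix}")
    if sum_oav_value <= 0:
        raise ValidationError(f"sum of OAVs must be > 0, got {sum_oav_value}")
    return float(sum_oav_value) / float(oav_mix)


def classify_x(x: float, additive_band: float = 0.2) -> str:
    """Label an X value: additive within the band around 1, else synergy/antagonism.

    ``synergy`` for x < 1 - band (the mixture outperforms OAV additivity),
    ``antagonism`` for x > 1 + band, ``additive`` in between.
    """
    if x <= 0:
        raise ValidationError(f"X must be > 0, got {x}")
    if additive_band < 0:
        raise ValidationError("additive_band must be >= 0")
    if abs(x - 1.0) <= additive_band:
        return "additive"
    return "synergy" if x < 1.0 else "antagonism"


#: Mapping from detection-model labels to X-statistic vocabulary.
_FELLER_TO_X = {
    "independent-additive": "additive",
    "synergy": "synergy",
    "suppression": "antagonism",
}


def combine_classifications(
    x_label: str, feller_label: str | None, prefer_feller: bool = True
) -> str:
    """Combined interaction call when both the X and Feller analyses exist.

    The X band is a heuristic on threshold ratios, while the Feller
    comparison carries a significance test; with ``prefer_feller`` (the
    default) the detection-model call wins whenever it is available — e.g.
    a mixture with X = 0.59 but a non-significant Feller departure is
    reported as additive.
    """
    if feller_label is None or not prefer_feller:
        return x_label
    try:
        return _FELLER_TO_X[feller_label]
    except KeyError:
        raise ValidationError(f"unknown Feller label {feller_label!r}") from None


def mixture_oav_from_measurements(
    component_concentrations: Sequence[float],
    component_thresholds: Sequence[float],
    mixture_threshold: float,
    mixture_id: str = "",
    additive_band: float = 0.2,
) -> MixtureOAV:
    """Full X-statistic computation from raw concentrations and thresholds.

    ``component_concentrations`` are the Ci at the tested mixture
    composition, ``component_thresholds`` the single-compound thresholds Ti
    (same units), and ``mixture_threshold`` the measured threshold Tm of the
    total mixture concentration.  OAVi = Ci/Ti, OAVmix = (sum Ci)/Tm.
    """
    cs = [float(c) for c in component_concentrations]
    ts = [float(t) for t in component_thresholds]
    if len(cs) != len(ts):
        raise ValidationError(
            f"{len(cs)} concentrations vs {len(ts)} thresholds"
        )
    if not cs:
        raise ValidationError("empty component lists")
    if any(c <= 0 for c in cs) or any(t <= 0 for t in ts) or mixture_threshold <= 0:
        raise ValidationError("all concentrations and thresholds must be > 0")
    oavs = [c / t for c, t in zip(cs, ts)]
    oav_mix = sum(cs) / float(mixture_threshold)
    s = sum_oav(oavs)
    x = x_statistic(s, oav_mix)
    return MixtureOAV(
        mixture_id=mixture_id,
        component_oavs=oavs,
        oav_mix=oav_mix,
        sum_oav=s,
        x=x,
        classification=classify_x(x, additive_band),
        additive_band=additive_band,
    )
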