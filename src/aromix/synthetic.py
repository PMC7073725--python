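"""Synthetic data with known ground truth for every pipeline stage.

The study designs emulated here are the ones the analysis modules expect:

* an olfactory panel of 20 assessors, each giving 3 presentations per
  concentration level of a 3-AFC detection series (60 trials/level), with
  responses drawn from the guessing-folded logistic
  p_correct(x) = 1/m + (1 - 1/m) * logistic((x - c)/D);
* binary-mixture detection series whose ground-truth interaction is
  controlled: independent (Feller) detection, or a synergy/suppression
  factor f that multiplies the mixture threshold on the linear scale;
* six-level internal-standard calibration series with multiplicative
  (lognormal) area noise;
* equal-intensity binary mixture ratings under the vector model with
  additive Gaussian rating noise, truncated at zero.

Panellists are exchangeable by default (one binomial draw per level); a
threshold-heterogeneity mode draws an individual threshold
c_i ~ Normal(c, sigma_c) per panellist, for studies of individual fits.

All generators take a seed (or Generator) and are deterministic under it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .psychophysics import (
    DetectionDataset,
    PsychometricFit,
    feller_predicted_curve,
)

__all__ = [
    "PanelSimConfig",
    "MixtureSimConfig",
    "simulate_panel",
    "simulate_mixture_panel",
    "simulate_calibration_points",
    "simulate_intensity_pairs",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class PanelSimConfig:
    """Design of a simulated single-odorant detection experiment.

    Defaults mirror the sensory design the analysis expects: a 20-member
    panel, three presentations per member and level, 3-AFC.
    """

    true_c: float  # log10 µg/L
    true_D: float
    concentration_levels: list[float]  # log10 µg/L
    m: int = 3
    n_panelists: int = 20
    reps: int = 3
    sigma_c: float = 0.0  # per-panellist threshold heterogeneity (log10 units)
    seed: int | None = None
    stimulus_id: str = "sim"

    def __post_init__(self) -> None:
        if self.reps < 1 or self.n_panelists < 1:
            raise ValidationError("need >= 1 panellist and >= 1 rep")
        if self.true_D <= 0:
            raise ValidationError("true_D must be > 0")
        levels = sorted(float(x) for x in self.concentration_levels)
        if not levels or not (levels[0] <= self.true_c <= levels[-1]):
            raise ValidationError("concentration levels must span true_c")
        self.concentration_levels = levels


def _p_correct(x: np.ndarray, c: float, D: float, m: int) -> np.ndarray:
    with np.errstate(over="ignore"):  # near-step curves underflow harmlessly
        P = 1.0 / (1.0 + np.exp(-(x - c) / D))
    return 1.0 / m + (1.0 - 1.0 / m) * P


def simulate_panel(config: PanelSimConfig) -> DetectionDataset:
    """Draw per-level 3-AFC correct counts from the logistic guessing model.

    With ``sigma_c = 0`` panellists are exchangeable and each level is one
    binomial draw of n_panelists*reps trials; with heterogeneity each
    panellist gets an own threshold c_i ~ Normal(true_c, sigma_c) and
    contributes ``reps`` Bernoulli trials per level.
    """
    rng = _rng(config.seed)
    x = np.array(config.concentration_levels)
    n_per_level = config.n_panelists * config.reps
    if config.sigma_c == 0.0:
        p = _p_correct(x, config.true_c, config.true_D, config.m)
        k = rng.binomial(n_per_level, p)
    else:
        c_i = rng.normal(config.true_c, config.sigma_c, size=config.n_panelists)
        k = np.zeros(len(x), dtype=int)
        for ci in c_i:
            p_i = _p_correct(x, ci, config.true_D, config.m)
            k += rng.binomial(config.reps, p_i)
    points = [(float(xi), float(n_per_level), float(ki)) for xi, ki in zip(x, k)]
    return DetectionDataset(config.stimulus_id, points, m=config.m)


def expected_panel(config: PanelSimConfig) -> DetectionDataset:
    """Noiseless companion of :func:`simulate_panel`: expected counts per level."""
    x = np.array(config.concentration_levels)
    n = config.n_panelists * config.reps
    p = _p_correct(x, config.true_c, config.true_D, config.m)
    points = [(float(xi), float(n), float(n * pi)) for xi, pi in zip(x, p)]
    return DetectionDataset(config.stimulus_id, points, m=config.m)


@dataclass
class MixtureSimConfig:
    """Ground truth for a simulated binary-mixture detection experiment.

    ``interaction_mode`` is "independent" (detection follows Feller's
    combination of the two component curves along the total-concentration
    axis) or a factor ``f`` applied to the mixture threshold on the linear
    scale: f < 1 lowers the threshold (synergy), f > 1 raises it
    (suppression).  The true mixture threshold is available from
    :attr:`true_threshold` for recovery checks.
    """

    fit_a: PsychometricFit
    fit_b: PsychometricFit
    w_a: float = 0.5
    w_b: float = 0.5
    interaction_mode: str = "independent"  # "independent" | "factor"
    factor: float = 1.0
    m: int = 3
    seed: int | None = None
    mixture_id: str = "sim-mix"
    _prediction: object = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        if not math.isclose(self.w_a + self.w_b, 1.0, abs_tol=1e-9):
            raise ValidationError("proportions must sum to 1")
        if self.factor <= 0:
            raise ValidationError("interaction factor must be > 0")
        if self.interaction_mode not in ("independent", "factor"):
            raise ValidationError(f"unknown interaction_mode {self.interaction_mode!r}")
        self._prediction = feller_predicted_curve(
            self.fit_a, self.fit_b, (self.w_a, self.w_b), mixture_id=self.mixture_id
        )

    @property
    def feller_prediction(self):
        return self._prediction

    @property
    def true_threshold(self) -> float:
        """True mixture threshold in log10 µg/L (total concentration)."""
        base = self._prediction.threshold
        if self.interaction_mode == "independent":
            return base
        return base + math.log10(self.factor)

    def detection_probability(self, x_total) -> np.ndarray:
        """True detection probability at log10 total concentration."""
        x_arr = np.asarray(x_total, dtype=float)
        if self.interaction_mode == "independent":
            out = self._prediction.detection_probability(x_arr)
        else:
            # shift the whole independent curve so its threshold moves by f
            out = self._prediction.detection_probability(x_arr - math.log10(self.factor))
        return out


def simulate_mixture_panel(
    config: MixtureSimConfig,
    levels: list[float],
    n_panelists: int = 20,
    reps: int = 3,
) -> DetectionDataset:
    """Draw mixture 3-AFC counts whose true threshold is known analytically."""
    rng = _rng(config.seed)
    x = np.sort(np.asarray(levels, dtype=float))
    P = config.detection_probability(x)
    p = 1.0 / config.m + (1.0 - 1.0 / config.m) * P
    n = n_panelists * reps
    k = rng.binomial(n, p)
    points = [(float(xi), float(n), float(ki)) for xi, ki in zip(x, k)]
    return DetectionDataset(config.mixture_id, points, m=config.m)


def simulate_calibration_points(
    true_slope: float,
    true_intercept: float,
    levels,
    noise_cv: float = 0.0,
    seed=None,
) -> list[tuple[float, float]]:
    """Six-gradient-style standard series with multiplicative area noise.

    ``levels`` are concentration ratios; area ratios are the true line times
    a lognormal factor with coefficient of variation ``noise_cv`` (exactly
    on the line when ``noise_cv`` is 0).
    """
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = _rng(seed)
    x = np.asarray(list(levels), dtype=float)
    y_true = true_slope * x + true_intercept
    if noise_cv == 0.0:
        y = y_true
    else:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(x))
        y = y_true * noise
    return [(float(xi), float(yi)) for xi, yi in zip(x, y)]


def simulate_intensity_pairs(
    true_cos_half_alpha: float,
    oi_levels,
    noise_sd: float = 0.0,
    seed=None,
) -> list[tuple[float, float]]:
    """Equal-intensity binary mixture ratings under the vector model.

    ``oi_levels`` are per-component intensities OIa = OIb; the mixture
    rating is cos(alpha/2) * (OIa + OIb) plus Gaussian noise, truncated at
    zero (ratings cannot be negative).  Returns (oi_sum, oi_ab) pairs.
    """
    if not (0.0 < true_cos_half_alpha <= 1.0):
        raise ValidationError("true_cos_half_alpha must be in (0, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = _rng(seed)
    oi = np.asarray(list(oi_levels), dtype=float)
    oi_sum = 2.0 * oi
    oi_ab = true_cos_half_alpha * oi_sum
    if noise_sd > 0:
        oi_ab = np.maximum(oi_ab + rng.normal(0.0, noise_sd, size=len(oi)), 0.0)
    return [(float(s), float(a)) for s, a in zip(oi_sum, oi_ab)]
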