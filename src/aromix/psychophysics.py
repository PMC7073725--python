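"""Detection psychophysics for single odorants and binary mixtures.

An olfactory threshold experiment presents an odorant at several
concentrations in an m-alternative forced-choice (m-AFC) design and records
the proportion of correct identifications per concentration.  Chance
success (1/m) is removed by

    P = (m * p_c - 1) / (m - 1),

and the detection probability is modelled as a logistic function of log10
concentration x,

    P(x) = 1 / (1 + exp(-(x - c) / D)),

with threshold ``c`` (the concentration at which P = 0.5, in log10 µg/L)
and gradient parameter ``D``.  Fitting is by maximum likelihood at the
trial level with the guessing rate folded in,

    p_correct(x) = 1/m + (1 - 1/m) * P(x),

which is equivalent to fitting the logistic to chance-corrected data but
remains well-defined when an observed proportion sits at 0 or 1.

For a binary mixture of statistically independent components, Feller's
additive model predicts

    P(AB) = P(A) + P(B) - P(A) P(B);

comparing a mixture's observed detection curve against this prediction
classifies the perceptual interaction: observed detection significantly
above the prediction is synergy, significantly below is suppression, and
anything else is consistent with independent additivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import optimize

from .errors import NonIdentifiableError, ValidationError

__all__ = [
    "DetectionDataset",
    "PsychometricFit",
    "FellerPrediction",
    "FellerComparison",
    "correct_for_chance",
    "psychometric_probability",
    "fit_psychometric",
    "feller_probability",
    "feller_predicted_curve",
    "classify_feller",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass
class DetectionDataset:
    """Per-concentration m-AFC trial counts for one odorant or mixture.

    ``points`` holds (x, n_trials, n_correct) triples with x in log10 µg/L;
    they are kept sorted by x.  Counts may be fractional (expected counts
    from a noiseless design) — the binomial log-likelihood extends smoothly.
    """

    stimulus_id: str
    points: list[tuple[float, float, float]]
    m: int = 3

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValidationError("m must be >= 2")
        pts = sorted((float(x), float(n), float(k)) for x, n, k in self.points)
        for x, n, k in pts:
            if not (0 <= k <= n) or n <= 0:
                raise ValidationError(
                    f"{self.stimulus_id}: invalid counts (x={x}, n={n}, k={k})"
                )
        self.points = pts

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def n_trials(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def n_correct(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])

    def proportion_correct(self) -> np.ndarray:
        return self.n_correct / self.n_trials


@dataclass
class PsychometricFit:
    """Threshold ``c`` and gradient ``D`` of a fitted logistic detection curve."""

    stimulus_id: str
    c: float  # log10 µg/L; detection probability is 0.5 here by construction
    D: float
    m: int = 3
    converged: bool = True
    residual_deviance: float | None = None
    log_likelihood: float | None = None

    @property
    def threshold_linear(self) -> float:
        """Threshold on the linear concentration scale, µg/L."""
        return 10.0**self.c

    def detection_probability(self, x) -> np.ndarray | float:
        return psychometric_probability(x, self.c, self.D)

    def proportion_correct(self, x) -> np.ndarray | float:
        return 1.0 / self.m + (1.0 - 1.0 / self.m) * self.detection_probability(x)


class ChanceCorrected(NamedTuple):
    P: float
    subchance: bool  # True when sampling noise pushed P below zero


# ---------------------------------------------------------------------------
# elementary operations


def correct_for_chance(p_c, m: int, with_flag: bool = False):
    """Chance-corrected detection probability P = (m*p_c - 1)/(m - 1).

    Sub-chance proportions give a (slightly) negative P; the value is
    returned as computed so averaging stays unbiased.  With
    ``with_flag=True`` a named tuple ``(P, subchance)`` is returned.
    """
    if m < 2:
        raise ValidationError(f"m must be >= 2, got {m}")
    p_arr = np.asarray(p_c, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValidationError("proportion correct must lie in [0, 1]")
    P = (m * p_arr - 1.0) / (m - 1.0)
    out = float(P) if np.isscalar(p_c) else P
    if with_flag:
        return ChanceCorrected(out, bool(np.any(P < 0)))
    return out


def psychometric_probability(x, c: float, D: float):
    """Logistic detection probability 1 / (1 + exp(-(x - c)/D)).

    Strictly increasing in x for D > 0; equals 0.5 at x = c.
    """
    if D <= 0:
        raise ValidationError(f"gradient D must be > 0, got {D}")
    x_arr = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        P = 1.0 / (1.0 + np.exp(-(x_arr - c) / D))
    return float(P) if np.isscalar(x) else P


def feller_probability(pA, pB):
    """Independence prediction P(AB) = P(A) + P(B) - P(A)P(B).

    Identical to 1 - (1-P(A))(1-P(B)): the mixture is missed only when both
    components are missed independently.  Symmetric and bounded below by
    max(pA, pB).
    """
    a = np.asarray(pA, dtype=float)
    b = np.asarray(pB, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValidationError("detection probabilities must lie in [0, 1]")
    out = a + b - a * b
    return float(out) if (np.isscalar(pA) and np.isscalar(pB)) else out


# ---------------------------------------------------------------------------
# maximum-likelihood psychometric fitting


def _nll(params: np.ndarray, x, n, k, m: int) -> float:
    c, log_d = params
    D = math.exp(log_d)
    P = 1.0 / (1.0 + np.exp(-(x - c) / D))
    p = 1.0 / m + (1.0 - 1.0 / m) * P
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _saturated_ll(n, k) -> float:
    p_hat = np.clip(k / n, 1e-12, 1.0 - 1e-12)
    return float(np.sum(k * np.log(p_hat) + (n - k) * np.log1p(-p_hat)))


def fit_psychometric(
    data: DetectionDataset,
    initial: tuple[float, float] | None = None,
) -> PsychometricFit:
    """Maximum-likelihood logistic fit to m-AFC trial counts.

    Requires at least three concentration levels with the apparent
    (chance-corrected) detection proportion crossing 0.5 inside the tested
    range; data that sit entirely at chance or entirely at ceiling do not
    identify the threshold and raise :class:`NonIdentifiableError`.
    """
    x, n, k = data.x, data.n_trials, data.n_correct
    if len(x) < 3:
        raise NonIdentifiableError(
            f"{data.stimulus_id}: need >= 3 concentration levels, got {len(x)}"
        )
    P_hat = correct_for_chance(k / n, data.m)
    if np.all(P_hat > 0.5):
        raise NonIdentifiableError(
            f"{data.stimulus_id}: all levels above P=0.5 (ceiling); "
            "threshold not spanned"
        )
    if np.all(P_hat < 0.5):
        raise NonIdentifiableError(
            f"{data.stimulus_id}: all levels below P=0.5 (chance); "
            "threshold not spanned"
        )
    if initial is None:
        # crude threshold guess: first crossing of 0.5 by linear interpolation
        c0 = float(np.interp(0.5, np.clip(P_hat, 0, 1), x))
        d0 = max(float(np.ptp(x)) / 6.0, 1e-3)
    else:
        c0, d0 = initial
    res = optimize.minimize(
        _nll,
        np.array([c0, math.log(d0)]),
        args=(x, n, k, data.m),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000},
    )
    c_hat, log_d_hat = res.x
    ll = -res.fun
    deviance = 2.0 * (_saturated_ll(n, k) - ll)
    return PsychometricFit(
        stimulus_id=data.stimulus_id,
        c=float(c_hat),
        D=float(math.exp(log_d_hat)),
        m=data.m,
        converged=bool(res.success),
        residual_deviance=float(deviance),
        log_likelihood=float(ll),
    )


# ---------------------------------------------------------------------------
# Feller prediction and interaction classification


@dataclass
class FellerPrediction:
    """Feller-additive detection curve for a binary mixture.

    The mixture is diluted along a *total concentration* axis; at total
    concentration C the components sit at wA*C and wB*C, and the predicted
    detection probability is Feller's combination of the two single-compound
    curves evaluated at those component concentrations.
    """

    mixture_id: str
    fit_a: PsychometricFit
    fit_b: PsychometricFit
    w_a: float
    w_b: float
    threshold: float = field(init=False)  # log10 µg/L total concentration

    def __post_init__(self) -> None:
        if not math.isclose(self.w_a + self.w_b, 1.0, abs_tol=1e-9):
            raise ValidationError("mixing proportions must sum to 1")
        if self.w_a <= 0 or self.w_b <= 0:
            raise ValidationError("mixing proportions must be positive")
        self.threshold = self._solve_threshold()

    def detection_probability(self, x_total) -> np.ndarray | float:
        """Predicted P(AB) at log10 total mixture concentration ``x_total``."""
        x_arr = np.asarray(x_total, dtype=float)
        pa = self.fit_a.detection_probability(x_arr + math.log10(self.w_a))
        pb = self.fit_b.detection_probability(x_arr + math.log10(self.w_b))
        out = pa + pb - pa * pb
        return float(out) if np.isscalar(x_total) else out

    def _solve_threshold(self) -> float:
        # Predicted P(AB) is strictly increasing in total concentration, so
        # the P = 0.5 point is a simple bracketed root on the log axis.
        lo = min(self.fit_a.c - math.log10(self.w_a), self.fit_b.c - math.log10(self.w_b)) - 10
        hi = min(self.fit_a.c - math.log10(self.w_a), self.fit_b.c - math.log10(self.w_b)) + 1
        f = lambda x: self.detection_probability(x) - 0.5
        while f(hi) < 0:  # pragma: no cover - defensive, P(hi) >= 0.5 by construction
            hi += 1
        return float(optimize.brentq(f, lo, hi, xtol=1e-12))

    @property
    def threshold_linear(self) -> float:
        return 10.0**self.threshold

    def as_dataset_shape(self, levels: Sequence[float]) -> list[tuple[float, float]]:
        """(x, predicted P) pairs at the requested log10 total concentrations."""
        return [(float(x), float(self.detection_probability(x))) for x in levels]


def _fisher_scoring_fits(
    x: np.ndarray,
    n: np.ndarray,
    K: np.ndarray,
    m: int,
    c0: float,
    d0: float,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised ML fits of the guessing-folded logistic for B datasets.

    ``K`` is a (B, L) matrix of correct counts sharing the level design
    (x, n).  Fisher scoring on (c, log D) from a common start; returns
    (c, D, ok) where ok flags replicates with finite estimates.  Used by
    the bootstrap, where thousands of refits of near-identical datasets
    make per-replicate simplex optimisation needlessly slow.
    """
    B = K.shape[0]
    g = 1.0 / m
    q = 1.0 - g
    c = np.full(B, c0)
    t = np.full(B, math.log(d0))
    for _ in range(max_iter):
        D = np.exp(t)
        z = (x[None, :] - c[:, None]) / D[:, None]
        with np.errstate(over="ignore"):
            sig = 1.0 / (1.0 + np.exp(-z))
        p = np.clip(g + q * sig, 1e-12, 1.0 - 1e-12)
        sp = sig * (1.0 - sig)
        dpc = -(q / D)[:, None] * sp
        dpt = -q * z * sp
        r = K / p - (n[None, :] - K) / (1.0 - p)
        g1 = np.sum(r * dpc, axis=1)
        g2 = np.sum(r * dpt, axis=1)
        W = n[None, :] / (p * (1.0 - p))
        F11 = np.sum(W * dpc * dpc, axis=1)
        F12 = np.sum(W * dpc * dpt, axis=1)
        F22 = np.sum(W * dpt * dpt, axis=1)
        det = F11 * F22 - F12 * F12
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        dc = (F22 * g1 - F12 * g2) / det
        dt = (F11 * g2 - F12 * g1) / det
        dc = np.clip(dc, -0.5, 0.5)
        dt = np.clip(dt, -0.5, 0.5)
        bad = ~(np.isfinite(dc) & np.isfinite(dt))
        dc[bad] = 0.0
        dt[bad] = 0.0
        c = c + dc
        t = t + dt
        if np.max(np.abs(dc)) < 1e-10 and np.max(np.abs(dt)) < 1e-10:
            break
    ok = np.isfinite(c) & np.isfinite(t)
    return c, np.exp(t), ok


@dataclass
class FellerComparison:
    """Observed-vs-predicted comparison for one binary mixture."""

    mixture_id: str
    predicted_threshold: float  # log10 µg/L
    observed_threshold: float  # log10 µg/L
    threshold_ratio: float  # observed / predicted, linear concentration scale
    p_value: float
    classification: str  # "synergy" | "independent-additive" | "suppression"
    alpha: float
    n_boot: int
    n_boot_failed: int = 0
    unstable: bool = False


def classify_feller(
    observed: PsychometricFit,
    predicted: FellerPrediction,
    observed_data: DetectionDataset,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> FellerComparison:
    """Classify a binary mixture against its Feller-additive prediction.

    The test statistic is the observed detection probability at the
    predicted threshold, which equals 0.5 exactly under independent
    additivity.  Trials are bootstrap-resampled within each concentration
    level, the curve refitted, and the statistic recomputed; the two-sided
    bootstrap p-value (with a +1/(B+1) finite-sample correction) is compared
    to ``alpha``.  Significant excess detection is synergy, significant
    deficit suppression; otherwise the mixture is called
    independent-additive.
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_pred = predicted.threshold
    x, n, k = observed_data.x, observed_data.n_trials, observed_data.n_correct
    p_hat = k / n
    n_int = np.round(n).astype(int)

    K = rng.binomial(n_int[None, :].repeat(n_boot, axis=0), p_hat[None, :])
    c_b, D_b, ok = _fisher_scoring_fits(
        x, n_int.astype(float), K.astype(float), observed_data.m, observed.c, observed.D
    )
    failures = int(np.sum(~ok))
    with np.errstate(over="ignore"):
        stats_arr = 1.0 / (1.0 + np.exp(-(t_pred - c_b[ok]) / D_b[ok]))
    b_eff = len(stats_arr)
    if b_eff == 0:
        raise NonIdentifiableError("all bootstrap refits failed")
    p_synergy = (1 + int(np.sum(stats_arr <= 0.5))) / (b_eff + 1)
    p_suppression = (1 + int(np.sum(stats_arr >= 0.5))) / (b_eff + 1)
    p_two = min(1.0, 2.0 * min(p_synergy, p_suppression))

    ratio = observed.threshold_linear / predicted.threshold_linear
    if p_two < alpha:
        classification = "synergy" if observed.c < t_pred else "suppression"
    else:
        classification = "independent-additive"
    return FellerComparison(
        mixture_id=predicted.mixture_id,
        predicted_threshold=t_pred,
        observed_threshold=observed.c,
        threshold_ratio=ratio,
        p_value=p_two,
        classification=classification,
        alpha=alpha,
        n_boot=n_boot,
        n_boot_failed=failures,
        unstable=failures > 0.1 * n_boot,
    )


def feller_predicted_curve(
    fit_a: PsychometricFit,
    fit_b: PsychometricFit,
    proportions: tuple[float, float],
    mixture_id: str | None = None,
) -> FellerPrediction:
    """Build the Feller-additive prediction for a binary mixture.

    ``proportions`` are the mass fractions (wA, wB) of the two components
    along the shared dilution axis; they must be positive and sum to 1
    (components are mixed at their ratio in the original sample, then
    diluted together).
    """
    w_a, w_b = proportions
    return FellerPrediction(
        mixture_id=mixture_id or f"{fit_a.stimulus_id}+{fit_b.stimulus_id}",
        fit_a=fit_a,
        fit_b=fit_b,
        w_a=float(w_a),
        w_b=float(w_b),
    )
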