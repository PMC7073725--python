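"""Exact binomial analysis of triangle and m-AFC discrimination tests.

In a triangle test a panellist receives three coded samples, two identical
and one different, and must name the odd one; guessing succeeds with
probability 1/3.  Evidence of discrimination is the exact one-sided
upper-tail binomial probability of observing at least the attained number
of correct choices under pure guessing.  Omission tests — does removing one
compound from a full aroma reconstitution produce a perceivable difference?
— are triangle tests and are reported with the conventional star labels.

Panel sizes in this setting are small (tens of presentations), so the exact
tail is used throughout; no normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "TriangleTest",
    "triangle_p_value",
    "significance_stars",
    "p_from_stars",
    "omission_report",
]


@dataclass(frozen=True)
class TriangleTest:
    """Aggregated outcome of one m-AFC discrimination test."""

    test_id: str
    n_trials: int
    n_correct: int
    m: int = 3
    omitted_compound: str | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValidationError(f"{self.test_id}: m must be >= 2")
        if not (0 <= self.n_correct <= self.n_trials):
            raise ValidationError(
                f"{self.test_id}: n_correct {self.n_correct} outside "
                f"[0, {self.n_trials}]"
            )

    @property
    def proportion_correct(self) -> float:
        return self.n_correct / self.n_trials if self.n_trials else float("nan")


def triangle_p_value(test: TriangleTest) -> float:
    """Exact one-sided binomial tail P(X >= n_correct | chance 1/m).

    Equals 1 when ``n_correct`` is 0 (every outcome is at least as extreme).
    """
    # sf(k-1) = P(X >= k) for the discrete binomial
    return float(stats.binom.sf(test.n_correct - 1, test.n_trials, 1.0 / test.m))


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star label.

    ``***`` p < 0.001, ``**`` p < 0.01, ``*`` p < 0.05, ``=`` otherwise.
    """
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "="


#: Representative p-value inside each star band, used when only the star
#: label of a published test is known (the underlying counts unprinted).
_STAR_REPRESENTATIVE = {"***": 5e-4, "**": 5e-3, "*": 0.03, "=": 0.5}


def p_from_stars(stars: str) -> float:
    """A p-value representative of a star label's significance band.

    Published omission tables often print only the star labels; this maps
    them back to a value strictly inside the corresponding band so that
    downstream filters (e.g. p < 0.001) behave as the labels dictate.
    """
    try:
        return _STAR_REPRESENTATIVE[stars.strip()]
    except KeyError:
        raise ValidationError(f"unknown significance label {stars!r}") from None


def omission_report(tests: list[TriangleTest]) -> pd.DataFrame:
    """Tabulate omission triangle tests, one row per omitted compound.

    Returns a DataFrame ordered by ``test_id`` with the omission design
    (which compound was absent), the exact p-value and its star label.
    Duplicate omitted compounds are rejected: each omission test must
    remove exactly one distinct compound.
    """
    if not tests:
        return pd.DataFrame(
            columns=["test_id", "omitted_compound", "n_trials", "n_correct", "p_value", "stars"]
        )
    omitted = [t.omitted_compound for t in tests]
    if any(o is None for o in omitted):
        raise ValidationError("every omission test must name its omitted compound")
    if len(set(omitted)) != len(omitted):
        raise ValidationError("duplicate omitted compound in omission battery")
    rows = []
    for t in sorted(tests, key=lambda t: t.test_id):
        p = triangle_p_value(t)
        rows.append(
            {
                "test_id": t.test_id,
                "omitted_compound": t.omitted_compound,
                "n_trials": t.n_trials,
                "n_correct": t.n_correct,
                "p_value": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)
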