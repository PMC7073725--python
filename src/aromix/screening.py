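"""Odour-activity screening of volatile compounds.

Two sieves are applied in sequence to decide which volatiles plausibly drive
an aroma profile:

* the **flavour dilution (FD) factor** from aroma extract dilution analysis
  (the highest extract dilution at which an odorant is still perceived at
  the sniff port), and
* the **odour activity value (OAV)** — the ratio of a compound's
  concentration to its odour detection threshold in a comparable matrix.

A compound with FD >= fd_min and OAV >= oav_min is a candidate key odorant;
the final key-odorant call additionally requires a significant omission
test (see :mod:`aromix.sensory`).

Compounds with no literature threshold can never pass an OAV filter, and
compounds not detected in a sample pass neither filter.  Display formatting
follows the convention of aroma papers: OAVs are printed as integers
(half-up rounding) and values below one are printed ``<1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = [
    "NOT_DETECTED",
    "CompoundRecord",
    "ScreenResult",
    "oav",
    "format_oav",
    "screen_compounds",
    "select_key_esters",
]

#: Sentinel for "not detected" cells in FD / concentration maps.
NOT_DETECTED = None


class FDRange:
    """An FD factor reported as a range, e.g. 128-256; filters use the lower bound."""

    __slots__ = ("low", "high")

    def __init__(self, low: float, high: float):
        if not (0 < low <= high):
            raise ValidationError(f"invalid FD range {low}-{high}")
        self.low = float(low)
        self.high = float(high)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FDRange({self.low:g}, {self.high:g})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FDRange)
            and (self.low, self.high) == (other.low, other.high)
        )


def _fd_lower(fd) -> float | None:
    if fd is NOT_DETECTED:
        return None
    if isinstance(fd, FDRange):
        return fd.low
    return float(fd)


@dataclass
class CompoundRecord:
    """One volatile compound with its screening inputs across samples.

    ``fd`` and ``concentration`` map sample ids to values; a ``None`` value
    means not detected.  FD factors may be numbers or :class:`FDRange`.
    """

    name: str
    descriptor: str = ""
    ri_wax: int | None = None
    ri_db5: int | None = None
    fd: dict = field(default_factory=dict)
    concentration: dict = field(default_factory=dict)
    threshold: float | None = None  # µg/L
    threshold_source: str = ""

    def __post_init__(self) -> None:
        if self.threshold is not None and self.threshold <= 0:
            raise ValidationError(f"{self.name}: threshold must be > 0")
        for sid, fd in self.fd.items():
            low = _fd_lower(fd)
            if low is not None and low <= 0:
                raise ValidationError(f"{self.name}/{sid}: FD must be positive")

    def fd_in(self, sample_id: str):
        return self.fd.get(sample_id, NOT_DETECTED)

    def concentration_in(self, sample_id: str):
        return self.concentration.get(sample_id, NOT_DETECTED)


@dataclass
class ScreenResult:
    """Per-compound outcome of the FD/OAV screening cascade for one sample."""

    name: str
    sample_id: str
    fd: object = None
    oav_value: float | None = None  # None when threshold or concentration missing
    passes_fd: bool = False
    passes_oav: bool = False

    @property
    def is_candidate_key(self) -> bool:
        return self.passes_fd and self.passes_oav


def oav(concentration: float, threshold: float) -> float:
    """Odour activity value: concentration / odour threshold (same units).

    OAV >= 1 marks a compound whose concentration exceeds its detection
    threshold and therefore a likely contributor to the perceived aroma.
    """
    if threshold is None or threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    if concentration < 0:
        raise ValidationError(f"concentration must be >= 0, got {concentration}")
    return concentration / threshold


def format_oav(value: float | None) -> str:
    """Format an OAV the way aroma tables print it: integer, or ``<1``.

    Rounding is half-up (14.98 -> "15", 1.17 -> "1"); values below one are
    collapsed to ``<1``; a missing OAV prints as an em-dash.
    """
    if value is None:
        return "-"
    if value < 1:
        return "<1"
    return str(int(math.floor(value + 0.5)))


def screen_compounds(
    records: list[CompoundRecord],
    sample_id: str,
    fd_min: float = 16,
    oav_min: float = 1,
) -> list[ScreenResult]:
    """Apply the FD and OAV filters to every record for one sample.

    A record with no threshold gets ``oav_value None`` and can never pass
    the OAV filter; a record not detected in the sample passes neither.
    """
    if not records:
        raise ValidationError("no compound records given")
    known_samples = set()
    for r in records:
        known_samples.update(r.fd)
        known_samples.update(r.concentration)
    if sample_id not in known_samples:
        raise ValidationError(
            f"unknown sample {sample_id!r}; known: {sorted(known_samples)}"
        )
    out = []
    for r in records:
        fd = r.fd_in(sample_id)
        conc = r.concentration_in(sample_id)
        fd_low = _fd_lower(fd)
        oav_value = None
        if conc is not NOT_DETECTED and r.threshold is not None:
            oav_value = oav(conc, r.threshold)
        out.append(
            ScreenResult(
                name=r.name,
                sample_id=sample_id,
                fd=fd,
                oav_value=oav_value,
                passes_fd=fd_low is not None and fd_low >= fd_min,
                passes_oav=oav_value is not None and oav_value >= oav_min,
            )
        )
    return out


def select_key_esters(
    screen: list[ScreenResult],
    omission,
    p_max: float = 0.001,
) -> list[str]:
    """Intersect the FD/OAV candidates with significant omission tests.

    ``omission`` maps compound name -> omission-test p-value (or an object
    with ``omitted_compound`` and ``p_value`` attributes).  A compound is a
    key ester when it passed both screening filters *and* omitting it from
    the full reconstitution changed the aroma at significance p < p_max.
    """
    if hasattr(omission, "items"):
        pvals = dict(omission)
    else:
        pvals = {t.omitted_compound: t.p_value for t in omission}
    candidates = [s for s in screen if s.is_candidate_key]
    missing = [s.name for s in candidates if s.name not in pvals]
    if missing:
        raise ValidationError(f"no omission result for screened compounds: {missing}")
    return [s.name for s in candidates if pvals[s.name] < p_max]
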