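"""Conversion of raw study statistics to Fisher-Z effect sizes.

Every extracted result — a reported correlation, a two-group test statistic,
two group summaries (means ± SD), or a 2×2 choice-frequency table — is mapped
to a correlation coefficient *r* and then to Fisher's Z, ``zr = arctanh(r)``,
whose sampling variance is ``1 / (n - 3)`` with *n* the total number of
animals tested.  Group comparisons go through Hedges' d (the small-sample
corrected standardized mean difference) and the exact unequal-n d→r
conversion; frequency tables use the phi coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RawCorrelation",
    "GroupSummary",
    "GroupTestStat",
    "FreqTable",
    "DegenerateInputError",
    "hedges_d",
    "d_to_r",
    "test_stat_to_r",
    "freq_table_to_r",
    "fisher_z",
    "zr_variance",
    "payload_to_r",
]

#: Correlations reported as exactly ±1 are clamped to this magnitude before
#: the Z transform so the sampling model stays finite.
R_CLAMP = 0.999


class DegenerateInputError(ValueError):
    """Raised when a raw payload cannot yield a defined correlation."""


@dataclass(frozen=True)
class RawCorrelation:
    """A correlation reported directly in the source study."""

    r_reported: float


@dataclass(frozen=True)
class GroupSummary:
    """Means ± SDs of a choosiness measure for two chooser-state groups.

    Group 1 is the "high" state group under the direction-coding scheme
    (young / attractive / large / good condition / mated / few parasites).
    """

    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int

    def __post_init__(self) -> None:
        if self.sd_1 < 0 or self.sd_2 < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.n_1 < 2 or self.n_2 < 2:
            raise ValueError("group sizes must be at least 2")


@dataclass(frozen=True)
class GroupTestStat:
    """A two-group test statistic (t, or F with 1 numerator df)."""

    statistic_kind: str  # "t" or "F_1df"
    value: float
    df: float
    n_1: int
    n_2: int

    def __post_init__(self) -> None:
        if self.statistic_kind not in ("t", "F_1df"):
            raise ValueError(
                f"unsupported statistic kind {self.statistic_kind!r}; "
                "F with >1 numerator df cannot be signed"
            )
        if self.statistic_kind == "F_1df" and self.value < 0:
            raise ValueError("F statistic must be nonnegative")
        if self.df <= 0:
            raise ValueError("df must be positive")


@dataclass(frozen=True)
class FreqTable:
    """2×2 table of choice counts: chooser state (rows) × chosen option (cols)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def hedges_d(g: GroupSummary) -> float:
    """Hedges' d for a two-group comparison.

    d = J * (mean_1 - mean_2) / s_pooled, with the (n-1)-weighted pooled SD
    and the small-sample correction J = 1 - 3 / (4*(n_1 + n_2 - 2) - 1).
    Positive when the high-state group is choosier.
    """
    dof = g.n_1 + g.n_2 - 2
    s_pooled = math.sqrt(
        ((g.n_1 - 1) * g.sd_1**2 + (g.n_2 - 1) * g.sd_2**2) / dof
    )
    if s_pooled == 0:
        raise DegenerateInputError("both group SDs are zero; d undefined")
    j = 1.0 - 3.0 / (4.0 * dof - 1.0)
    return j * (g.mean_1 - g.mean_2) / s_pooled


def d_to_r(d: float, n_1: int, n_2: int) -> float:
    """Convert a standardized mean difference to a point-biserial correlation.

    Uses the exact unequal-n constant a = (n_1 + n_2)^2 / (n_1 * n_2)
    (which reduces to 4 for balanced groups): r = d / sqrt(d^2 + a).
    """
    if n_1 < 2 or n_2 < 2:
        raise ValueError("group sizes must be at least 2")
    a = (n_1 + n_2) ** 2 / (n_1 * n_2)
    return d / math.sqrt(d * d + a)


def test_stat_to_r(s: GroupTestStat) -> float:
    """Convert a two-group t (or 1-df F) statistic to a correlation.

    t is mapped to d via d = t * sqrt(1/n_1 + 1/n_2), then through
    :func:`d_to_r`.  A 1-df F is |t| = sqrt(F); its sign must already be
    encoded by the caller in the reported direction, so the magnitude is
    returned positive.
    """
    if s.statistic_kind == "F_1df":
        t = math.sqrt(s.value)
    else:
        t = s.value
    d = t * math.sqrt(1.0 / s.n_1 + 1.0 / s.n_2)
    return d_to_r(d, s.n_1, s.n_2)


def freq_table_to_r(tbl: FreqTable) -> float:
    """Phi coefficient of a 2×2 frequency table.

    r = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).  All four margins must be
    positive; a single zero cell is allowed (no continuity correction).
    """
    a, b, c, d = tbl.a, tbl.b, tbl.c, tbl.d
    margins = (a + b, c + d, a + c, b + d)
    if min(margins) == 0:
        raise DegenerateInputError(
            f"zero margin in 2x2 table {a, b, c, d}; phi undefined"
        )
    denom = math.sqrt(math.prod(float(m) for m in margins))
    return (a * d - b * c) / denom


def fisher_z(r: float) -> float:
    """Fisher's Z transform, zr = arctanh(r).  Requires |r| < 1."""
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1 for Fisher's Z, got {r}")
    return math.atanh(r)


def zr_variance(n_total: int) -> float:
    """Sampling variance of Fisher's Z: 1 / (n - 3), n the total animals used."""
    if n_total <= 3:
        raise ValueError(f"n_total must be >= 4 for a finite variance, got {n_total}")
    return 1.0 / (n_total - 3)


def payload_to_r(payload) -> float:
    """Dispatch a raw payload to its correlation, clamping reported ±1."""
    if isinstance(payload, RawCorrelation):
        r = payload.r_reported
        if abs(r) > 1.0:
            raise ValueError(f"reported correlation out of range: {r}")
        if abs(r) == 1.0:
            r = math.copysign(R_CLAMP, r)
        return r
    if isinstance(payload, GroupSummary):
        return d_to_r(hedges_d(payload), payload.n_1, payload.n_2)
    if isinstance(payload, GroupTestStat):
        return test_stat_to_r(payload)
    if isinstance(payload, FreqTable):
        return freq_table_to_r(payload)
    raise TypeError(f"unknown payload type: {type(payload).__name__}")
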