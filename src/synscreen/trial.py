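"""Two-arm binary-outcome trial statistics.

Closed-form Wald machinery for a randomized trial with a binary responder
endpoint (e.g. ACR20): per-group proportions with normal-approximation
confidence intervals, the between-group risk difference with its Wald CI,
the Pearson chi-square test on the 2x2 table (with optional Yates
continuity correction), and the classical two-proportion sample-size
formula with drop-out inflation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import DomainError


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Responder counts of a two-arm trial: a/n1 vs b/n2."""

    a: int   # responders, group 1
    n1: int  # group 1 size
    b: int   # responders, group 2
    n2: int  # group 2 size

    def __post_init__(self):
        for v in (self.a, self.n1, self.b, self.n2):
            if not isinstance(v, int):
                raise DomainError("contingency counts must be integers")
        if not (0 <= self.a <= self.n1 and 0 <= self.b <= self.n2):
            raise DomainError("responder counts must satisfy 0 <= x <= n")
        if self.n1 < 1 or self.n2 < 1:
            raise DomainError("group sizes must be >= 1")

    def as_rows(self) -> list[list[int]]:
        """Rows (responders, non-responders) per group."""
        return [[self.a, self.n1 - self.a], [self.b, self.n2 - self.b]]


@dataclass(frozen=True)
class RiskDifferenceResult:
    """Between-group risk difference p1 - p2 with a Wald CI."""

    p1: float
    p2: float
    rd: float
    ci_low: float
    ci_high: float
    conf_level: float


def _z(conf_level: float) -> float:
    if not 0 < conf_level < 1:
        raise DomainError(f"confidence level must be in (0, 1), "
                          f"got {conf_level}")
    return float(stats.norm.ppf(0.5 + conf_level / 2.0))


def wald_proportion_ci(x: int, n: int,
                       conf_level: float = 0.95) -> tuple[float, float, float]:
    """Proportion x/n with the Wald normal-approximation CI, clamped to
    [0, 1]. Returns (p, low, high)."""
    if n < 1:
        raise DomainError("n must be >= 1")
    if not 0 <= x <= n:
        raise DomainError("x must satisfy 0 <= x <= n")
    p = x / n
    half = _z(conf_level) * math.sqrt(p * (1.0 - p) / n)
    return p, max(0.0, p - half), min(1.0, p + half)


def risk_difference_ci(t: ContingencyTable2x2,
                       conf_level: float = 0.95) -> RiskDifferenceResult:
    """Risk difference a/n1 - b/n2 with its Wald confidence interval."""
    p1, p2 = t.a / t.n1, t.b / t.n2
    rd = p1 - p2
    se = math.sqrt(p1 * (1.0 - p1) / t.n1 + p2 * (1.0 - p2) / t.n2)
    half = _z(conf_level) * se
    return RiskDifferenceResult(p1, p2, rd, rd - half, rd + half, conf_level)


def chi_square_2x2(t: ContingencyTable2x2,
                   correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of association on the 2x2 table.

    Without continuity correction (default) the statistic is
    N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on the table
    {a, n1-a; b, n2-b}; the Yates flag subtracts N/2 from |ad - bc|.
    Returns (statistic, p_value) with p from the chi-square(1) tail.
    """
    a, c = t.a, t.n1 - t.a
    b, d = t.b, t.n2 - t.b
    n = a + b + c + d
    margins = [a + c, b + d, a + b, c + d]
    if any(m == 0 for m in margins):
        raise DomainError("chi-square undefined: a table margin is zero")
    det = abs(a * d - b * c)
    if correction:
        det = max(0.0, det - n / 2.0)
    stat = n * det * det / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def sample_size_two_proportions(p1: float, delta: float, alpha: float = 0.05,
                                power: float = 0.80,
                                dropout: float = 0.0) -> int:
    """Per-group sample size to detect a difference of ``delta`` over a
    control rate ``p1`` with a two-sided level-``alpha`` test.

    Uses the standard two-proportion normal approximation

        n = (z_{a/2} sqrt(2 pbar qbar) + z_b sqrt(p1 q1 + p2 q2))^2 / delta^2

    rounded up, then inflated by 1/(1 - dropout) and rounded up again.
    """
    p2 = p1 + delta
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise DomainError("need 0 < p1 < 1 and 0 < p1 + delta < 1")
    if delta == 0:
        raise DomainError("delta must be nonzero")
    if not 0 < power < 1:
        raise DomainError("power must be in (0, 1)")
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    if not 0 <= dropout < 1:
        raise DomainError("dropout must be in [0, 1)")
    z_a = float(stats.norm.ppf(1.0 - alpha / 2.0))
    z_b = float(stats.norm.ppf(power))
    pbar = (p1 + p2) / 2.0
    term_a = z_a * math.sqrt(2.0 * pbar * (1.0 - pbar))
    term_b = z_b * math.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2))
    n = (term_a + term_b) ** 2 / delta ** 2
    n = math.ceil(n)
    if dropout > 0:
        n = math.ceil(n / (1.0 - dropout))
    return int(n)


def trial_report(t: ContingencyTable2x2, conf_level: float = 0.95,
                 correction: bool = False) -> str:
    """Text report: group rates, risk difference with CI, chi-square."""
    p1, lo1, hi1 = wald_proportion_ci(t.a, t.n1, conf_level)
    p2, lo2, hi2 = wald_proportion_ci(t.b, t.n2, conf_level)
    rd = risk_difference_ci(t, conf_level)
    stat, p = chi_square_2x2(t, correction=correction)
    pct = conf_level * 100
    lines = [
        f"group 1: {t.a}/{t.n1} = {p1 * 100:.1f}% "
        f"({lo1 * 100:.1f}%, {hi1 * 100:.1f}%)",
        f"group 2: {t.b}/{t.n2} = {p2 * 100:.1f}% "
        f"({lo2 * 100:.1f}%, {hi2 * 100:.1f}%)",
        f"risk difference: {rd.rd * 100:.1f}% "
        f"({pct:.0f}% CI {rd.ci_low * 100:.1f}%, {rd.ci_high * 100:.1f}%)",
        f"chi-square{' (Yates)' if correction else ''}: "
        f"{stat:.4f}, P = {p:.4f}",
    ]
    return "\n".join(lines)
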