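"""Subsampling and counting-design math.

Zooplankton samples are enumerated by subsampling (1-ml aliquots on a
Sedgewick-Rafter cell for micro/meso, divider trays for macro).  Under the
assumption that organisms land in an aliquot as a Poisson process, the
precision of an abundance estimate depends only on the total number of
organisms counted; these helpers quantify that and the organism-count
bounds implied by a counting protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import DomainError

__all__ = ["CountingDesign", "poisson_precision", "poisson_precision_percent", "count_bounds"]


@dataclass(frozen=True)
class CountingDesign:
    """A dilute-and-count protocol.

    target_concentration_range: organisms per ml after dilution (low, high).
    subsample_count_range: number of 1-ml aliquots processed (min, max).
    target_total: minimum organisms counted before stopping.
    """

    target_concentration_range: tuple[float, float] = (200.0, 400.0)
    subsample_count_range: tuple[int, int] = (5, 20)
    target_total: int = 400

    def __post_init__(self):
        lo, hi = self.target_concentration_range
        mn, mx = self.subsample_count_range
        if not (0 < lo <= hi and 0 < mn <= mx and self.target_total > 0):
            raise DomainError("invalid counting design")


def poisson_precision(n: int, method: str = "normal") -> float:
    """Relative 95% CI half-width of a count of ``n`` organisms.

    ``method="normal"``: the classic plankton-counting result
    1.96*sqrt(n)/n (e.g. counting 400 organisms gives roughly +/-10%).
    ``method="exact"``: half-width of the exact (chi-square) Poisson-mean
    interval for an observed count n, relative to n.
    """
    if int(n) != n or n <= 0:
        raise DomainError("organism count must be a positive integer")
    n = int(n)
    if method == "normal":
        return 1.96 * n ** 0.5 / n
    if method == "exact":
        lower = stats.chi2.ppf(0.025, 2 * n) / 2.0
        upper = stats.chi2.ppf(0.975, 2 * n + 2) / 2.0
        return (upper - lower) / (2.0 * n)
    raise DomainError(f"unknown method: {method!r}")


def poisson_precision_percent(n: int, method: str = "normal") -> int:
    """Convenience form: precision as a rounded whole percentage."""
    return round(100.0 * poisson_precision(n, method=method))


def count_bounds(design: CountingDesign) -> tuple[float, float]:
    """(min, max) organisms counted per sample implied by a design.

    Minimum: lowest target concentration over the fewest aliquots;
    maximum: highest concentration over the most aliquots.
    """
    lo, hi = design.target_concentration_range
    mn, mx = design.subsample_count_range
    return (lo * mn, hi * mx)
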