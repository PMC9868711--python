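"""Descriptive change statistics for panel indicators.

Two conventions are used throughout health-yearbook reporting and are fixed
here once: the overall growth rate between two endpoint values, and the
geometric average annual growth rate over a span of years.
"""

from __future__ import annotations

__all__ = ["overall_growth_rate", "average_annual_growth_rate"]


def overall_growth_rate(start: float, end: float) -> float:
    """Total percentage change ``(end - start) / start × 100``.

    Negative results describe declines; e.g. facilities per 1,000 persons
    rising from 0.29 to 0.74 is an overall growth of ~155.17%.
    """
    if start == 0:
        raise ZeroDivisionError("overall growth rate undefined for a zero start value")
    return (end - start) / start * 100.0


def average_annual_growth_rate(start: float, end: float, years: int) -> float:
    """Geometric mean annual growth, ``((end/start)^(1/years) − 1) × 100``."""
    if start <= 0 or end <= 0:
        raise ValueError("annual growth rate requires positive endpoint values")
    if years <= 0:
        raise ValueError("years must be positive")
    return ((end / start) ** (1.0 / years) - 1.0) * 100.0
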