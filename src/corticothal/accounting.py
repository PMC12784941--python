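"""Cohort and scan accounting arithmetic.

Longitudinal animal-imaging studies report attrition and quality-control
bookkeeping as rounded percentages of explicit counts (animals lost at
surgery, scans discarded by the component-removal rule, failed injections).
These helpers keep that arithmetic in one audited place.
"""

from __future__ import annotations


def percent(part: int | float, whole: int | float, decimals: int = 2) -> float:
    """Percentage ``100 * part / whole`` rounded to ``decimals`` places.

    Raises
    ------
    ValueError
        If ``whole`` is zero or ``part`` is negative.
    """
    if whole == 0:
        raise ValueError("cannot form a percentage with a zero denominator")
    if part < 0 or whole < 0:
        raise ValueError("counts must be non-negative")
    return round(100.0 * part / whole, decimals)


def retention_percent(n_retained: int, n_total: int, decimals: int = 2) -> float:
    """Percentage of units retained out of ``n_total``."""
    if n_retained > n_total:
        raise ValueError(f"retained count {n_retained} exceeds total {n_total}")
    return percent(n_retained, n_total, decimals)


def discard_percent(n_discarded: int, n_total: int, decimals: int = 2) -> float:
    """Percentage of units discarded out of ``n_total``."""
    if n_discarded > n_total:
        raise ValueError(f"discarded count {n_discarded} exceeds total {n_total}")
    return percent(n_discarded, n_total, decimals)
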