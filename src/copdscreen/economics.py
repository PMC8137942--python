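"""Discounting, per-arm totals, and pairwise incremental analysis.

All monetary quantities are full-precision 2018 CNY per screened patient;
effects are (quality-adjusted) life-years per screened patient.  The
incremental cost-effectiveness ratio ICER = dC / dQ is flagged undefined
when |dQ| falls below a tolerance, in which case dominance is classified by
the cost sign alone.  Net monetary benefit NMB = WTP * dQ - dC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import pandas as pd

__all__ = [
    "discount_factor",
    "ArmResult",
    "IncrementalResult",
    "incremental",
    "compare_all",
    "incremental_table",
]

ICER_QALY_TOLERANCE = 1e-9


def discount_factor(cycle: float, annual_rate: float) -> float:
    """Present-value factor for a monthly cycle index: (1+r)^(-cycle/12)."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be non-negative")
    return (1.0 + annual_rate) ** (-cycle / 12.0)


@dataclass
class ArmResult:
    """Discounted per-patient totals for one strategy arm."""

    arm: str
    total_cost: float
    life_years: float
    qalys: float
    cost_components: Dict[str, float] = field(default_factory=dict)
    upfront_cost: float = 0.0
    undiscounted: Dict[str, float] = field(default_factory=dict)
    ledger: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.total_cost < -1e-9:
            raise ValueError("total cost must be non-negative")
        if self.qalys > self.life_years + 1e-9:
            raise ValueError("QALYs cannot exceed life-years")


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise comparison of a strategy ``b`` against comparator ``a``."""

    label: str
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    dominance: str  # dominant | dominated | tradeoff
    nmb: float
    wtp: float


def _classify(delta_cost: float, delta_qaly: float, tol: float) -> str:
    if abs(delta_qaly) < tol:
        if delta_cost < 0:
            return "dominant"
        if delta_cost > 0:
            return "dominated"
        return "tradeoff"
    if delta_cost < 0 and delta_qaly > 0:
        return "dominant"
    if delta_cost > 0 and delta_qaly < 0:
        return "dominated"
    return "tradeoff"


def incremental(
    a: ArmResult, b: ArmResult, wtp: float, tol: float = ICER_QALY_TOLERANCE
) -> IncrementalResult:
    """Incremental analysis of ``b`` versus ``a`` (b minus a)."""
    d_cost = b.total_cost - a.total_cost
    d_qaly = b.qalys - a.qalys
    icer = d_cost / d_qaly if abs(d_qaly) >= tol else None
    return IncrementalResult(
        label=f"{b.arm} vs {a.arm}",
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        icer=icer,
        dominance=_classify(d_cost, d_qaly, tol),
        nmb=wtp * d_qaly - d_cost,
        wtp=wtp,
    )


def compare_all(results: Sequence[ArmResult], wtp: float) -> list[IncrementalResult]:
    """The three pairwise comparisons B vs A, C vs B, C vs A for arms
    ordered (A, B, C)."""
    if len(results) != 3:
        raise ValueError("compare_all expects exactly three arm results")
    a, b, c = results
    return [incremental(a, b, wtp), incremental(b, c, wtp), incremental(a, c, wtp)]


def incremental_table(comparisons: Sequence[IncrementalResult]) -> pd.DataFrame:
    rows = [
        {
            "comparison": r.label,
            "delta_cost": r.delta_cost,
            "delta_qaly": r.delta_qaly,
            "icer": r.icer,
            "dominance": r.dominance,
            "nmb": r.nmb,
            "wtp": r.wtp,
        }
        for r in comparisons
    ]
    return pd.DataFrame(rows)
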