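"""One-way and probabilistic sensitivity analyses, scenario analysis, and
the treatment-duration (horizon) sweep.

The tornado table reports both the ICER and the incremental net monetary
benefit (NMB) at the configured willingness-to-pay for every one-way
variant; NMB is the sort key because it stays well-defined when a strategy
dominates.  The cost-effectiveness acceptability curve (CEAC) marks an arm
cost-effective in a draw when its NMB is maximal among the compared arms; a
pairwise mode against a single comparator is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .economics import ArmResult, compare_all, incremental, incremental_table
from .markov_engine import run_arm
from .parameters import ParameterSet, default_parameters, owsa_variants, sample_parameter_set
from .screening_tree import arms_from_parameters

__all__ = [
    "run_arms",
    "run_owsa",
    "PsaResult",
    "run_psa",
    "default_wtp_grid",
    "run_scenario_no_confirmation",
    "run_duration_sweep",
]

ARM_ORDER = ("no_screening", "questionnaire", "portable_spirometer")
COMPARISONS = (
    ("questionnaire", "no_screening"),
    ("portable_spirometer", "questionnaire"),
    ("portable_spirometer", "no_screening"),
)


def run_arms(
    params: ParameterSet,
    horizon: Optional[int] = None,
    spirometer_confirmation: bool = True,
    collect_ledger: bool = False,
) -> Dict[str, ArmResult]:
    """Run all three strategy arms under one parameter set."""
    arms = arms_from_parameters(params, spirometer_confirmation=spirometer_confirmation)
    return {
        name: run_arm(arms[name], params, horizon=horizon, collect_ledger=collect_ledger)
        for name in ARM_ORDER
    }


def _comparisons(results: Dict[str, ArmResult], wtp: float):
    ordered = [results[name] for name in ARM_ORDER]
    return compare_all(ordered, wtp)


def run_owsa(params: ParameterSet | None = None) -> pd.DataFrame:
    """One-way sensitivity analysis over every tunable parameter.

    One row per (parameter, comparison): the ICER and incremental NMB at
    the low and high bound, the NMB range width, and whether dominance is
    preserved at both bounds.  Rows sort descending by NMB range within
    comparison.
    """
    base = params if params is not None else default_parameters()
    wtp = base.settings.wtp
    rows = []
    for name, low_ps, high_ps in owsa_variants(base):
        for variant_name, ps in (("low", low_ps), ("high", high_ps)):
            results = run_arms(ps)
            for comp in _comparisons(results, wtp):
                rows.append(
                    {
                        "parameter": name,
                        "bound": variant_name,
                        "comparison": comp.label,
                        "icer": comp.icer,
                        "nmb": comp.nmb,
                        "delta_cost": comp.delta_cost,
                        "delta_qaly": comp.delta_qaly,
                        "dominance": comp.dominance,
                    }
                )
    long = pd.DataFrame(rows)
    wide = long.pivot_table(
        index=["parameter", "comparison"],
        columns="bound",
        values=["icer", "nmb"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    dom = (
        long.assign(dominant=long["dominance"] == "dominant")
        .groupby(["parameter", "comparison"])["dominant"]
        .all()
        .rename("dominance_preserved")
    )
    out = wide.join(dom).reset_index()
    out["nmb_range"] = (out["nmb_high"] - out["nmb_low"]).abs()
    out = out.sort_values(
        ["comparison", "nmb_range"], ascending=[True, False]
    ).reset_index(drop=True)
    return out


def default_wtp_grid(n: int = 25) -> np.ndarray:
    """Logarithmic willingness-to-pay grid from 1,000 to 1,000,000 CNY."""
    return np.logspace(3, 6, n)


@dataclass
class PsaResult:
    """Probabilistic sensitivity analysis output."""

    draws: pd.DataFrame  # one row per draw: per-arm cost and QALY
    ceac: pd.DataFrame  # one row per WTP point: P(cost-effective) per arm
    seed: int

    def prob_cost_effective(
        self, arm: str, wtp: float, versus: Optional[str] = "no_screening"
    ) -> float:
        """Fraction of draws in which ``arm`` is cost-effective at ``wtp``.

        With ``versus`` set, cost-effective means higher net monetary
        benefit than that single comparator; with ``versus=None``, maximal
        NMB among all three arms.
        """
        nmb_arm = wtp * self.draws[f"qaly_{arm}"] - self.draws[f"cost_{arm}"]
        if versus is not None:
            nmb_cmp = wtp * self.draws[f"qaly_{versus}"] - self.draws[f"cost_{versus}"]
            return float((nmb_arm > nmb_cmp).mean())
        best = np.column_stack(
            [wtp * self.draws[f"qaly_{a}"] - self.draws[f"cost_{a}"] for a in ARM_ORDER]
        ).max(axis=1)
        return float((nmb_arm >= best).mean())


def run_psa(
    params: ParameterSet | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    wtp_grid: Optional[Sequence[float]] = None,
) -> PsaResult:
    """Monte-Carlo parameter uncertainty analysis.

    Each draw samples a full parameter set, runs all three arms, and
    records per-arm discounted cost and QALYs; the CEAC gives, per WTP
    point, the fraction of draws in which each arm has the maximal net
    monetary benefit.  Reproducible given ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    base = params if params is not None else default_parameters()
    grid = np.asarray(wtp_grid if wtp_grid is not None else default_wtp_grid(), dtype=float)
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_draws)
    rows = []
    for i, s in enumerate(seeds):
        ps = sample_parameter_set(base, seed=int(s))
        results = run_arms(ps)
        row: Dict[str, float] = {"draw": i, "seed": int(s)}
        for name in ARM_ORDER:
            row[f"cost_{name}"] = results[name].total_cost
            row[f"qaly_{name}"] = results[name].qalys
        rows.append(row)
    draws = pd.DataFrame(rows)

    qal = draws[[f"qaly_{a}" for a in ARM_ORDER]].to_numpy()
    cst = draws[[f"cost_{a}" for a in ARM_ORDER]].to_numpy()
    ceac_rows = []
    for wtp in grid:
        nmb = wtp * qal - cst
        winner = nmb.argmax(axis=1)
        row = {"wtp": float(wtp)}
        for j, name in enumerate(ARM_ORDER):
            row[f"p_{name}"] = float((winner == j).mean())
        ceac_rows.append(row)
    return PsaResult(draws=draws, ceac=pd.DataFrame(ceac_rows), seed=seed)


def run_scenario_no_confirmation(params: ParameterSet | None = None) -> pd.DataFrame:
    """Scenario: screen-positive patients in the portable-spirometer arm
    skip the confirmatory diagnostic test (its upfront cost is removed);
    the other arms are unchanged."""
    base = params if params is not None else default_parameters()
    results = run_arms(base, spirometer_confirmation=False)
    return incremental_table(_comparisons(results, base.settings.wtp))


def run_duration_sweep(
    params: ParameterSet | None = None, horizons: Optional[Sequence[int]] = None
) -> pd.DataFrame:
    """ICER of each comparison as the model horizon (treatment duration)
    grows; one row per (horizon, comparison)."""
    base = params if params is not None else default_parameters()
    if horizons is None:
        horizons = (12, 60, 120, 240, 480)
    horizons = list(horizons)
    if sorted(horizons) != horizons:
        raise ValueError("horizons must be ascending")
    rows = []
    for h in horizons:
        results = run_arms(base, horizon=h)
        for comp in _comparisons(results, base.settings.wtp):
            rows.append(
                {
                    "horizon": h,
                    "comparison": comp.label,
                    "delta_cost": comp.delta_cost,
                    "delta_qaly": comp.delta_qaly,
                    "icer": comp.icer,
                    "dominance": comp.dominance,
                    "nmb": comp.nmb,
                }
            )
    return pd.DataFrame(rows)
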