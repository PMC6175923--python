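"""Score plans under scenario uncertainty and summarize habitat networks.

A plan's per-scenario total corrected NPV sums, over managed stands, the
scenario NPV of the chosen regime minus the per-hectare island-area
correction.  The Value-at-Risk is the empirical lower 5% quantile of that
distribution (type-1 / lower-interpolation convention, fixed because the
robust model's certificate bounds a quantile and conventions differ).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np


from .milp.deterministic import DeterministicModelSpec, Plan, verify_solution
from .uncertainty import ScenarioSet


@dataclass
class EvaluationReport:
    expected_npv: float
    var_5: float
    per_period_harvest: np.ndarray
    reserve_area_ha: float
    reserve_share_pct: float
    island_count: int
    regime_share: dict
    n_scenarios: int
    scenario_totals: np.ndarray

    def as_dict(self) -> dict:
        return {
            "expected_npv": self.expected_npv,
            "var_5": self.var_5,
            "per_period_harvest": [float(v) for v in self.per_period_harvest],
            "reserve_area_ha": self.reserve_area_ha,
            "reserve_share_pct": self.reserve_share_pct,
            "island_count": self.island_count,
            "regime_share": self.regime_share,
            "n_scenarios": self.n_scenarios,
        }


def plan_scenario_totals(plan: Plan, scen: ScenarioSet, spec: DeterministicModelSpec) -> np.ndarray:
    """Total corrected NPV per scenario for a fixed plan."""
    s_idx = scen.stand_index()
    r_idx = scen.regime_index()
    totals = np.zeros(scen.n_scenarios)
    for s, j in plan.regime_of.items():
        factor = 1.0 - plan.auxz.get((s, j), 0) / spec.areas[s]
        totals += scen.npv[s_idx[s], r_idx[j], :] * factor
    return totals


def evaluate_plan(
    plan: Plan,
    scen: ScenarioSet,
    spec: DeterministicModelSpec,
    var_level: float = 0.05,
    audit: bool = True,
) -> EvaluationReport:
    """Expected NPV and empirical VaR of a plan over a scenario set."""
    if audit:
        report = verify_solution(plan, spec)
        if not report.ok:
            raise ValueError(f"plan fails feasibility audit: {report.failed()}")
    s_idx = scen.stand_index()
    r_idx = scen.regime_index()
    totals = np.zeros(scen.n_scenarios)
    for s, j in plan.regime_of.items():
        npvs = scen.npv[s_idx[s], r_idx[j], :]
        factor = 1.0 - plan.auxz.get((s, j), 0) / spec.areas[s]
        totals += npvs * factor
    expected = float(totals.mean())
    var5 = float(np.quantile(totals, var_level, method="lower"))
    harvest = plan.period_harvests(spec)
    r_area = plan.reserve_area(spec)
    shares: dict = {}
    for s, j in plan.regime_of.items():
        shares[j] = shares.get(j, 0.0) + spec.areas[s]
    managed_area = sum(shares.values()) or 1.0
    regime_share = {int(j): a / managed_area for j, a in sorted(shares.items())}
    return EvaluationReport(
        expected_npv=expected,
        var_5=var5,
        per_period_harvest=harvest,
        reserve_area_ha=r_area,
        reserve_share_pct=100.0 * r_area / spec.total_area,
        island_count=int(round(plan.sum_pt)),
        regime_share=regime_share,
        n_scenarios=scen.n_scenarios,
        scenario_totals=totals,
    )


@dataclass
class PairedComparison:
    expected_npv: tuple[float, float]  # (deterministic, robust)
    var_5: tuple[float, float]
    d_expected: float  # robust - deterministic
    d_var: float
    ci_expected: tuple[float, float]
    ci_var: tuple[float, float]
    n_bootstrap: int

    def as_dict(self) -> dict:
        return {
            "expected_npv_det": self.expected_npv[0],
            "expected_npv_rob": self.expected_npv[1],
            "var_5_det": self.var_5[0],
            "var_5_rob": self.var_5[1],
            "d_expected": self.d_expected,
            "d_var": self.d_var,
            "ci_expected": list(self.ci_expected),
            "ci_var": list(self.ci_var),
            "n_bootstrap": self.n_bootstrap,
        }


def compare_plans(
    det_plan: Plan,
    rob_plan: Plan,
    scen: ScenarioSet,
    spec: DeterministicModelSpec,
    n_bootstrap: int = 1000,
    seed: int = 0,
    var_level: float = 0.05,
) -> PairedComparison:
    """Paired expected-NPV and VaR comparison with bootstrap CIs.

    Both plans are scored on the same scenarios; bootstrap resamples
    scenario indices jointly so the differences stay paired.
    """
    rep_d = evaluate_plan(det_plan, scen, spec, var_level=var_level)
    rep_r = evaluate_plan(rob_plan, scen, spec, var_level=var_level)
    td, tr = rep_d.scenario_totals, rep_r.scenario_totals
    n = len(td)
    rng = np.random.default_rng(seed)
    d_exp = np.zeros(n_bootstrap)
    d_var = np.zeros(n_bootstrap)
    for bidx in range(n_bootstrap):
        take = rng.integers(0, n, size=n)
        d_exp[bidx] = tr[take].mean() - td[take].mean()
        d_var[bidx] = np.quantile(tr[take], var_level, method="lower") - np.quantile(
            td[take], var_level, method="lower"
        )
    ci = lambda a: (float(np.quantile(a, 0.025)), float(np.quantile(a, 0.975)))
    return PairedComparison(
        expected_npv=(rep_d.expected_npv, rep_r.expected_npv),
        var_5=(rep_d.var_5, rep_r.var_5),
        d_expected=rep_r.expected_npv - rep_d.expected_npv,
        d_var=rep_r.var_5 - rep_d.var_5,
        ci_expected=ci(d_exp),
        ci_var=ci(d_var),
        n_bootstrap=n_bootstrap,
    )


@dataclass
class NetworkSummary:
    reserve_blocks: list  # (stand ids, area)
    island_components: int
    islands_per_reserve: dict
    total_reserve_area: float

    def as_dict(self) -> dict:
        return {
            "reserve_blocks": [
                {"stands": list(map(int, s)), "area_ha": float(a)} for s, a in self.reserve_blocks
            ],
            "island_components": self.island_components,
            "islands_per_reserve": {int(k): int(v) for k, v in self.islands_per_reserve.items()},
            "total_reserve_area": self.total_reserve_area,
        }


def summarize_network(plan: Plan, spec: DeterministicModelSpec) -> NetworkSummary:
    """Reserve blocks and island-graph structure of a feasible plan."""
    blocks = [
        (sorted(c), float(sum(spec.areas[s] for s in c)))
        for c in nx.connected_components(spec.neighbour_graph.subgraph(plan.reserves))
    ]
    g = nx.Graph()
    g.add_nodes_from(plan.points)
    g.add_edges_from(plan.arcs)
    comps = nx.number_connected_components(g) if len(g) else 0
    islands_per_reserve = {s: plan.z.get(s, 0) for s in sorted(plan.reserves)}
    return NetworkSummary(
        reserve_blocks=sorted(blocks, key=lambda t: t[1]),
        island_components=comps,
        islands_per_reserve=islands_per_reserve,
        total_reserve_area=float(sum(a for _, a in blocks)),
    )
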