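"""Deterministic harvest-scheduling + habitat-network MILP.

Maximizes landscape NPV net of deadwood-island area corrections, subject
to: every stand is either managed under exactly one regime or set aside
as a reserve; periodic harvests stay within a band around an optimized
volume bound; final standing volume is at least the initial one; reserves
cover at least a share of the forest and every maximal reserve block
reaches a minimum area (enforced lazily through ring inequalities); each
reserve hosts at least one deadwood island; and the selected island
centre points form a single root-connected network under the dispersal
adjacency, enforced with a single-commodity flow formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ..geometry import CandidateGrid, DispersalGraph, max_points_per_stand, reserve_candidates, stand_neighbour_graph
from ..synth import Landscape, n_periods_of
from .core import MilpBuilder, SolveResult


@dataclass
class DeterministicModelSpec:
    stand_ids: list[int]
    areas: dict[int, float]
    existing_reserves: set[int]
    candidates: set[int]  # reserve-eligible stands, includes existing reserves
    neighbour_graph: nx.Graph
    regime_ids: list[int]
    npv: dict  # (stand_id, regime_id) -> EUR, retention-corrected
    volumes: dict  # (stand_id, regime_id) -> np.ndarray over periods
    iniv: dict  # (stand_id, regime_id) -> m3
    finv: dict
    grid: CandidateGrid
    adjacency: DispersalGraph
    reserve_share: float = 0.10
    flow_band: float = 0.30
    min_reserve_block_area: float = 50.0
    mip_gap: float = 0.03
    volb_floor: float = 0.0

    @property
    def managed_ids(self) -> list[int]:
        return [s for s in self.stand_ids if s not in self.existing_reserves]

    @property
    def total_area(self) -> float:
        return float(sum(self.areas.values()))

    @property
    def n_periods(self) -> int:
        k = next(iter(self.volumes.values()))
        return len(k)

    @property
    def bpt(self) -> int:
        return max_points_per_stand(self.grid)

    def candidate_area(self) -> float:
        return float(sum(self.areas[i] for i in self.candidates))


def build_spec(
    landscape: Landscape,
    outcomes: pd.DataFrame,
    npv_df: pd.DataFrame,
    grid: CandidateGrid,
    adjacency: DispersalGraph,
    trajectory: str = "RCP4.5",
    npv_column: str = "npv_corrected",
    **params,
) -> DeterministicModelSpec:
    """Assemble the model data for one climate trajectory.

    ``npv_df`` may carry a trajectory column (filtered to ``trajectory``)
    or already be trajectory-free (e.g. expected NPVs for the robust
    model, passed with ``trajectory=None``).
    """
    sub_o = outcomes
    sub_n = npv_df
    if trajectory is not None:
        sub_o = outcomes[outcomes["trajectory"] == trajectory]
        if "trajectory" in npv_df.columns:
            sub_n = npv_df[npv_df["trajectory"] == trajectory]
    n_periods = n_periods_of(outcomes)
    vol_cols = [f"vol_p{k + 1}" for k in range(n_periods)]
    npv = {
        (int(r["stand_id"]), int(r["regime_id"])): float(r[npv_column])
        for _, r in sub_n.iterrows()
    }
    volumes, iniv, finv = {}, {}, {}
    for _, r in sub_o.iterrows():
        key = (int(r["stand_id"]), int(r["regime_id"]))
        volumes[key] = r[vol_cols].to_numpy(dtype=float)
        iniv[key] = float(r["ini_stock_volume"])
        finv[key] = float(r["fin_stock_volume"])
    return DeterministicModelSpec(
        stand_ids=[s.id for s in landscape.stands],
        areas={s.id: s.area for s in landscape.stands},
        existing_reserves={s.id for s in landscape.stands if s.existing_reserve},
        candidates=reserve_candidates(landscape),
        neighbour_graph=stand_neighbour_graph(landscape),
        regime_ids=sorted(outcomes["regime_id"].unique()),
        npv=npv,
        volumes=volumes,
        iniv=iniv,
        finv=finv,
        grid=grid,
        adjacency=adjacency,
        **params,
    )


@dataclass
class Plan:
    regime_of: dict  # managed stand -> chosen regime (absent if reserve)
    reserves: set
    z: dict  # stand -> island count
    auxz: dict  # (stand, regime) -> int
    points: set  # selected island centre ids
    arcs: set  # selected arcs (i, j)
    flow: dict
    linsum: dict
    sum_pt: float
    vol_b: float
    objective: float
    status: str
    gap: float | None
    cut_rounds: int = 0
    cuts: list = field(default_factory=list)
    network: bool = True
    detail: str = ""
    t: float | None = None  # robust plans: VaR deviation allowance
    beta: float | None = None

    def x(self, stand: int, regime: int) -> int:
        return 1 if self.regime_of.get(stand) == regime else 0

    def reserve_area(self, spec: DeterministicModelSpec) -> float:
        return float(sum(spec.areas[i] for i in self.reserves))

    def period_harvests(self, spec: DeterministicModelSpec) -> np.ndarray:
        h = np.zeros(spec.n_periods)
        for s, j in self.regime_of.items():
            h += spec.volumes[(s, j)]
        return h


def build_deterministic_model(
    spec: DeterministicModelSpec,
    cuts: list | None = None,
    network: bool = True,
    objective_override: dict | None = None,
) -> MilpBuilder:
    """Build the MILP; ``cuts`` are (block, boundary) ring inequalities.

    ``objective_override`` replaces the per-(stand, regime) NPV used in the
    objective (the robust model builds on this with expected NPVs).
    """
    b = MilpBuilder()
    managed = spec.managed_ids
    regimes = spec.regime_ids
    npv = objective_override if objective_override is not None else spec.npv
    nm, nr = len(managed), len(regimes)
    x = b.add_vars("x", nm * nr, lb=0, ub=1, integer=True)
    xi = {(s, j): x[a * nr + c] for a, s in enumerate(managed) for c, j in enumerate(regimes)}

    b.add_vars("VolB", 1, lb=spec.volb_floor)
    volb = b.names["VolB"][0]

    # objective: managed NPV ...
    for (s, j), v in xi.items():
        b.set_objective(v, npv[(s, j)])

    # Eq 9 partition (y added below when the network is active)
    part_rows = {}
    for s in managed:
        row = b.add_constraint([xi[(s, j)] for j in regimes], np.ones(nr), lb=1.0, ub=1.0)
        part_rows[s] = row

    # wood-flow band and stock conservation
    lo, hi = 1.0 - spec.flow_band, 1.0 + spec.flow_band
    for k in range(spec.n_periods):
        idx = [xi[(s, j)] for s in managed for j in regimes]
        co = [spec.volumes[(s, j)][k] for s in managed for j in regimes]
        b.add_constraint(idx + [volb], co + [-lo], lb=0.0)
        b.add_constraint(idx + [volb], co + [-hi], ub=0.0)
    idx = [xi[(s, j)] for s in managed for j in regimes]
    co = [spec.iniv[(s, j)] - spec.finv[(s, j)] for s in managed for j in regimes]
    b.add_constraint(idx, co, ub=0.0)

    if not network:
        return b

    stand_list = spec.stand_ids
    y = b.add_vars("y", len(stand_list), lb=0, ub=1, integer=True)
    yi = {s: y[a] for a, s in enumerate(stand_list)}
    for s in stand_list:
        if s in spec.existing_reserves:
            b.fix(yi[s], 1.0)
        elif s not in spec.candidates:
            b.fix(yi[s], 0.0)
    # fold y into the partition rows: sum_j x + y = 1
    for s in managed:
        b._rows_i.append(part_rows[s])
        b._rows_j.append(int(yi[s]))
        b._rows_v.append(1.0)

    grid = spec.grid
    by_stand = grid.by_stand()
    n_pt = len(grid.points)
    bpt = spec.bpt
    z = b.add_vars("z", len(stand_list), lb=0, ub=n_pt, integer=True)
    zi = {s: z[a] for a, s in enumerate(stand_list)}
    auxz = b.add_vars("auxz", nm * nr, lb=0, ub=bpt, integer=True)
    azi = {(s, j): auxz[a * nr + c] for a, s in enumerate(managed) for c, j in enumerate(regimes)}
    pt = b.add_vars("pt", n_pt, lb=0, ub=1, integer=True)
    pti = {p.id: pt[a] for a, p in enumerate(grid.points)}
    b.fix(pti[grid.root_id], 1.0)
    arcs = spec.adjacency.arcs
    na = len(arcs)
    kk = b.add_vars("k", na, lb=0, ub=1, integer=True)
    lin = b.add_vars("linSum", na, lb=0, ub=n_pt)
    flw = b.add_vars("flow", na, lb=0, ub=n_pt)
    b.add_vars("sumPT", 1, lb=0, ub=n_pt)
    spt = b.names["sumPT"][0]

    # objective island-area correction
    for (s, j), v in azi.items():
        b.set_objective(v, -npv[(s, j)] / spec.areas[s])

    # Eqs 6-8: auxz_ij = z_i * x_ij
    for (s, j), v in azi.items():
        b.add_constraint([v, xi[(s, j)]], [1.0, -bpt], ub=0.0)
        b.add_constraint([v, zi[s], xi[(s, j)]], [1.0, -1.0, -bpt], lb=-bpt)
        b.add_constraint([v, zi[s]], [1.0, -1.0], ub=0.0)

    # Eq 14 reserve share
    b.add_constraint(
        [yi[s] for s in stand_list],
        [spec.areas[s] for s in stand_list],
        lb=spec.reserve_share * spec.total_area,
    )

    # Eq 15 island count; Eq 16 per-stand linkage; Eq 17 reserves hold islands
    b.add_constraint(list(pt) + [spt], [1.0] * n_pt + [-1.0], lb=0.0, ub=0.0)
    for s in stand_list:
        pts = by_stand.get(s, [])
        b.add_constraint([pti[p] for p in pts] + [zi[s]], [1.0] * len(pts) + [-1.0], lb=0.0, ub=0.0)
        if s in spec.candidates:
            b.add_constraint([zi[s], yi[s]], [1.0, -1.0], lb=0.0)

    # Eqs 18-22: linSum_a = sumPT * k_a; arc endpoints selected
    for a, (i, j) in enumerate(arcs):
        b.add_constraint([lin[a], kk[a]], [1.0, -n_pt], ub=0.0)
        b.add_constraint([lin[a], spt], [1.0, -1.0], ub=0.0)
        b.add_constraint([lin[a], spt, kk[a]], [1.0, -1.0, -n_pt], lb=-n_pt)
        b.add_constraint([pti[i], kk[a]], [1.0, -1.0], lb=0.0)
        b.add_constraint([pti[j], kk[a]], [1.0, -1.0], lb=0.0)

    # Eqs 23-25: single-commodity flow rooted at the root point
    out_of = {}
    into = {}
    for a, (i, j) in enumerate(arcs):
        out_of.setdefault(i, []).append(a)
        into.setdefault(j, []).append(a)
    root = grid.root_id
    b.add_constraint(
        [flw[a] for a in out_of.get(root, [])] + [spt],
        [1.0] * len(out_of.get(root, [])) + [-1.0],
        lb=-1.0,
        ub=-1.0,
    )
    for a in range(na):
        b.add_constraint([flw[a], lin[a]], [1.0, -1.0], ub=0.0)
    for p in grid.points:
        if p.id == root:
            continue
        ins = into.get(p.id, [])
        outs = out_of.get(p.id, [])
        b.add_constraint(
            [flw[a] for a in ins] + [flw[a] for a in outs] + [pti[p.id]],
            [1.0] * len(ins) + [-1.0] * len(outs) + [-1.0],
            lb=0.0,
            ub=0.0,
        )

    # ring-inequality cuts accumulated by the separation loop
    for block, boundary in cuts or []:
        bb = [s for s in boundary if s in spec.candidates]
        b.add_constraint(
            [yi[s] for s in bb] + [yi[s] for s in block],
            [1.0] * len(bb) + [-1.0] * len(block),
            lb=-(len(block) - 1),
        )
    return b


def extract_plan(
    b: MilpBuilder, res: SolveResult, spec: DeterministicModelSpec, network: bool = True
) -> Plan:
    managed = spec.managed_ids
    regimes = spec.regime_ids
    nr = len(regimes)
    xv = b.value(res, "x")
    regime_of = {}
    for a, s in enumerate(managed):
        for c, j in enumerate(regimes):
            if xv[a * nr + c] > 0.5:
                regime_of[s] = j
    vol_b = float(b.value(res, "VolB")[0])
    if not network:
        return Plan(
            regime_of=regime_of,
            reserves=set(),
            z={},
            auxz={},
            points=set(),
            arcs=set(),
            flow={},
            linsum={},
            sum_pt=0.0,
            vol_b=vol_b,
            objective=res.objective,
            status=res.status,
            gap=res.gap,
            network=False,
        )
    yv = b.value(res, "y")
    zv = b.value(res, "z")
    azv = b.value(res, "auxz")
    ptv = b.value(res, "pt")
    kv = b.value(res, "k")
    fv = b.value(res, "flow")
    lv = b.value(res, "linSum")
    reserves = {s for a, s in enumerate(spec.stand_ids) if yv[a] > 0.5}
    z = {s: int(round(zv[a])) for a, s in enumerate(spec.stand_ids)}
    auxz = {
        (s, j): int(round(azv[a * nr + c]))
        for a, s in enumerate(managed)
        for c, j in enumerate(regimes)
    }
    points = {p.id for a, p in enumerate(spec.grid.points) if ptv[a] > 0.5}
    arcs = {arc for a, arc in enumerate(spec.adjacency.arcs) if kv[a] > 0.5}
    flow = {arc: float(fv[a]) for a, arc in enumerate(spec.adjacency.arcs) if fv[a] > 1e-9}
    linsum = {arc: float(lv[a]) for a, arc in enumerate(spec.adjacency.arcs) if lv[a] > 1e-9}
    return Plan(
        regime_of=regime_of,
        reserves=reserves,
        z=z,
        auxz=auxz,
        points=points,
        arcs=arcs,
        flow=flow,
        linsum=linsum,
        sum_pt=float(b.value(res, "sumPT")[0]),
        vol_b=vol_b,
        objective=res.objective,
        status=res.status,
        gap=res.gap,
    )


def separate_ring_inequalities(
    reserves: set, spec: DeterministicModelSpec
) -> list[tuple[tuple, tuple]]:
    """Violated ring inequalities for the given reserve selection.

    Enumerates maximal connected reserve blocks in the stand neighbour
    graph; each block whose area falls short of the minimum yields one
    (block, boundary) cut.
    """
    g = spec.neighbour_graph
    sub = g.subgraph(reserves)
    cuts = []
    for comp in nx.connected_components(sub):
        area = sum(spec.areas[s] for s in comp)
        if area < spec.min_reserve_block_area - 1e-9:
            boundary = {
                n for s in comp for n in g.neighbors(s) if n not in comp
            }
            cuts.append((tuple(sorted(comp)), tuple(sorted(boundary))))
    return cuts


def solve_deterministic(
    spec: DeterministicModelSpec,
    time_limit: float | None = None,
    seed: int = 0,
    network: bool = True,
    max_cut_rounds: int = 30,
    objective_override: dict | None = None,
    total_time_limit: float | None = None,
) -> Plan:
    """Solve with lazy ring-inequality separation until no block is undersized.

    ``time_limit`` caps each solver call; ``total_time_limit`` caps the
    whole separation loop (the last incumbent is returned with status
    ``time_limit`` when it runs out).  ``seed`` is part of the determinism
    contract of the pipeline; the underlying branch-and-cut is itself
    deterministic for a fixed model.
    """
    import time as _time

    deadline = None if total_time_limit is None else _time.monotonic() + total_time_limit
    if network and spec.candidate_area() < spec.reserve_share * spec.total_area - 1e-9:
        return Plan(
            regime_of={},
            reserves=set(),
            z={},
            auxz={},
            points=set(),
            arcs=set(),
            flow={},
            linsum={},
            sum_pt=0.0,
            vol_b=0.0,
            objective=float("nan"),
            status="infeasible",
            gap=None,
            detail="reserve candidates cover less than the required share of the forest area",
        )
    cuts: list = []
    plan = None
    for round_no in range(max_cut_rounds):
        round_limit = time_limit
        if deadline is not None:
            remaining = deadline - _time.monotonic()
            if remaining <= 1.0 and plan is not None:
                plan.status = "time_limit"
                return plan
            round_limit = remaining if round_limit is None else min(round_limit, remaining)
            round_limit = max(round_limit, 1.0)
        b = build_deterministic_model(
            spec, cuts=cuts, network=network, objective_override=objective_override
        )
        res = b.solve(mip_rel_gap=spec.mip_gap, time_limit=round_limit)
        if res.x is None:
            return Plan(
                regime_of={},
                reserves=set(),
                z={},
                auxz={},
                points=set(),
                arcs=set(),
                flow={},
                linsum={},
                sum_pt=0.0,
                vol_b=0.0,
                objective=float("nan"),
                status=res.status,
                gap=None,
                cut_rounds=round_no,
                cuts=cuts,
            )
        plan = extract_plan(b, res, spec, network=network)
        plan.cut_rounds = round_no + 1
        plan.cuts = list(cuts)
        if not network:
            return plan
        new_cuts = separate_ring_inequalities(plan.reserves, spec)
        fresh = [c for c in new_cuts if c not in cuts]
        if not fresh:
            return plan
        cuts.extend(fresh)
    plan.status = "cut_limit"
    return plan


# ---------------------------------------------------------------------------
# audit


@dataclass
class AuditReport:
    checks: dict  # name -> (ok, message)

    @property
    def ok(self) -> bool:
        return all(v[0] for v in self.checks.values())

    def failed(self) -> list[str]:
        return [k for k, v in self.checks.items() if not v[0]]


def verify_solution(plan: Plan, spec: DeterministicModelSpec, tol: float = 1e-5) -> AuditReport:
    """Re-check every constraint family arithmetically, outside the solver."""
    checks = {}

    managed = set(spec.managed_ids)
    assigned = set(plan.regime_of)
    both = assigned & plan.reserves
    uncovered = managed - assigned - plan.reserves
    reserves_ok = (spec.existing_reserves <= plan.reserves) if plan.network else True
    checks["partition"] = (
        not both and not uncovered and reserves_ok,
        f"double-assigned={sorted(both)} uncovered={sorted(uncovered)}",
    )

    h = plan.period_harvests(spec)
    lo, hi = (1 - spec.flow_band) * plan.vol_b, (1 + spec.flow_band) * plan.vol_b
    band_tol = tol * max(1.0, plan.vol_b)
    checks["flow_band"] = (
        bool(np.all(h >= lo - band_tol) and np.all(h <= hi + band_tol)),
        f"harvests={h.round(1).tolist()} VolB={plan.vol_b:.1f}",
    )

    ini = sum(spec.iniv[(s, j)] for s, j in plan.regime_of.items())
    fin = sum(spec.finv[(s, j)] for s, j in plan.regime_of.items())
    checks["stock"] = (ini <= fin + tol * max(1.0, abs(fin)), f"ini={ini:.1f} fin={fin:.1f}")

    if not plan.network:
        return AuditReport(checks=checks)

    r_area = plan.reserve_area(spec)
    checks["reserve_share"] = (
        r_area >= spec.reserve_share * spec.total_area - tol * spec.total_area,
        f"reserve_area={r_area:.2f} of {spec.total_area:.2f}",
    )

    blocks = [
        (sorted(c), sum(spec.areas[s] for s in c))
        for c in nx.connected_components(spec.neighbour_graph.subgraph(plan.reserves))
    ]
    checks["min_block_area"] = (
        all(a >= spec.min_reserve_block_area - 1e-6 for _, a in blocks),
        f"block_areas={[round(a, 2) for _, a in blocks]}",
    )

    checks["islands_in_reserves"] = (
        all(plan.z.get(s, 0) >= 1 for s in plan.reserves),
        "every reserve stand holds at least one island",
    )

    by_stand = spec.grid.by_stand()
    z_audit = all(
        plan.z.get(s, 0) == sum(1 for p in by_stand.get(s, []) if p in plan.points)
        for s in spec.stand_ids
    )
    checks["island_count_linkage"] = (z_audit, "z_i equals selected points in stand i")

    az_ok = all(
        plan.auxz.get((s, j), 0) == plan.z.get(s, 0) * plan.x(s, j)
        for s in spec.managed_ids
        for j in spec.regime_ids
    )
    checks["auxz_linearization"] = (az_ok, "auxz_ij == z_i * x_ij")

    ls_ok = all(
        abs(plan.linsum.get(arc, 0.0) - plan.sum_pt * (1 if arc in plan.arcs else 0)) <= tol * max(1.0, plan.sum_pt)
        for arc in spec.adjacency.arcs
    )
    checks["linsum_linearization"] = (ls_ok, "linSum_ij == sumPT * k_ij")

    endpoints_ok = all(i in plan.points and j in plan.points for i, j in plan.arcs)
    g = nx.Graph()
    g.add_nodes_from(plan.points)
    g.add_edges_from((i, j) for i, j in plan.arcs)
    root = spec.grid.root_id
    connected = (
        root in plan.points
        and endpoints_ok
        and (len(plan.points) == 0 or nx.is_connected(g))
    )
    checks["island_connectivity"] = (
        bool(connected),
        f"points={len(plan.points)} components={nx.number_connected_components(g) if len(g) else 0}",
    )

    checks["sum_pt"] = (
        abs(plan.sum_pt - len(plan.points)) <= tol * max(1.0, plan.sum_pt),
        f"sumPT={plan.sum_pt} selected={len(plan.points)}",
    )

    out_root = sum(f for (i, _), f in plan.flow.items() if i == root)
    checks["root_injection"] = (
        abs(out_root - (plan.sum_pt - 1.0)) <= tol * max(1.0, plan.sum_pt),
        f"out_of_root={out_root:.3f} sumPT-1={plan.sum_pt - 1:.3f}",
    )
    bal_ok = True
    for p in plan.points:
        if p == root:
            continue
        inflow = sum(f for (i, j), f in plan.flow.items() if j == p)
        outflow = sum(f for (i, j), f in plan.flow.items() if i == p)
        if abs(inflow - outflow - 1.0) > tol * max(1.0, plan.sum_pt):
            bal_ok = False
            break
    cap_ok = all(
        f <= plan.linsum.get(arc, 0.0) + tol * max(1.0, plan.sum_pt)
        for arc, f in plan.flow.items()
    )
    checks["flow_balance"] = (bal_ok and cap_ok, "unit consumption at each selected point")

    return AuditReport(checks=checks)
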