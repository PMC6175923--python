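"""Deterministic MILP: oracle equivalence on toys, cuts, audits, monotonicity."""

import itertools

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import box

from deadwoodnet import geometry, synth
from deadwoodnet.milp import (
    DeterministicModelSpec,
    separate_ring_inequalities,
    solve_deterministic,
    verify_solution,
)

# ---------------------------------------------------------------------------
# toy instance: five 1-ha strip stands, one candidate point per stand


def strip_landscape(n=5, reserve=(0,), candidates=(0, 1, 2), side=100.0):
    stands = []
    for i in range(n):
        poly = box(i * side, 0.0, (i + 1) * side, side)
        stands.append(
            synth.Stand(
                id=i,
                area=poly.area / 1e4,
                centroid=(poly.centroid.x, poly.centroid.y),
                polygon=poly,
                dominant_species="beech" if i in candidates else "spruce",
                age=200.0 if i in candidates else 80.0,
                existing_reserve=i in reserve,
                topex_class=1,
            )
        )
    return synth.Landscape(stands=stands, bounds=(0.0, 0.0, n * side, side))


def toy_spec(
    npv,
    volumes,
    n=5,
    reserve=(0,),
    candidates=(0, 1, 2),
    reserve_share=0.2,
    min_block_area=2.0,
    flow_band=0.3,
    iniv=None,
    finv=None,
    mip_gap=1e-9,
):
    """Hand-built model spec over the strip landscape.

    ``npv``/``volumes`` map (stand, regime) over managed stands; volumes
    are per-period arrays.
    """
    ls = strip_landscape(n=n, reserve=reserve, candidates=candidates)
    grid = geometry.build_candidate_grid(ls, spacing=100.0)
    adjacency = geometry.build_adjacency(grid, dispersal_m=50.0)
    regimes = sorted({j for _, j in npv})
    managed = [s.id for s in ls.stands if not s.existing_reserve]
    if iniv is None:
        iniv = {k: 100.0 for k in npv}
    if finv is None:
        finv = {k: 120.0 for k in npv}
    return DeterministicModelSpec(
        stand_ids=[s.id for s in ls.stands],
        areas={s.id: s.area for s in ls.stands},
        existing_reserves=set(reserve),
        candidates=set(candidates) | set(reserve),
        neighbour_graph=geometry.stand_neighbour_graph(ls),
        regime_ids=regimes,
        npv=npv,
        volumes={k: np.asarray(v, float) for k, v in volumes.items()},
        iniv=iniv,
        finv=finv,
        grid=grid,
        adjacency=adjacency,
        reserve_share=reserve_share,
        flow_band=flow_band,
        min_reserve_block_area=min_block_area,
        mip_gap=mip_gap,
    )


def brute_force_optimum(spec):
    """Exhaustive enumeration over assignments and connected island subsets.

    Independent of the MILP: iterates stand->(reserve|regime) maps and all
    root-containing connected point subsets, checks every constraint
    arithmetically, and maximizes the corrected objective.
    """
    managed = spec.managed_ids
    regimes = spec.regime_ids
    lo, hi = 1.0 - spec.flow_band, 1.0 + spec.flow_band
    pts = [p.id for p in spec.grid.points]
    stand_of_pt = {p.id: p.stand_id for p in spec.grid.points}
    root = spec.grid.root_id
    und = nx.Graph()
    und.add_nodes_from(pts)
    und.add_edges_from(spec.adjacency.undirected_edges())

    options = []
    for s in managed:
        opts = [("r", None)] if s in spec.candidates else []
        opts += [("m", j) for j in regimes]
        options.append(opts)

    best = None
    for combo in itertools.product(*options):
        reserves = set(spec.existing_reserves)
        assign = {}
        for s, (kind, j) in zip(managed, combo):
            if kind == "r":
                reserves.add(s)
            else:
                assign[s] = j
        # reserve share and block minimums
        if sum(spec.areas[s] for s in reserves) < spec.reserve_share * spec.total_area - 1e-12:
            continue
        blocks = nx.connected_components(spec.neighbour_graph.subgraph(reserves))
        if any(sum(spec.areas[s] for s in c) < spec.min_reserve_block_area - 1e-12 for c in blocks):
            continue
        # wood flow: a feasible VolB interval must exist
        h = np.zeros(spec.n_periods)
        for s, j in assign.items():
            h += spec.volumes[(s, j)]
        lb = h.max() / hi
        ub = h.min() / lo if lo > 0 else np.inf
        if lb > ub + 1e-12:
            continue
        if sum(spec.iniv[(s, j)] for s, j in assign.items()) > sum(
            spec.finv[(s, j)] for s, j in assign.items()
        ) + 1e-12:
            continue
        # island subsets: connected, contain root, z_i >= 1 on reserves
        for r in range(len(pts)):
            for subset in itertools.combinations(pts, r + 1):
                sel = set(subset)
                if root not in sel:
                    continue
                sub = und.subgraph(sel)
                if not nx.is_connected(sub):
                    continue
                z = {s: 0 for s in spec.stand_ids}
                for p in sel:
                    z[stand_of_pt[p]] += 1
                if any(z[s] < 1 for s in reserves):
                    continue
                obj = sum(spec.npv[(s, j)] for s, j in assign.items())
                obj -= sum(
                    spec.npv[(s, assign[s])] / spec.areas[s] * z[s] for s in assign
                )
                if best is None or obj > best[0]:
                    best = (obj, dict(assign), set(reserves), dict(z))
    return best


def default_toy(npv_sign=1.0):
    regimes = [1, 2]
    npv = {}
    volumes = {}
    for s in range(1, 5):
        for j in regimes:
            npv[(s, j)] = npv_sign * (1000.0 + 300.0 * s - 200.0 * j)
            volumes[(s, j)] = np.array([50.0 + 10 * j, 60.0, 55.0 - 5 * j])
    # stand 4 loses money under every regime
    for j in regimes:
        npv[(4, j)] = -500.0 * j
    return npv, volumes


class TestOracleEquivalence:
    @pytest.mark.parametrize("variant", ["base", "negative_stand", "band_tight"])
    def test_solver_matches_enumeration(self, variant):
        npv, volumes = default_toy()
        kwargs = {}
        if variant == "negative_stand":
            for j in (1, 2):
                npv[(2, j)] = -800.0 - 100 * j
        if variant == "band_tight":
            kwargs["flow_band"] = 0.1
        spec = toy_spec(npv, volumes, **kwargs)
        plan = solve_deterministic(spec)
        oracle = brute_force_optimum(spec)
        assert plan.status == "optimal"
        assert oracle is not None
        assert plan.objective == pytest.approx(oracle[0], rel=1e-6, abs=1e-6)
        assert verify_solution(plan, spec).ok

    def test_two_stand_forced_reserve(self):
        """With one candidate holding >10% of area and no alternative, it is set aside."""
        npv = {(1, 1): 1000.0}
        volumes = {(1, 1): np.array([50.0, 50.0, 50.0])}
        spec = toy_spec(
            npv,
            volumes,
            n=2,
            reserve=(0,),
            candidates=(0, 1),
            reserve_share=0.9,
            min_block_area=1.0,
        )
        plan = solve_deterministic(spec)
        oracle = brute_force_optimum(spec)
        assert plan.status == "optimal"
        assert plan.reserves == {0, 1} == oracle[2]

    def test_all_negative_candidate_becomes_reserve_or_island(self):
        npv, volumes = default_toy()
        for j in (1, 2):
            npv[(2, j)] = -1000.0 - 100 * j  # stand 2 is a candidate
        spec = toy_spec(npv, volumes)
        plan = solve_deterministic(spec)
        assert plan.status == "optimal"
        covered = 2 in plan.reserves or plan.z.get(2, 0) >= 1
        # managing a pure-loss candidate without offset never beats the oracle
        assert plan.objective == pytest.approx(brute_force_optimum(spec)[0], rel=1e-6)
        assert covered or plan.regime_of.get(2) is None


class TestSolveContracts:
    def test_infeasible_reserve_share_reported(self):
        npv, volumes = default_toy()
        spec = toy_spec(npv, volumes, reserve_share=1.0)
        plan = solve_deterministic(spec)
        assert plan.status == "infeasible"

    def test_resolve_same_seed_same_objective(self):
        npv, volumes = default_toy()
        spec = toy_spec(npv, volumes)
        a = solve_deterministic(spec, seed=3)
        b = solve_deterministic(spec, seed=3)
        assert a.objective == pytest.approx(b.objective, rel=1e-9)

    def test_zero_flow_band_forces_equal_harvests(self):
        npv = {(s, 1): 100.0 * s for s in range(1, 5)}
        volumes = {(s, 1): np.array([30.0, 30.0, 30.0]) for s in range(1, 5)}
        spec = toy_spec(npv, volumes, flow_band=0.0)
        plan = solve_deterministic(spec)
        assert plan.status == "optimal"
        h = plan.period_harvests(spec)
        assert np.allclose(h, plan.vol_b)


class TestRingSeparation:
    def _spec_with_graph(self, areas, edges, candidates, min_block=50.0):
        g = nx.Graph()
        g.add_nodes_from(areas)
        g.add_edges_from(edges)
        npv = {(s, 1): 1.0 for s in areas}
        ls = strip_landscape(n=2)
        grid = geometry.build_candidate_grid(ls, spacing=100.0)
        return DeterministicModelSpec(
            stand_ids=list(areas),
            areas=dict(areas),
            existing_reserves=set(),
            candidates=set(candidates),
            neighbour_graph=g,
            regime_ids=[1],
            npv=npv,
            volumes={(s, 1): np.array([1.0]) for s in areas},
            iniv={(s, 1): 0.0 for s in areas},
            finv={(s, 1): 0.0 for s in areas},
            grid=grid,
            adjacency=geometry.build_adjacency(grid, dispersal_m=50.0),
            min_reserve_block_area=min_block,
        )

    def test_undersized_block_emits_one_cut(self):
        spec = self._spec_with_graph({0: 30.0, 1: 40.0, 2: 40.0}, [(0, 1), (1, 2)], {0, 1, 2})
        cuts = separate_ring_inequalities({0}, spec)
        assert len(cuts) == 1
        block, boundary = cuts[0]
        assert block == (0,)
        assert boundary == (1,)

    def test_large_block_no_cut(self):
        spec = self._spec_with_graph({0: 60.0, 1: 40.0}, [(0, 1)], {0, 1})
        assert separate_ring_inequalities({0}, spec) == []

    def test_two_disjoint_blocks_two_cuts(self):
        spec = self._spec_with_graph(
            {0: 30.0, 1: 10.0, 2: 30.0}, [(0, 1), (1, 2)], {0, 1, 2}
        )
        cuts = separate_ring_inequalities({0, 2}, spec)
        assert len(cuts) == 2


class TestMonotonicity:
    def test_more_dispersal_never_hurts(self):
        npv, volumes = default_toy()
        objs = []
        for disp in (50.0, 300.0):
            spec = toy_spec(npv, volumes)
            spec.adjacency = geometry.build_adjacency(spec.grid, dispersal_m=disp)
            plan = solve_deterministic(spec)
            assert plan.status == "optimal"
            objs.append(plan.objective)
        assert objs[1] >= objs[0] - 1e-6

    def test_baseline_without_network_dominates(self):
        npv, volumes = default_toy()
        spec = toy_spec(npv, volumes)
        with_net = solve_deterministic(spec)
        baseline = solve_deterministic(spec, network=False)
        assert baseline.status == "optimal"
        assert baseline.objective >= with_net.objective - 1e-6


class TestAudit:
    def test_feasible_plan_passes_all_checks(self):
        npv, volumes = default_toy()
        spec = toy_spec(npv, volumes)
        plan = solve_deterministic(spec)
        report = verify_solution(plan, spec)
        assert report.ok, report.failed()

    def test_disconnected_point_fails_connectivity(self):
        npv, volumes = default_toy()
        spec = toy_spec(npv, volumes)
        plan = solve_deterministic(spec)
        far = [p.id for p in spec.grid.points if p.id not in plan.points]
        plan.points.add(far[-1])  # inject an unconnected selected point
        report = verify_solution(plan, spec)
        assert not report.ok
        assert "island_connectivity" in report.failed() or "island_count_linkage" in report.failed()

    def test_broken_auxz_fails_linearization(self):
        npv, volumes = default_toy()
        spec = toy_spec(npv, volumes)
        plan = solve_deterministic(spec)
        s, j = next(iter(plan.regime_of.items()))
        plan.auxz[(s, j)] = plan.auxz.get((s, j), 0) + 1
        plan.z[s] = plan.z.get(s, 0)  # leave z inconsistent on purpose
        report = verify_solution(plan, spec)
        assert "auxz_linearization" in report.failed()


def test_default_instance_deterministic_solution(default_instance):
    """The default seeded instance solves at 3% gap with a fully clean audit."""
    spec = default_instance.spec
    plan = solve_deterministic(spec, time_limit=240)
    assert plan.status == "optimal"
    assert plan.gap is None or plan.gap <= 0.03 + 1e-9
    report = verify_solution(plan, spec)
    assert report.ok, report.failed()
    # network structure: one rooted island component, reserves hold islands
    assert plan.sum_pt == len(plan.points) >= 1
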