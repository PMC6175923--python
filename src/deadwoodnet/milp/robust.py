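"""Robust counterpart: maximize expected NPV minus a VaR allowance ``t``.

The chance that total NPV falls more than ``t`` below its expectation is
bounded with a Bernstein-type safe approximation: with ``L`` the
(per-regime) Cholesky factor of the stand-NPV covariance, the bound

    -t + beta * sum ln cosh(a_i / beta)
       - beta * sum ln cosh(b_i / beta) + beta * ln(1/eps) <= 0

with ``a = L^T x`` (harvest terms) and ``b = L^T auxz/area`` (island-area
corrections) certifies the epsilon-quantile protection.  ``ln cosh`` is
handled piecewise-linearly: the added sum through the epigraph of its
chord interpolant (an over-approximation, plain linear rows), the
subtracted sum through a segment-selection formulation whose node values
are shifted down by the chord error (an under-approximation), so the
linearized constraint is conservative in both directions and the safe
guarantee survives the approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .core import MilpBuilder
from .deterministic import (
    DeterministicModelSpec,
    Plan,
    build_deterministic_model,
    extract_plan,
    separate_ring_inequalities,
)


def lncosh(x):
    """Numerically stable ln cosh."""
    ax = np.abs(np.asarray(x, dtype=float))
    return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)


@dataclass(frozen=True)
class LnCoshPWL:
    """Two-sided piecewise-linear handles on ln cosh over [-X, X].

    ``upper_pieces`` (slope, intercept) are the chords between breakpoints
    plus slope-+/-1 asymptotic pieces through (+/-X, ln cosh X); their max
    over-approximates ln cosh everywhere.  ``tangent_pieces`` are tangents
    at the breakpoints; their max under-approximates it everywhere.
    ``node_values_safe`` shift each breakpoint value down by the local
    chord error so the interpolant of the shifted nodes stays below
    ln cosh.
    """

    breakpoints: np.ndarray
    upper_pieces: np.ndarray  # (m, 2) slope, intercept
    tangent_pieces: np.ndarray
    node_values_safe: np.ndarray
    max_error: float

    def upper(self, x):
        x = np.asarray(x, dtype=float)
        return np.max(
            self.upper_pieces[:, 0][:, None] * x[None, :] + self.upper_pieces[:, 1][:, None],
            axis=0,
        ) if x.ndim else float(np.max(self.upper_pieces[:, 0] * x + self.upper_pieces[:, 1]))

    def lower(self, x):
        x = np.asarray(x, dtype=float)
        vals = self.tangent_pieces[:, 0][:, None] * np.atleast_1d(x)[None, :] + self.tangent_pieces[:, 1][:, None]
        out = np.max(vals, axis=0)
        return out if np.ndim(x) else float(out[0])


def _chord_error(u: float, v: float) -> float:
    """Max of chord(x) - ln cosh(x) on [u, v]; attained where slope matches."""
    fu, fv = float(lncosh(u)), float(lncosh(v))
    slope = (fv - fu) / (v - u)
    slope = np.clip(slope, -1 + 1e-12, 1 - 1e-12)
    xstar = float(np.arctanh(slope))
    xstar = min(max(xstar, u), v)
    chord = fu + slope * (xstar - u)
    return max(0.0, chord - float(lncosh(xstar)))


def lncosh_pwl(halfwidth: float = 10.0, n_segments: int = 24) -> LnCoshPWL:
    """Symmetric PWL of ln cosh with ``n_segments`` chords on [-X, X]."""
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    n_segments += n_segments % 2  # keep 0 as a breakpoint
    bp = np.linspace(-halfwidth, halfwidth, n_segments + 1)
    f = lncosh(bp)
    upper = []
    for m in range(n_segments):
        slope = (f[m + 1] - f[m]) / (bp[m + 1] - bp[m])
        upper.append((slope, f[m] - slope * bp[m]))
    fx = float(lncosh(halfwidth))
    upper.append((1.0, fx - halfwidth))  # asymptotic pieces keep the
    upper.append((-1.0, fx - halfwidth))  # over-approximation valid beyond X
    tangents = np.column_stack([np.tanh(bp), f - bp * np.tanh(bp)])
    gaps = np.zeros(n_segments + 1)
    seg_err = np.array([_chord_error(bp[m], bp[m + 1]) for m in range(n_segments)])
    for m in range(n_segments + 1):
        adj = []
        if m > 0:
            adj.append(seg_err[m - 1])
        if m < n_segments:
            adj.append(seg_err[m])
        gaps[m] = max(adj)
    return LnCoshPWL(
        breakpoints=bp,
        upper_pieces=np.array(upper),
        tangent_pieces=tangents,
        node_values_safe=f - gaps,
        max_error=float(seg_err.max()),
    )


@dataclass
class RobustModelSpec:
    stand_ids: list[int]  # managed stands, order of the Cholesky axes
    regime_ids: list[int]
    enpv: dict  # (stand, regime) -> expected NPV over all trajectories
    chol: np.ndarray  # (n_regimes, n_stands, n_stands) lower-triangular
    beta: float
    epsilon: float = 0.05
    pwl_halfwidth: float = 10.0
    pwl_segments: int = 24
    pwl_segments_hypo: int = 6
    volb_floor: float = 0.0
    mip_gap: float = 0.05
    second_term_sign: str = "minus"  # printed-model default; "plus" accumulates

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0.0 < self.epsilon < 1.0) and self.epsilon != 1.0:
            raise ValueError("epsilon must lie in (0, 1]")
        if self.second_term_sign not in ("minus", "plus"):
            raise ValueError("second_term_sign must be 'minus' or 'plus'")
        nr, n, n2 = self.chol.shape
        if n != n2 or nr != len(self.regime_ids) or n != len(self.stand_ids):
            raise ValueError("Cholesky dimensions do not match stands/regimes")


def build_robust_model(
    rspec: RobustModelSpec,
    base: DeterministicModelSpec,
    cuts: list | None = None,
) -> MilpBuilder:
    """Deterministic constraints + Bernstein VaR constraint, expected NPVs."""
    if rspec.stand_ids != base.managed_ids:
        raise ValueError("robust spec stand order must match the managed stands")
    if rspec.regime_ids != base.regime_ids:
        raise ValueError("robust spec regimes must match the base spec")
    base = replace(base, volb_floor=rspec.volb_floor, mip_gap=rspec.mip_gap)
    b = build_deterministic_model(base, cuts=cuts, network=True, objective_override=rspec.enpv)
    managed = base.managed_ids
    regimes = base.regime_ids
    nm, nr = len(managed), len(regimes)
    xs = b.names["x"]
    azs = b.names["auxz"]
    xi = {(s, j): xs[a * nr + c] for a, s in enumerate(managed) for c, j in enumerate(regimes)}
    azi = {(s, j): azs[a * nr + c] for a, s in enumerate(managed) for c, j in enumerate(regimes)}
    areas = np.array([base.areas[s] for s in managed])
    by_stand = base.grid.by_stand()
    max_pts = np.array([len(by_stand.get(s, [])) for s in managed], dtype=float)

    beta = rspec.beta
    pwl_epi = lncosh_pwl(rspec.pwl_halfwidth, rspec.pwl_segments)
    t = b.add_vars("t", 1, lb=0.0)[0]
    b.set_objective(t, -1.0)

    bern_idx: list[int] = [t]
    bern_co: list[float] = [-1.0]

    for jr, j in enumerate(regimes):
        lmat = rspec.chol[jr]
        for i in range(nm):
            col = lmat[:, i]
            nz = np.nonzero(np.abs(col) > 1e-14)[0]
            if nz.size == 0:
                continue
            # epigraph block for the harvest (x) terms
            u1 = b.add_vars(f"u1_{jr}_{i}", 1, lb=-np.inf)[0]
            l1 = b.add_vars(f"L1_{jr}_{i}", 1, lb=0.0)[0]
            b.add_constraint(
                [xi[(managed[k], j)] for k in nz] + [u1],
                [col[k] / beta for k in nz] + [-1.0],
                lb=0.0,
                ub=0.0,
            )
            for slope, inter in pwl_epi.upper_pieces:
                b.add_constraint([l1, u1], [1.0, -slope], lb=inter)
            bern_idx.append(l1)
            bern_co.append(beta)

            # island-correction (auxz) terms
            ub2 = float(np.sum(np.abs(col[nz]) * max_pts[nz] / areas[nz]) / beta)
            if ub2 <= 1e-12:
                continue
            u2 = b.add_vars(f"u2_{jr}_{i}", 1, lb=-np.inf)[0]
            b.add_constraint(
                [azi[(managed[k], j)] for k in nz] + [u2],
                [col[k] / (beta * areas[k]) for k in nz] + [-1.0],
                lb=0.0,
                ub=0.0,
            )
            if rspec.second_term_sign == "plus":
                l2 = b.add_vars(f"L2_{jr}_{i}", 1, lb=0.0)[0]
                for slope, inter in pwl_epi.upper_pieces:
                    b.add_constraint([l2, u2], [1.0, -slope], lb=inter)
                bern_idx.append(l2)
                bern_co.append(beta)
                continue
            x2 = min(rspec.pwl_halfwidth, ub2)
            pwl2 = lncosh_pwl(x2, rspec.pwl_segments_hypo)
            nseg = len(pwl2.breakpoints) - 1
            l2 = b.add_vars(f"L2_{jr}_{i}", 1, lb=-np.inf)[0]
            lam = b.add_vars(f"lam_{jr}_{i}", nseg + 1, lb=0.0, ub=1.0)
            dl = b.add_vars(f"dl_{jr}_{i}", nseg, lb=0, ub=1, integer=True)
            b.add_constraint(lam, np.ones(nseg + 1), lb=1.0, ub=1.0)
            b.add_constraint(dl, np.ones(nseg), lb=1.0, ub=1.0)
            b.add_constraint(list(lam) + [u2], list(pwl2.breakpoints) + [-1.0], lb=0.0, ub=0.0)
            b.add_constraint(
                list(lam) + [l2], list(pwl2.node_values_safe) + [-1.0], lb=0.0, ub=0.0
            )
            for m in range(nseg + 1):
                segs = [dl[m - 1]] if m > 0 else []
                if m < nseg:
                    segs.append(dl[m])
                b.add_constraint([lam[m]] + segs, [1.0] + [-1.0] * len(segs), ub=0.0)
            bern_idx.append(l2)
            bern_co.append(-beta)

    # -t + beta*sum L1 (-/+) beta*sum L2 <= -beta*ln(1/eps)
    b.add_constraint(bern_idx, bern_co, ub=-beta * np.log(1.0 / rspec.epsilon))
    return b


def bernstein_t(
    a_terms: np.ndarray,
    b_terms: np.ndarray,
    beta: float,
    epsilon: float = 0.05,
    second_term_sign: str = "minus",
) -> float:
    """Exact (non-linearized) value of the VaR allowance at fixed decisions."""
    s = -1.0 if second_term_sign == "minus" else 1.0
    return float(
        beta * np.sum(lncosh(np.asarray(a_terms) / beta))
        + s * beta * np.sum(lncosh(np.asarray(b_terms) / beta))
        + beta * np.log(1.0 / epsilon)
    )


@dataclass
class BetaCalibration:
    proxy: float
    grid: np.ndarray
    t_at_proxy: float
    floor: float


def plan_bernstein_terms(
    plan: Plan, rspec: RobustModelSpec, base: DeterministicModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """(a, b) linear-combination terms of the Bernstein bound at a fixed plan."""
    managed = base.managed_ids
    nm = len(managed)
    nr = len(rspec.regime_ids)
    a = np.zeros((nr, nm))
    bb = np.zeros((nr, nm))
    for jr, j in enumerate(rspec.regime_ids):
        xvec = np.array([plan.x(s, j) for s in managed], dtype=float)
        azvec = np.array(
            [plan.auxz.get((s, j), 0) / base.areas[s] for s in managed], dtype=float
        )
        a[jr] = rspec.chol[jr].T @ xvec
        bb[jr] = rspec.chol[jr].T @ azvec
    return a.ravel(), bb.ravel()


def calibrate_beta(
    det_plan: Plan,
    rspec: RobustModelSpec,
    base: DeterministicModelSpec,
    beta_floor: float | None = None,
    grid_multipliers: tuple = (0.25, 0.5, 1.0, 2.0, 4.0),
) -> BetaCalibration:
    """Proxy beta: minimizes the exact ``t`` at the deterministic decisions.

    One-dimensional golden-type search over log beta; the proxy is
    clamped at a floor (default 1e-4 x mean |E npv|) to keep the
    ln cosh arguments numerically sane.
    """
    a, bb = plan_bernstein_terms(det_plan, rspec, base)
    if beta_floor is None:
        scale = np.mean(np.abs(list(rspec.enpv.values()))) or 1.0
        beta_floor = 1e-4 * scale
    hi = max(1e3 * max(np.abs(a).max(), beta_floor), 10 * beta_floor)

    def t_of_logb(lb: float) -> float:
        val = bernstein_t(a, bb, np.exp(lb), rspec.epsilon, rspec.second_term_sign)
        return val if np.isfinite(val) else 1e30

    res = minimize_scalar(
        t_of_logb,
        bounds=(np.log(beta_floor), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise ValueError("Bernstein allowance non-finite over the whole beta range")
    proxy = float(np.clip(np.exp(res.x), beta_floor, hi))
    return BetaCalibration(
        proxy=proxy,
        grid=proxy * np.asarray(grid_multipliers, dtype=float),
        t_at_proxy=float(res.fun),
        floor=float(beta_floor),
    )


def solve_robust(
    rspec: RobustModelSpec,
    base: DeterministicModelSpec,
    time_limit: float | None = None,
    seed: int = 0,
    max_cut_rounds: int = 30,
    initial_cuts: list | None = None,
) -> Plan:
    """Solve the robust counterpart with lazy ring-inequality separation.

    ``initial_cuts`` (e.g. from a prior deterministic solve) are valid for
    any objective and warm-start the separation loop.
    """
    base_eff = replace(base, volb_floor=rspec.volb_floor, mip_gap=rspec.mip_gap)
    cuts: list = list(initial_cuts or [])
    plan = None
    for round_no in range(max_cut_rounds):
        b = build_robust_model(rspec, base_eff, cuts=cuts)
        res = b.solve(mip_rel_gap=rspec.mip_gap, time_limit=time_limit)
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
        plan = extract_plan(b, res, base_eff, network=True)
        plan.cut_rounds = round_no + 1
        plan.cuts = list(cuts)
        plan.t = float(res.x[b.names["t"][0]])
        plan.beta = rspec.beta
        new_cuts = separate_ring_inequalities(plan.reserves, base_eff)
        fresh = [c for c in new_cuts if c not in cuts]
        if not fresh:
            return plan
        cuts.extend(fresh)
    plan.status = "cut_limit"
    return plan


def choose_beta_by_var(
    grid: np.ndarray,
    rspec: RobustModelSpec,
    base: DeterministicModelSpec,
    scen,
    time_limit: float | None = None,
) -> tuple[Plan, list[dict]]:
    """Solve the robust model per candidate beta; keep the best by MC VaR."""
    from ..evaluation import evaluate_plan

    records = []
    best = None
    for bval in np.asarray(grid, dtype=float):
        rs = replace(rspec, beta=float(bval))
        plan = solve_robust(rs, base, time_limit=time_limit)
        if plan.status not in ("optimal", "time_limit"):
            records.append({"beta": float(bval), "status": plan.status, "var_5": np.nan})
            continue
        rep = evaluate_plan(plan, scen, base)
        records.append(
            {
                "beta": float(bval),
                "status": plan.status,
                "var_5": rep.var_5,
                "expected_npv": rep.expected_npv,
                "t": plan.t,
            }
        )
        if best is None or rep.var_5 > best[1]:
            best = (plan, rep.var_5)
    if best is None:
        raise RuntimeError("no beta in the grid produced a solvable robust model")
    return best[0], records
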