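"""End-to-end study drivers: deterministic plan, scenarios, robust plan.

Chains the synthetic generators, the economics and uncertainty engines and
the two optimization models into the standard study sequence, so scripts
and tests share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import presets, uncertainty
from .milp import (
    Plan,
    RobustModelSpec,
    calibrate_beta,
    solve_deterministic,
    solve_robust,
    verify_solution,
)
from .milp.robust import choose_beta_by_var


@dataclass
class RobustStudy:
    instance: presets.Instance
    det_plan: Plan
    scenarios: uncertainty.ScenarioSet
    covariance: uncertainty.CovarianceModel
    rspec: RobustModelSpec
    beta_proxy: float
    rob_plan: Plan
    beta_records: list | None = None


def expected_npv_dict(scen: uncertainty.ScenarioSet) -> dict:
    return {
        (int(r["stand_id"]), int(r["regime_id"])): float(r["enpv"])
        for _, r in scen.expected_npv().iterrows()
    }


def scaled_volb_floor(instance: presets.Instance, full_scale_m3: float = 200_000.0) -> float:
    """The robust volume-bound floor, scaled from the full study area.

    200,000 m3 per decade on 2,534 ha corresponds pro rata to the
    instance's total area.
    """
    return full_scale_m3 * instance.spec.total_area / 2534.0


def run_robust_study(
    seed: int = 1,
    instance: presets.Instance | None = None,
    n_per_trajectory: int = 100,
    det_time_limit: float = 120.0,
    rob_time_limit: float = 120.0,
    pwl_segments_hypo: int = 2,
    beta_grid: tuple | None = None,
    scenario_seed_offset: int = 100,
) -> RobustStudy:
    """Deterministic plan -> scenario engine -> covariance -> robust plan.

    ``beta_grid`` of multipliers triggers grid search with Monte-Carlo VaR
    selection; otherwise the calibrated proxy is used directly.
    """
    inst = instance or presets.small_instance(seed=seed)
    det = solve_deterministic(inst.spec, time_limit=det_time_limit)
    if det.status not in ("optimal", "time_limit"):
        raise RuntimeError(f"deterministic solve failed: {det.status}")
    scen = presets.default_scenarios(
        inst, n_per_trajectory=n_per_trajectory, seed=seed + scenario_seed_offset
    )
    cov = uncertainty.estimate_covariance(scen)
    rspec = RobustModelSpec(
        stand_ids=inst.spec.managed_ids,
        regime_ids=inst.spec.regime_ids,
        enpv=expected_npv_dict(scen),
        chol=cov.chol,
        beta=1.0,
        pwl_segments_hypo=pwl_segments_hypo,
        volb_floor=scaled_volb_floor(inst),
    )
    cal = calibrate_beta(det, rspec, inst.spec)
    records = None
    if beta_grid:
        cal_grid = cal.proxy * np.asarray(beta_grid, dtype=float)
        rob, records = choose_beta_by_var(
            cal_grid, rspec, inst.spec, scen, time_limit=rob_time_limit
        )
    else:
        rob = solve_robust(
            replace(rspec, beta=cal.proxy),
            inst.spec,
            time_limit=rob_time_limit,
            initial_cuts=det.cuts,
        )
    if rob.status not in ("optimal", "time_limit"):
        raise RuntimeError(f"robust solve failed: {rob.status}")
    return RobustStudy(
        instance=inst,
        det_plan=det,
        scenarios=scen,
        covariance=cov,
        rspec=rspec,
        beta_proxy=cal.proxy,
        rob_plan=rob,
        beta_records=records,
    )


def audited(plan: Plan, spec) -> Plan:
    report = verify_solution(plan, spec)
    if not report.ok:
        raise RuntimeError(f"plan audit failed: {report.failed()}")
    return plan
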