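"""Serialization helpers: plans and reports to JSON-friendly dicts."""

from __future__ import annotations

import json
from pathlib import Path

from .milp.deterministic import Plan


def plan_to_dict(plan: Plan) -> dict:
    return {
        "status": plan.status,
        "objective": plan.objective,
        "gap": plan.gap,
        "vol_b": plan.vol_b,
        "sum_pt": plan.sum_pt,
        "t": plan.t,
        "beta": plan.beta,
        "network": plan.network,
        "cut_rounds": plan.cut_rounds,
        "regime_of": {str(k): int(v) for k, v in plan.regime_of.items()},
        "reserves": sorted(int(s) for s in plan.reserves),
        "z": {str(k): int(v) for k, v in plan.z.items() if v},
        "auxz": {f"{s},{j}": int(v) for (s, j), v in plan.auxz.items() if v},
        "points": sorted(int(p) for p in plan.points),
        "arcs": sorted([int(i), int(j)] for i, j in plan.arcs),
    }


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=float)
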