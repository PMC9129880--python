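"""Systematic parameter sweeps over chain simulations.

Covaries interaction levels (leader CIL intensity, co-attraction, cell
size) and chain composition on a full factorial grid, runs seeded
replicates of each combination, scores every replicate with the
five-criterion suite, and counts which parameter sets fulfil each score.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import (
    CELL_SIZE_LEVELS,
    CIL_TURN_LEVELS,
    COATTRACTION_LEVELS,
    Arena,
    Composition,
    Identity,
    ModelParams,
    simulate,
)
from .scoring import ScoreConfig, ScoreReport, score_all
from .seeds import derive_seed

__all__ = [
    "DEFAULT_LEVELS",
    "SCORE_NAMES",
    "SweepResult",
    "enumerate_grid",
    "apply_levels",
    "run_sweep",
    "count_passing",
]

SCORE_NAMES = (
    "cohesion",
    "single_file",
    "follower_rearrangement",
    "leader_front",
    "path_completion",
)

# LevelMap: parameter name -> ordered {low, medium, high} numeric levels.
DEFAULT_LEVELS: dict[str, dict[str, float]] = {
    "cil_intensity": {k: CIL_TURN_LEVELS[k] for k in ("low", "medium", "high")},
    "coattraction": {k: COATTRACTION_LEVELS[k] for k in ("low", "medium", "high")},
    "cell_size": dict(CELL_SIZE_LEVELS),
}


def _check_levels(levels: dict[str, dict[str, float]]) -> None:
    for name, lv in levels.items():
        vals = list(lv.values())
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ConfigurationError(
                f"levels of {name!r} must strictly increase in effect magnitude"
            )


def enumerate_grid(
    levels: dict[str, dict[str, float]],
    swept: list[str],
    composition: Composition,
) -> list[dict]:
    """Full Cartesian product of level choices for the swept parameters.

    Deterministic order: parameters in the given ``swept`` order, levels in
    their stored (low < medium < high) order.  An empty ``swept`` list
    yields the single default combination.
    """
    _check_levels(levels)
    for name in swept:
        if name not in levels:
            raise ConfigurationError(f"unknown swept parameter {name!r}")
    choices = [list(levels[name].keys()) for name in swept]
    combos = []
    for values in itertools.product(*choices) if swept else [()]:
        combos.append(
            {"levels": dict(zip(swept, values)), "composition": composition}
        )
    return combos


def apply_levels(
    base: ModelParams, level_names: dict[str, str]
) -> ModelParams:
    """Realise a grid point as ModelParams.

    ``cil_intensity`` and ``coattraction`` set the leader CIL level and the
    group co-attraction level; ``cell_size`` scales the leader radius
    (followers keep their defaults, the low setting).
    """
    params = base
    if "cil_intensity" in level_names:
        intensity = dict(params.cil_intensity)
        intensity[Identity.LEADER] = level_names["cil_intensity"]
        params = dc_replace(params, cil_intensity=intensity)
    if "coattraction" in level_names:
        params = dc_replace(params, coattraction_strength=level_names["coattraction"])
    if "cell_size" in level_names:
        scale = CELL_SIZE_LEVELS[level_names["cell_size"]]
        radii = dict(params.cell_radius)
        radii[Identity.LEADER] = ModelParams().cell_radius[Identity.LEADER] * scale
        params = dc_replace(params, cell_radius=radii)
    return params


@dataclass
class SweepResult:
    """Per-combination replicate scores and pass fractions."""

    combinations: list[dict] = field(default_factory=list)
    n_reps: int = 0
    match_threshold: float = 0.7
    master_seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per combination x replicate x score outcome."""
        rows = []
        for c in self.combinations:
            for rep, report in enumerate(c["reports"]):
                row = {
                    "combination": c["index"],
                    "composition": c["composition"],
                    **{f"level_{k}": v for k, v in c["levels"].items()},
                    "replicate": rep,
                    "seed": c["seeds"][rep],
                    "failed": report is None,
                }
                if report is not None:
                    row.update({s: report[s] for s in SCORE_NAMES})
                    row["all"] = all(report[s] for s in SCORE_NAMES)
                rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "match_threshold": self.match_threshold,
            "master_seed": self.master_seed,
            "combinations": [
                {k: v for k, v in c.items() if k != "reports"}
                | {"reports": c["reports"]}
                for c in self.combinations
            ],
        }


def run_sweep(
    grid: list[dict],
    arena: Arena | None = None,
    n_reps: int = 20,
    master_seed: int = 0,
    base_params: ModelParams | None = None,
    score_cfg: ScoreConfig | None = None,
    match_threshold: float = 0.7,
) -> SweepResult:
    """Simulate and score every grid combination with seeded replicates.

    Replicate seeds derive from ``(master_seed, combination index,
    replicate index)`` only, so results are independent of execution order.
    A combination matches a score when at least ``match_threshold`` of its
    replicates pass it, and matches overall when that holds for all five.
    A replicate that raises is recorded as failed, not fatal.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    arena = arena or Arena()
    base_params = base_params or ModelParams()
    score_cfg = score_cfg or ScoreConfig()
    result = SweepResult(
        n_reps=n_reps, match_threshold=match_threshold, master_seed=master_seed
    )
    for index, combo in enumerate(grid):
        params = apply_levels(base_params, combo["levels"])
        seeds = [derive_seed(master_seed, "sweep", index, rep) for rep in range(n_reps)]
        reports: list[dict | None] = []
        for rep_seed in seeds:
            try:
                traj = simulate(combo["composition"], arena, params, seed=rep_seed)
                report = score_all(traj, arena, score_cfg)
                reports.append(
                    {s: bool(report.passes()[s]) for s in SCORE_NAMES}
                )
            except Exception:
                reports.append(None)
        scored = [r for r in reports if r is not None]
        fractions = {
            s: (np.mean([r[s] for r in scored]) if scored else 0.0)
            for s in SCORE_NAMES
        }
        matches = all(fractions[s] >= match_threshold for s in SCORE_NAMES)
        result.combinations.append(
            {
                "index": index,
                "levels": dict(combo["levels"]),
                "composition": combo["composition"].to_string(),
                "seeds": seeds,
                "reports": reports,
                "pass_fractions": {s: float(fractions[s]) for s in SCORE_NAMES},
                "combination_matches": bool(matches),
            }
        )
    return result


def count_passing(sweep: SweepResult, score_name: str = "all") -> int:
    """Number of combinations fulfilling one score (or all five)."""
    if score_name == "all":
        return sum(c["combination_matches"] for c in sweep.combinations)
    if score_name not in SCORE_NAMES:
        raise ConfigurationError(f"unknown score {score_name!r}")
    return sum(
        c["pass_fractions"][score_name] >= sweep.match_threshold
        for c in sweep.combinations
    )
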