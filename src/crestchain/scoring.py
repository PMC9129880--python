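"""Multi-objective scoring of simulated chain behaviour.

Five criteria, calibrated on in-vivo trunk neural crest measurements, decide
whether a simulated chain "matches" control migration:

1. **cohesion** — adjacent cells (in ventral chain order) never separate by
   more than 57 um;
2. **single_file** — no side-by-side cell pair in at least 80% of frames;
3. **follower_rearrangement** — at least one sustained follower-follower
   rank swap occurs;
4. **leader_front** — a leader holds the chain front nearly throughout, and
   no follower sustainedly overtakes the designated front leader;
5. **path_completion** — the chain front reaches the end of the migratory
   path (with a separate over-migration flag for fronts that end beyond it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InapplicableCriterionError
from .model import Arena, Identity, Trajectory

__all__ = [
    "ScoreConfig",
    "ScoreReport",
    "score_cohesion",
    "score_single_file",
    "detect_overtakings",
    "score_follower_rearrangement",
    "score_leader_front",
    "score_path_completion",
    "score_all",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Thresholds of the five chain criteria.

    ``cohesion_max`` (57 um) and ``singlefile_min_fraction`` (0.80) are the
    in-vivo calibrated values; the remaining knobs make the discrete rules
    robust to jitter at 5-minute sampling.  ``cohesion_tolerated_fraction``
    optionally relaxes cohesion from "never" to "in at most this fraction
    of frames" (off by default: the criterion states a maximum).
    """

    cohesion_max: float = 57.0
    singlefile_min_fraction: float = 0.80
    front_retention_min_fraction: float = 0.95
    overmigration_margin: float = 11.4  # one leader diameter
    overtake_delta: float = 2.0  # um a cell must lead by
    overtake_min_frames: int = 3  # consecutive frames (15 min)
    side_by_side_slack: float = 2.0  # um added to contact distance
    side_by_side_level_fraction: float = 0.5  # |dy| < this * min radius
    cohesion_tolerated_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.cohesion_max <= 0:
            raise ValueError("cohesion_max must be > 0")
        if not (0 < self.singlefile_min_fraction <= 1):
            raise ValueError("singlefile_min_fraction must be in (0, 1]")
        if not (0 < self.front_retention_min_fraction <= 1):
            raise ValueError("front_retention_min_fraction must be in (0, 1]")
        if self.overmigration_margin < 0 or self.overtake_delta < 0:
            raise ValueError("margins must be >= 0")


@dataclass
class ScoreReport:
    """Pass/fail plus the measured value for each of the five criteria."""

    cohesion: dict
    single_file: dict
    follower_rearrangement: dict
    leader_front: dict
    path_completion: dict

    @property
    def all_pass(self) -> bool:
        return all(
            part["pass"]
            for part in (
                self.cohesion,
                self.single_file,
                self.follower_rearrangement,
                self.leader_front,
                self.path_completion,
            )
        )

    def passes(self) -> dict[str, bool]:
        return {
            "cohesion": self.cohesion["pass"],
            "single_file": self.single_file["pass"],
            "follower_rearrangement": self.follower_rearrangement["pass"],
            "leader_front": self.leader_front["pass"],
            "path_completion": self.path_completion["pass"],
            "all": self.all_pass,
        }

    def to_dict(self) -> dict:
        return {
            "cohesion": self.cohesion,
            "single_file": self.single_file,
            "follower_rearrangement": self.follower_rearrangement,
            "leader_front": self.leader_front,
            "path_completion": self.path_completion,
            "all_pass": self.all_pass,
        }


def _adjacent_gaps(traj: Trajectory) -> np.ndarray:
    """Per frame, Euclidean distances between ventral-order neighbours."""
    pos = traj.positions
    order = np.argsort(-pos[:, :, 1], axis=1, kind="stable")
    frames = np.arange(pos.shape[0])[:, None]
    ordered = pos[frames, order]
    return np.linalg.norm(np.diff(ordered, axis=1), axis=2)


def score_cohesion(traj: Trajectory, cfg: ScoreConfig | None = None) -> dict:
    """Maximum adjacent-cell gap in chain order; pass iff within 57 um."""
    cfg = cfg or ScoreConfig()
    if traj.n_cells < 2:
        raise InapplicableCriterionError("cohesion needs at least two cells")
    gaps = _adjacent_gaps(traj)
    max_gap = float(gaps.max())
    if cfg.cohesion_tolerated_fraction is None:
        ok = max_gap <= cfg.cohesion_max
    else:
        bad = np.any(gaps > cfg.cohesion_max, axis=1).mean()
        ok = bad <= cfg.cohesion_tolerated_fraction
    return {"pass": bool(ok), "max_adjacent_gap": max_gap}


def _side_by_side_any(traj: Trajectory, cfg: ScoreConfig) -> np.ndarray:
    """Boolean per frame: does any pair sit side by side?

    A pair is side by side when the cells are laterally level (|dy| within
    ``side_by_side_level_fraction`` of the smaller radius) while effectively
    in contact.  The half-radius default counts genuinely abreast cells but
    not the transient diagonal contacts of cells squeezing past each other
    in a narrow corridor.
    """
    pos = traj.positions
    r = traj.radii
    n = traj.n_cells
    flags = np.zeros(pos.shape[0], dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            dy = np.abs(pos[:, i, 1] - pos[:, j, 1])
            dist = np.linalg.norm(pos[:, i] - pos[:, j], axis=1)
            close = dist < r[i] + r[j] + cfg.side_by_side_slack
            level = dy < cfg.side_by_side_level_fraction * min(r[i], r[j])
            flags |= close & level
    return flags


def score_single_file(traj: Trajectory, cfg: ScoreConfig | None = None) -> dict:
    """Fraction of frames with no side-by-side pair; pass iff >= 80%."""
    cfg = cfg or ScoreConfig()
    if traj.n_cells < 2:
        raise InapplicableCriterionError("single-file needs at least two cells")
    bad = _side_by_side_any(traj, cfg)
    fraction = float(1.0 - bad.mean())
    return {"pass": bool(fraction >= cfg.singlefile_min_fraction), "fraction": fraction}


def _sustained_lead_events(
    delta_y: np.ndarray, delta: float, min_frames: int
) -> list[tuple[int, int]]:
    """Maximal runs where ``delta_y > delta`` for at least ``min_frames``."""
    ahead = delta_y > delta
    events = []
    start = None
    for t, flag in enumerate(ahead):
        if flag and start is None:
            start = t
        elif not flag and start is not None:
            if t - start >= min_frames:
                events.append((start, t))
            start = None
    if start is not None and len(ahead) - start >= min_frames:
        events.append((start, len(ahead)))
    return events


def detect_overtakings(traj: Trajectory, cfg: ScoreConfig | None = None) -> dict:
    """Sustained overtaking events relative to the designated front cell.

    The front cell is the most ventral cell at frame 0.  A follower
    overtakes it by staying more than ``overtake_delta`` um ahead for at
    least ``overtake_min_frames`` consecutive frames; the count of distinct
    follower overtakers maps to the categories 0 / 1 / >1.  The same
    sustained rule, applied to follower pairs, yields the rank swaps of the
    rearrangement criterion.
    """
    cfg = cfg or ScoreConfig()
    pos = traj.positions
    front = int(np.argmax(pos[0, :, 1]))
    followers = [
        k for k, ident in enumerate(traj.identities) if ident is Identity.FOLLOWER
    ]

    overtakers = []
    for j in followers:
        if j == front:
            continue
        events = _sustained_lead_events(
            pos[:, j, 1] - pos[:, front, 1], cfg.overtake_delta, cfg.overtake_min_frames
        )
        if events:
            overtakers.append(j)
    count = len(overtakers)
    category = "0" if count == 0 else ("1" if count == 1 else ">1")

    # follower-follower rank swaps: transitions between sustained lead states
    swaps = 0
    swap_pairs = []
    for a_idx in range(len(followers)):
        for b_idx in range(a_idx + 1, len(followers)):
            a, b = followers[a_idx], followers[b_idx]
            s = pos[:, a, 1] - pos[:, b, 1]
            lead_a = _sustained_lead_events(s, cfg.overtake_delta, cfg.overtake_min_frames)
            lead_b = _sustained_lead_events(-s, cfg.overtake_delta, cfg.overtake_min_frames)
            states = sorted(
                [(ev[0], "a") for ev in lead_a] + [(ev[0], "b") for ev in lead_b]
            )
            for prev, cur in zip(states, states[1:]):
                if prev[1] != cur[1]:
                    swaps += 1
                    swap_pairs.append((a, b))
    return {
        "front_cell": front,
        "overtakers": overtakers,
        "overtaken_category": category,
        "swap_count": swaps,
        "swap_pairs": swap_pairs,
    }


def score_follower_rearrangement(
    traj: Trajectory, cfg: ScoreConfig | None = None
) -> dict:
    """Pass iff at least one sustained follower-follower rank swap occurs."""
    events = detect_overtakings(traj, cfg)
    return {"pass": events["swap_count"] >= 1, "swap_count": events["swap_count"]}


def score_leader_front(traj: Trajectory, cfg: ScoreConfig | None = None) -> dict:
    """Leaders hold the front; no follower sustainedly overtakes.

    ``retention_fraction`` is the fraction of frames whose most ventral
    cell is a leader.  A chain without any leader cannot pass.
    """
    cfg = cfg or ScoreConfig()
    has_leader = any(i is Identity.LEADER for i in traj.identities)
    events = detect_overtakings(traj, cfg)
    if not has_leader:
        return {
            "pass": False,
            "retention_fraction": 0.0,
            "overtaken_category": events["overtaken_category"],
        }
    leader_mask = np.array([i is Identity.LEADER for i in traj.identities])
    front_each_frame = np.argmax(traj.positions[:, :, 1], axis=1)
    retention = float(leader_mask[front_each_frame].mean())
    ok = (
        retention >= cfg.front_retention_min_fraction
        and events["overtaken_category"] == "0"
    )
    return {
        "pass": bool(ok),
        "retention_fraction": retention,
        "overtaken_category": events["overtaken_category"],
    }


def score_path_completion(
    traj: Trajectory, arena: Arena | None = None, cfg: ScoreConfig | None = None
) -> dict:
    """Front of the chain reaches the end of the migratory path.

    ``reached`` uses the maximum ventral position attained by any leader
    (any cell, for leaderless chains); ``over_migrated`` flags a final
    front position beyond ``y_end`` plus the over-migration margin.
    """
    cfg = cfg or ScoreConfig()
    arena = arena or traj.arena or Arena()
    leader_mask = np.array([i is Identity.LEADER for i in traj.identities])
    y = traj.positions[:, :, 1]
    y_front_pool = y[:, leader_mask] if leader_mask.any() else y
    reached = bool(y_front_pool.max() >= arena.y_end)
    final_front = float(y[-1].max())
    over = bool(final_front > arena.y_end + cfg.overmigration_margin)
    return {
        "pass": reached,
        "reached": reached,
        "over_migrated": over,
        "final_front_y": final_front,
    }


def score_all(
    traj: Trajectory, arena: Arena | None = None, cfg: ScoreConfig | None = None
) -> ScoreReport:
    """Evaluate all five criteria on one trajectory."""
    cfg = cfg or ScoreConfig()
    return ScoreReport(
        cohesion=score_cohesion(traj, cfg),
        single_file=score_single_file(traj, cfg),
        follower_rearrangement=score_follower_rearrangement(traj, cfg),
        leader_front=score_leader_front(traj, cfg),
        path_completion=score_path_completion(traj, arena, cfg),
    )
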