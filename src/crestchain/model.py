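"""Discrete-element model of trunk neural crest (TNC) chain migration.

Cells are 2D particles in a dorsoventral corridor (x = anteroposterior,
y increasing ventrally).  Each carries a migratory identity (leader or
follower) and moves with intrinsic motility along a persistent heading.
Four interactions shape collective movement:

* **Contact inhibition of locomotion (CIL)** — on contact, a cell's heading
  rotates away from its partner.  In ``differential`` mode only
  leader-follower contacts trigger CIL; in ``all_pairs`` mode every contact
  does.  The turn magnitude grows with the cell's CIL intensity level, and
  the post-collision heading persists for a refractory window.
* **Co-attraction** — a displacement toward the centroid of neighbours
  within a finite range, holding the group together.
* **Volume exclusion** — hard projection resolving cell overlap; the
  exclusion radius is the model's proxy for cell size.
* **Heading noise (zeta)** — a per-step Gaussian rotation of the heading.

Chains start single file in the premigratory region and migrate ventrally.
Intrinsic motility arrests once a cell reaches the end of the migratory
path (``y_end``); co-attraction and exclusion still apply there, so a
crowded chain arriving early can push its front past the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, NumericalError
from .seeds import derive_rng

__all__ = [
    "Identity",
    "AgentState",
    "ModelParams",
    "Arena",
    "Composition",
    "Trajectory",
    "CIL_TURN_LEVELS",
    "COATTRACTION_LEVELS",
    "CELL_SIZE_LEVELS",
    "init_chain",
    "step",
    "resolve_cil",
    "coattraction_displacement",
    "simulate",
]


class Identity(str, Enum):
    LEADER = "leader"
    FOLLOWER = "follower"

    @classmethod
    def from_char(cls, c: str) -> "Identity":
        if c.upper() == "L":
            return cls.LEADER
        if c.upper() == "F":
            return cls.FOLLOWER
        raise ConfigurationError(f"unknown identity character {c!r}")


# Calibration constants for the low/medium/high interaction levels.  These
# are model calibration values, not measured quantities: the CIL levels are
# heading-turn angles (radians), the co-attraction levels drift magnitudes
# (um/min), and the cell-size levels multipliers on the leader radius.
CIL_TURN_LEVELS: dict[str, float] = {
    "off": 0.0,
    "low": math.pi / 12,
    "medium": math.pi / 4,
    "high": math.pi / 2,
}
COATTRACTION_LEVELS: dict[str, float] = {
    "off": 0.0,
    "low": 0.05,
    "medium": 0.15,
    "high": 0.3,
}
CELL_SIZE_LEVELS: dict[str, float] = {
    "low": 0.84,
    "medium": 1.0,
    "high": 1.2,
}


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one simulation.

    Lengths are um, times minutes, angles radians.  ``cil_intensity`` and
    ``coattraction_strength`` name levels in the calibration maps above.
    """

    cil_mode: str = "differential"  # off | differential | all_pairs
    cil_intensity: dict[Identity, str] = field(
        default_factory=lambda: {Identity.LEADER: "high", Identity.FOLLOWER: "low"}
    )
    coattraction_strength: str = "high"
    coattraction_range: float = 60.0
    cell_radius: dict[Identity, float] = field(
        default_factory=lambda: {Identity.LEADER: 5.70, Identity.FOLLOWER: 4.79}
    )
    zeta: float = 0.15  # heading-noise SD, radians per step
    base_speed: dict[Identity, float] = field(
        default_factory=lambda: {Identity.LEADER: 0.7, Identity.FOLLOWER: 0.5}
    )
    dt: float = 1.0
    n_steps: int = 960
    sample_every: int = 5
    cil_persistence: int = 1  # steps the post-CIL heading persists
    contact_tolerance: float = 0.5  # um beyond touching that counts as contact
    exclusion_tolerance: float = 0.1  # um of tolerated residual overlap
    init_gap: float = 0.2  # um clearance between stacked cells at t=0
    coattraction_deadzone: float = 2.0  # um beyond touching where co-A is off
    # relaxation of the heading toward the realized displacement; followers
    # follow the motion of the group, leaders keep their own polarity
    heading_alignment: dict[Identity, float] = field(
        default_factory=lambda: {Identity.LEADER: 0.0, Identity.FOLLOWER: 0.05}
    )
    # co-attraction also re-polarises motility: while a cell is separated
    # from the group, its heading relaxes at this rate toward its nearest
    # detached in-range neighbour ahead of it (contact-following of the
    # chain).  A cell with nobody ahead is the pioneer: a leader keeps its
    # own polarity there, a follower is steered back toward the group
    # centroid instead.
    coattraction_steering: dict[Identity, float] = field(
        default_factory=lambda: {Identity.LEADER: 0.0, Identity.FOLLOWER: 0.15}
    )

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        if self.zeta < 0:
            raise ConfigurationError("zeta must be >= 0")
        if self.cil_mode not in ("off", "differential", "all_pairs"):
            raise ConfigurationError(f"unknown cil_mode {self.cil_mode!r}")
        for ident, level in self.cil_intensity.items():
            if level not in CIL_TURN_LEVELS:
                raise ConfigurationError(
                    f"unknown CIL intensity level {level!r} for {ident}"
                )
        if self.coattraction_strength not in COATTRACTION_LEVELS:
            raise ConfigurationError(
                f"unknown co-attraction level {self.coattraction_strength!r}"
            )

    def cil_turn(self, identity: Identity) -> float:
        return CIL_TURN_LEVELS[self.cil_intensity[identity]]

    @property
    def coattraction_step(self) -> float:
        return COATTRACTION_LEVELS[self.coattraction_strength]


@dataclass(frozen=True)
class Arena:
    """Dorsoventral migration corridor.

    ``y`` increases ventrally: 0 is the dorsal edge of the embryo,
    ``y_premigratory`` the ventral edge of the premigratory band,
    ``y_ntnot`` the neural-tube/notochord boundary landmark and ``y_end``
    the end of the migratory path.  The corridor is closed by reflective
    walls on both anteroposterior sides and on the dorsal side
    (``y_dorsal``, a staging extent behind the dorsal edge so that long
    chains can pack single file); the ventral end is open so chains can
    over-migrate beyond ``y_end``.
    """

    width: float = 18.0
    y_premigratory: float = 25.0
    y_ntnot: float = 65.0
    y_end: float = 150.0
    y_dorsal: float = -100.0
    boundary_mode: str = "reflect"

    def __post_init__(self) -> None:
        if not (0 < self.y_premigratory < self.y_ntnot < self.y_end):
            raise ConfigurationError(
                "require 0 < y_premigratory < y_ntnot < y_end"
            )
        if self.y_dorsal >= 0:
            raise ConfigurationError("y_dorsal must be < 0")
        if self.boundary_mode != "reflect":
            raise ConfigurationError("only reflective boundaries are supported")


@dataclass(frozen=True)
class Composition:
    """Ordered identity pattern of a chain; index 0 is the front cell."""

    pattern: tuple[Identity, ...]

    def __post_init__(self) -> None:
        if len(self.pattern) == 0:
            raise ConfigurationError("composition pattern must be non-empty")

    def __len__(self) -> int:
        return len(self.pattern)

    @classmethod
    def from_string(cls, s: str) -> "Composition":
        return cls(tuple(Identity.from_char(c) for c in s))

    @classmethod
    def preset(cls, name: str, n: int = 8) -> "Composition":
        """Named chain architectures.

        ``1:2`` and ``1:3`` are leader:follower ratios realised as repeating
        patterns from the front (``LFF``, ``LFFF``).  ``1:1`` places its
        leaders as a front block (``LLLLFFFF`` for n = 8): with equal
        numbers the excess leaders crowd the chain front rather than
        alternating through it.
        """
        name = name.replace("_", "-")
        if name == "all-leader":
            return cls.from_string("L" * n)
        if name == "all-follower":
            return cls.from_string("F" * n)
        if name == "single-leader":
            return cls.from_string("L" + "F" * (n - 1))
        if name == "1:1":
            k = n - n // 2
            return cls.from_string("L" * k + "F" * (n - k))
        units = {"1:2": "LFF", "1:3": "LFFF"}
        if name in units:
            unit = units[name]
            s = (unit * (n // len(unit) + 1))[:n]
            return cls.from_string(s)
        raise ConfigurationError(f"unknown composition preset {name!r}")

    def to_string(self) -> str:
        return "".join("L" if i is Identity.LEADER else "F" for i in self.pattern)


@dataclass
class AgentState:
    """One simulated cell."""

    agent_id: int
    identity: Identity
    position: np.ndarray  # (2,) [x, y] um
    heading: np.ndarray  # (2,) unit vector
    radius: float
    speed: float  # um/min
    cil_refractory: int = 0  # steps of CIL heading persistence remaining

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        norm = np.linalg.norm(self.heading)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ConfigurationError("heading must be non-zero")
            self.heading = self.heading / norm
        if self.radius <= 0:
            raise ConfigurationError("radius must be > 0")
        if self.speed < 0:
            raise ConfigurationError("speed must be >= 0")


@dataclass
class Trajectory:
    """Sampled positions of one simulated chain.

    ``positions`` has shape (n_frames, n_cells, 2) in um; ``times`` are
    minutes with constant spacing ``dt * sample_every``.
    """

    positions: np.ndarray
    identities: tuple[Identity, ...]
    times: np.ndarray
    radii: np.ndarray
    params: ModelParams | None = None
    arena: Arena | None = None
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_cells(self) -> int:
        return self.positions.shape[1]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ConfigurationError("positions must have shape (frames, cells, 2)")
        if len(self.identities) != self.n_cells:
            raise ConfigurationError("one identity per cell required")
        dts = np.diff(self.times)
        if len(dts) and (np.any(dts <= 0) or not np.allclose(dts, dts[0])):
            raise ConfigurationError("times must increase with constant spacing")


# ---------------------------------------------------------------------------
# geometry helpers


def _rotate(vec: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def _rotate_toward(heading: np.ndarray, target: np.ndarray, max_turn: float) -> np.ndarray:
    """Rotate ``heading`` toward ``target`` by at most ``max_turn`` radians.

    For an exactly antiparallel pair the turn direction is the positive
    (counter-clockwise) sense, a deterministic tie-break.
    """
    if max_turn <= 0:
        return heading.copy()
    cross = heading[0] * target[1] - heading[1] * target[0]
    dot = float(np.clip(np.dot(heading, target), -1.0, 1.0))
    delta = math.atan2(cross, dot)
    if abs(delta) < 1e-12 and dot < 0:  # antiparallel: pick CCW
        delta = math.pi
    turn = math.copysign(min(max_turn, abs(delta)), delta if delta != 0 else 1.0)
    return _rotate(heading, turn)


# ---------------------------------------------------------------------------
# operations


def init_chain(
    composition: Composition,
    arena: Arena,
    params: ModelParams,
    seed: int,
) -> list[AgentState]:
    """Place a chain single file in the premigratory region.

    The front cell (pattern index 0) sits at the ventral edge of the
    premigratory band; the rest stack dorsally, non-overlapping, possibly
    extending into the dorsal staging region.  Headings point ventrally
    (+y) with a small seeded jitter.
    """
    radii = np.array([params.cell_radius[i] for i in composition.pattern])
    if arena.width <= 2 * radii.max():
        raise ConfigurationError(
            f"arena width {arena.width} um must exceed one cell diameter"
        )
    stacked = float(2 * radii.sum() + params.init_gap * (len(radii) - 1))
    capacity = arena.y_premigratory - arena.y_dorsal
    if stacked > capacity:
        raise ConfigurationError(
            f"chain of {len(radii)} cells needs {stacked:.1f} um of stacked "
            f"length but the premigratory region holds {capacity:.1f} um"
        )
    rng = derive_rng(seed, "init")
    agents: list[AgentState] = []
    y = arena.y_premigratory - radii[0]
    for idx, ident in enumerate(composition.pattern):
        if idx > 0:
            y -= radii[idx - 1] + radii[idx] + params.init_gap
        x = arena.width / 2 + float(rng.normal(0, 0.5))
        x = float(np.clip(x, radii[idx], arena.width - radii[idx]))
        # heading jitter scales with the noise model: exactly ventral when
        # the simulation is deterministic (zeta = 0)
        jitter_sd = min(0.05, params.zeta)
        heading = _rotate(
            np.array([0.0, 1.0]),
            float(rng.normal(0, jitter_sd)) if jitter_sd > 0 else 0.0,
        )
        agents.append(
            AgentState(
                agent_id=idx,
                identity=ident,
                position=np.array([x, y]),
                heading=heading,
                radius=float(radii[idx]),
                speed=params.base_speed[ident],
            )
        )
    return agents


def resolve_cil(
    a: AgentState,
    b: AgentState,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """New headings for a contacting pair under contact inhibition.

    Each cell turns away from its partner by at most its identity's CIL
    turn angle.  In ``differential`` mode same-identity contacts leave
    headings unchanged.  Coincident centres are a degenerate contact: the
    repulsion axis is drawn from ``rng``.
    """
    if params.cil_mode == "off" or (
        params.cil_mode == "differential" and a.identity is b.identity
    ):
        return a.heading.copy(), b.heading.copy()
    diff = a.position - b.position
    dist = float(np.linalg.norm(diff))
    if dist < 1e-9:
        if rng is None:
            rng = np.random.default_rng(0)
        angle = float(rng.uniform(0, 2 * math.pi))
        axis = np.array([math.cos(angle), math.sin(angle)])
    else:
        axis = diff / dist
    new_a = _rotate_toward(a.heading, axis, params.cil_turn(a.identity))
    new_b = _rotate_toward(b.heading, -axis, params.cil_turn(b.identity))
    return new_a, new_b


def coattraction_displacement(
    focal: AgentState,
    others: Sequence[AgentState],
    params: ModelParams,
) -> np.ndarray:
    """Co-attraction step toward the centroid of in-range neighbours.

    Co-attraction pulls together cells *at a distance*: a neighbour counts
    only when separated beyond contact (touching distance plus a small
    dead zone) and within ``coattraction_range``.  Zero for an isolated
    cell or when no neighbour is in that annulus; magnitude
    ``epsilon * dt`` otherwise.
    """
    eps = params.coattraction_step
    if eps == 0 or not others:
        return np.zeros(2)
    pos = np.array([o.position for o in others])
    dists = np.linalg.norm(pos - focal.position, axis=1)
    inner = np.array(
        [focal.radius + o.radius + params.coattraction_deadzone for o in others]
    )
    in_range = (dists <= params.coattraction_range) & (dists > inner)
    if not in_range.any():
        return np.zeros(2)
    centroid = pos[in_range].mean(axis=0)
    direction = centroid - focal.position
    norm = float(np.linalg.norm(direction))
    if norm < 1e-12:
        return np.zeros(2)
    return eps * params.dt * direction / norm


def _contact_pairs(pos: np.ndarray, radii: np.ndarray, tol: float) -> list[tuple[int, int]]:
    d = squareform(pdist(pos))
    n = len(pos)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < radii[i] + radii[j] + tol:
                out.append((i, j))
    return out


def _resolve_exclusion(
    pos: np.ndarray,
    radii: np.ndarray,
    tol: float,
    rng: np.random.Generator,
    max_sweeps: int = 60,
) -> np.ndarray:
    """Iterative hard projection removing pairwise overlap beyond ``tol``."""
    pos = pos.copy()
    n = len(pos)
    for _ in range(max_sweeps):
        d = squareform(pdist(pos))
        moved = False
        for i in range(n):
            for j in range(i + 1, n):
                target = radii[i] + radii[j]
                if d[i, j] >= target - tol:
                    continue
                if d[i, j] < 1e-9:
                    angle = float(rng.uniform(0, 2 * math.pi))
                    axis = np.array([math.cos(angle), math.sin(angle)])
                else:
                    axis = (pos[i] - pos[j]) / d[i, j]
                push = (target - d[i, j]) / 2
                pos[i] += push * axis
                pos[j] -= push * axis
                moved = True
        if not moved:
            break
    return pos


def _reflect(
    pos: np.ndarray, head: np.ndarray, arena: Arena, radii: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    pos = pos.copy()
    head = head.copy()
    # anteroposterior walls act on cell edges: centres stay in [r, width - r]
    xmin, xmax = radii, arena.width - radii
    low = pos[:, 0] < xmin
    pos[low, 0] = 2 * xmin[low] - pos[low, 0]
    head[low, 0] = np.abs(head[low, 0])
    high = pos[:, 0] > xmax
    pos[high, 0] = 2 * xmax[high] - pos[high, 0]
    head[high, 0] = -np.abs(head[high, 0])
    # dorsal wall
    ymin = arena.y_dorsal + radii
    dorsal = pos[:, 1] < ymin
    pos[dorsal, 1] = 2 * ymin[dorsal] - pos[dorsal, 1]
    head[dorsal, 1] = np.abs(head[dorsal, 1])
    # safety clamp for pathological displacements
    pos[:, 0] = np.clip(pos[:, 0], xmin, xmax)
    pos[:, 1] = np.maximum(pos[:, 1], ymin)
    norms = np.linalg.norm(head, axis=1, keepdims=True)
    head = head / np.where(norms == 0, 1.0, norms)
    return pos, head


def _step_arrays(
    pos: np.ndarray,
    head: np.ndarray,
    refractory: np.ndarray,
    speeds: np.ndarray,
    radii: np.ndarray,
    identities: Sequence[Identity],
    params: ModelParams,
    arena: Arena,
    noise: np.ndarray,
    event_rng: np.random.Generator,
    step_index: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One update, in the contractual order: intrinsic motility, CIL,
    co-attraction, volume exclusion, heading noise, boundary reflection."""
    n = len(pos)
    pos = pos.copy()
    head = head.copy()
    refractory = refractory.copy()
    pos_start = pos.copy()

    # 1. intrinsic motility.  Cells arrest at the end of the migratory path;
    # the arrest propagates dorsally through the queue by contact, but only
    # for followers — a follower touching a stopped cell stops too, while a
    # leader keeps driving until it reaches the end itself.
    stopped = pos[:, 1] >= arena.y_end
    if stopped.any() and n > 1:
        dmat = squareform(pdist(pos))
        touch = dmat < radii[:, None] + radii[None, :] + params.contact_tolerance
        followers = np.array([ident is Identity.FOLLOWER for ident in identities])
        for _ in range(n):
            grew = followers & ~stopped & (touch & stopped[None, :]).any(axis=1)
            if not grew.any():
                break
            stopped = stopped | grew
    pos = pos + (speeds * params.dt)[:, None] * head * (~stopped)[:, None]

    # 2. contact inhibition of locomotion
    if params.cil_mode != "off":
        kicked = np.zeros(n, dtype=bool)
        for i, j in _contact_pairs(pos, radii, params.contact_tolerance):
            if params.cil_mode == "differential" and identities[i] is identities[j]:
                continue
            diff = pos[i] - pos[j]
            dist = float(np.linalg.norm(diff))
            if dist < 1e-9:
                angle = float(event_rng.uniform(0, 2 * math.pi))
                axis = np.array([math.cos(angle), math.sin(angle)])
            else:
                axis = diff / dist
            for cell, away in ((i, axis), (j, -axis)):
                turn = params.cil_turn(identities[cell])
                if turn == 0 or kicked[cell] or refractory[cell] > 0:
                    continue
                head[cell] = _rotate_toward(head[cell], away, turn)
                refractory[cell] = params.cil_persistence
                kicked[cell] = True

    # 3. co-attraction
    eps = params.coattraction_step
    if eps > 0 and n > 1:
        d = squareform(pdist(pos))
        np.fill_diagonal(d, np.inf)
        contact = radii[:, None] + radii[None, :] + params.coattraction_deadzone
        disp = np.zeros_like(pos)
        for i in range(n):
            in_range = (d[i] <= params.coattraction_range) & (d[i] > contact[i])
            if not in_range.any():
                continue
            direction = pos[in_range].mean(axis=0) - pos[i]
            norm = float(np.linalg.norm(direction))
            if norm > 1e-12:
                disp[i] = eps * params.dt * direction / norm
            beta = params.coattraction_steering[identities[i]]
            if beta > 0 and refractory[i] == 0:
                ahead = in_range & (pos[:, 1] > pos[i, 1])
                if ahead.any():
                    nearest = int(np.flatnonzero(ahead)[np.argmin(d[i][ahead])])
                    target = pos[nearest] - pos[i]
                elif identities[i] is Identity.FOLLOWER and norm > 1e-12:
                    target = direction
                else:
                    target = None
                if target is not None:
                    tnorm = float(np.linalg.norm(target))
                    if tnorm > 1e-12:
                        blend = (1 - beta) * head[i] + beta * target / tnorm
                        bnorm = float(np.linalg.norm(blend))
                        if bnorm > 1e-12:
                            head[i] = blend / bnorm
        pos = pos + disp

    # 4. volume exclusion
    if n > 1:
        pos = _resolve_exclusion(pos, radii, params.exclusion_tolerance, event_rng)

    # 5a. motility persistence: the heading relaxes toward the direction the
    # cell actually moved (motility + co-attraction + exclusion), so drift
    # toward the group feeds back into intrinsic motility and followers
    # chase the chain instead of diffusing.  Suppressed while a post-CIL
    # heading persists.
    disp = pos - pos_start
    norms = np.linalg.norm(disp, axis=1)
    for i in range(n):
        alpha = params.heading_alignment[identities[i]]
        if alpha <= 0 or refractory[i] > 0 or norms[i] < 1e-9:
            continue
        blend = (1 - alpha) * head[i] + alpha * disp[i] / norms[i]
        bnorm = float(np.linalg.norm(blend))
        if bnorm > 1e-12:
            head[i] = blend / bnorm

    # 5b. heading noise (suppressed during the post-CIL persistence window)
    if params.zeta > 0:
        free = refractory == 0
        angles = noise * free
        c, s = np.cos(angles), np.sin(angles)
        head = np.stack(
            [c * head[:, 0] - s * head[:, 1], s * head[:, 0] + c * head[:, 1]],
            axis=1,
        )
    refractory = np.maximum(refractory - 1, 0)

    # 6. boundary reflection
    pos, head = _reflect(pos, head, arena, radii)

    if not np.all(np.isfinite(pos)):
        raise NumericalError(f"non-finite position at step {step_index}")
    return pos, head, refractory


def step(
    agents: list[AgentState],
    params: ModelParams,
    arena: Arena,
    rng: np.random.Generator,
) -> list[AgentState]:
    """Advance every agent by one time step ``dt``.

    Noise angles for all agents are drawn from ``rng`` in agent order; the
    same generator supplies degenerate-contact repulsion axes.
    """
    pos = np.array([a.position for a in agents])
    head = np.array([a.heading for a in agents])
    refractory = np.array([a.cil_refractory for a in agents])
    speeds = np.array([a.speed for a in agents])
    radii = np.array([a.radius for a in agents])
    identities = [a.identity for a in agents]
    noise = rng.normal(0.0, params.zeta, len(agents)) if params.zeta > 0 else np.zeros(len(agents))
    pos, head, refractory = _step_arrays(
        pos, head, refractory, speeds, radii, identities, params, arena, noise, rng
    )
    return [
        replace(
            a,
            position=pos[k],
            heading=head[k],
            cil_refractory=int(refractory[k]),
        )
        for k, a in enumerate(agents)
    ]


def simulate(
    composition: Composition,
    arena: Arena | None = None,
    params: ModelParams | None = None,
    seed: int = 0,
) -> Trajectory:
    """Run one chain simulation and sample it every ``sample_every`` steps.

    Fully reproducible from ``(composition, arena, params, seed)``: noise
    uses one pre-drawn per-agent stream each, and discrete events share a
    dedicated derived stream.
    """
    arena = arena or Arena()
    params = params or ModelParams()
    agents = init_chain(composition, arena, params, seed)
    n = len(agents)
    pos = np.array([a.position for a in agents])
    head = np.array([a.heading for a in agents])
    refractory = np.zeros(n, dtype=int)
    speeds = np.array([a.speed for a in agents])
    radii = np.array([a.radius for a in agents])
    identities = [a.identity for a in agents]

    # per-agent noise substreams, pre-drawn for the whole run
    if params.zeta > 0:
        noise = np.stack(
            [
                derive_rng(seed, "agent-noise", k).normal(0.0, params.zeta, params.n_steps)
                for k in range(n)
            ],
            axis=1,
        )
    else:
        noise = np.zeros((params.n_steps, n))
    event_rng = derive_rng(seed, "events")

    n_frames = params.n_steps // params.sample_every + 1
    out = np.empty((n_frames, n, 2))
    out[0] = pos
    frame = 1
    for s in range(params.n_steps):
        pos, head, refractory = _step_arrays(
            pos, head, refractory, speeds, radii, identities, params, arena,
            noise[s], event_rng, step_index=s,
        )
        if (s + 1) % params.sample_every == 0 and frame < n_frames:
            out[frame] = pos
            frame += 1
    times = np.arange(n_frames) * params.dt * params.sample_every
    return Trajectory(
        positions=out[:frame],
        identities=tuple(identities),
        times=times[:frame],
        radii=radii,
        params=params,
        arena=arena,
        seed=seed,
    )
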