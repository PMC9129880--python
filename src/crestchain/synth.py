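"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the study's imaging-derived datasets so the whole
analysis runs without any download: biased-random-walk leader/follower
tracks sampled every 5 minutes, PCNA-like per-frame phase-state sequences,
Gaussian (and two-component mixture) cell-cycle phase-duration samples,
and asymmetric/symmetric division daughter-area pairs.  Defaults are the
published in-vivo summary statistics:

* phase durations (hours): leaders G1 3.2 +/- 0.6, S 8.7 +/- 1.3,
  G2 1.6 +/- 0.4, M 0.6 +/- 0.1; followers G2 1.5 +/- 0.3, M 0.5 +/- 0.1,
  with follower G1 and S drawn from two-component mixtures whose minor
  (leader-like) peaks carry 26% and 31% of cells and whose overall
  mean/SD reproduce the printed 7.4 +/- 2.7 and 4.6 +/- 2.8 hours;
* onset-in-S probabilities 0.79 (leaders) and 0.23 (followers, who start
  in G1 77% of the time);
* daughter areas (um^2): asymmetric 102 +/- 20 and 72 +/- 9, symmetric
  87 +/- 27.

All duration and area draws are Normal truncated at zero (the study
reports mean +/- SD only; near-zero mass is negligible at these
parameters).  Track contrasts (leaders faster, straighter, more ventrally
biased) are generator choices shaped to reproduce the in-vivo orderings,
not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cellcycle import PHASES, PhaseStateSequence
from .errors import ConfigurationError
from .metrics import TRACK_COLUMNS

__all__ = [
    "PhaseSpec",
    "MixtureSpec",
    "TrackSpec",
    "GeneratorConfig",
    "notch_inhibited_config",
    "gen_cellcycle",
    "gen_phase_sequences",
    "gen_tracks",
    "gen_division_areas",
]


@dataclass(frozen=True)
class PhaseSpec:
    mean: float  # hours
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigurationError("sd must be > 0")


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component duration mixture; the minor peak is leader-like."""

    minor_weight: float
    minor_mean: float
    minor_sd: float
    major_mean: float
    major_sd: float

    def __post_init__(self) -> None:
        if not (0 < self.minor_weight <= 0.5):
            raise ConfigurationError("minor_weight must be in (0, 0.5]")
        if self.minor_sd <= 0 or self.major_sd <= 0:
            raise ConfigurationError("sds must be > 0")


@dataclass(frozen=True)
class TrackSpec:
    speed_mean: float  # um/hr
    speed_sd: float
    ventral_bias: float  # in [0, 1]
    heading_noise: float  # >= 0
    bias_sd: float = 0.0  # cell-to-cell spread of the ventral bias

    def __post_init__(self) -> None:
        if not (0 <= self.ventral_bias <= 1):
            raise ConfigurationError("ventral_bias must be in [0, 1]")
        if self.heading_noise < 0 or self.speed_sd < 0 or self.bias_sd < 0:
            raise ConfigurationError("noise, speed_sd and bias_sd must be >= 0")


def _default_cellcycle() -> dict:
    # Follower G1 major mean 8.9 h makes 0.26*3.2 + 0.74*8.9 = 7.4 h; the
    # major SD 1.13 h makes the mixture SD = 2.7 h.  Follower S major mean
    # (4.6 - 0.31*8.7)/0.69 = 2.758 h preserves the printed mean; SDs give
    # a mixture SD close to the printed 2.8 h.
    return {
        "leader": {
            "G1": PhaseSpec(3.2, 0.6),
            "S": PhaseSpec(8.7, 1.3),
            "G2": PhaseSpec(1.6, 0.4),
            "M": PhaseSpec(0.6, 0.1),
        },
        "follower": {
            "G1": MixtureSpec(0.26, 3.2, 0.6, 8.9, 1.13),
            "S": MixtureSpec(0.31, 8.7, 0.6, 2.758, 0.51),
            "G2": PhaseSpec(1.5, 0.3),
            "M": PhaseSpec(0.5, 0.1),
        },
    }


@dataclass(frozen=True)
class GeneratorConfig:
    cellcycle: dict = field(default_factory=_default_cellcycle)
    onset_in_s: dict = field(
        default_factory=lambda: {"leader": 0.79, "follower": 0.23}
    )
    tracks: dict = field(
        default_factory=lambda: {
            "leader": TrackSpec(25.0, 5.0, 0.90, 0.5, bias_sd=0.08),
            "follower": TrackSpec(15.0, 5.0, 0.55, 0.7, bias_sd=0.18),
        }
    )
    areas: dict = field(
        default_factory=lambda: {
            "asym": {"leader": PhaseSpec(102.0, 20.0), "follower": PhaseSpec(72.0, 9.0)},
            "sym": PhaseSpec(87.0, 27.0),
        }
    )


def notch_inhibited_config() -> GeneratorConfig:
    """Generator emulating Notch-inhibited embryos.

    Followers lose their bimodal G1/S distributions: single components at
    the control means with the halved SDs (2.7 -> 1.42 h for G1,
    2.8 -> 1.38 h for S).  Former leaders adopt follower-like cycling.
    """
    cc = _default_cellcycle()
    follower = {
        "G1": PhaseSpec(7.4, 1.42),
        "S": PhaseSpec(4.6, 1.38),
        "G2": cc["follower"]["G2"],
        "M": cc["follower"]["M"],
    }
    cc["follower"] = follower
    cc["leader"] = dict(follower)
    return GeneratorConfig(cellcycle=cc)


def _trunc_normal(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def gen_cellcycle(
    identity: str,
    phase: str,
    n: int,
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw n phase durations (hours) for one identity and phase."""
    cfg = cfg or GeneratorConfig()
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    spec = cfg.cellcycle[identity][phase]
    rng = np.random.default_rng(seed)
    if isinstance(spec, MixtureSpec):
        minor = rng.random(n) < spec.minor_weight
        out = np.empty(n)
        n_minor = int(minor.sum())
        if n_minor:
            out[minor] = _trunc_normal(spec.minor_mean, spec.minor_sd, n_minor, rng)
        if n - n_minor:
            out[~minor] = _trunc_normal(spec.major_mean, spec.major_sd, n - n_minor, rng)
        return out
    return _trunc_normal(spec.mean, spec.sd, n, rng)


def _frames(duration_h: float, frame_interval: float) -> int:
    return max(1, round(duration_h * 60.0 / frame_interval))


def gen_phase_sequences(
    identity: str,
    n_cells: int,
    cfg: GeneratorConfig | None = None,
    frame_interval: float = 5.0,
    n_cycles: int = 1,
    seed: int = 0,
    left_censor: bool = False,
    with_onset: bool = False,
) -> list[PhaseStateSequence]:
    """Per-frame phase-label sequences with boundaries quantised to frames.

    Each cell's sequence is a leading M frame (so the first G1 run is
    bounded), ``n_cycles`` full G1-S-G2-M cycles with per-cycle durations
    drawn from the configured distributions, and a trailing G1 frame (so
    the last M run is bounded and two M-to-G1 transitions exist when
    n_cycles >= 2 is not required for the total: one cycle already spans
    two such transitions).  Optional left-censoring drops a random prefix;
    optional onset frames are placed in S or G1 per the configured
    onset-in-S probability.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    sequences = []
    for c in range(n_cells):
        labels: list[str] = ["M"]
        s_runs: list[tuple[int, int]] = []
        g1_runs: list[tuple[int, int]] = []
        for _ in range(n_cycles):
            for phase in PHASES:
                dur = float(
                    gen_cellcycle(
                        identity, phase, 1, cfg, seed=int(rng.integers(2**31))
                    )[0]
                )
                k = _frames(dur, frame_interval)
                start = len(labels)
                labels.extend([phase] * k)
                if phase == "S":
                    s_runs.append((start, start + k))
                elif phase == "G1":
                    g1_runs.append((start, start + k))
        labels.append("G1")

        onset = None
        if with_onset:
            p_s = cfg.onset_in_s[identity]
            runs = s_runs if rng.random() < p_s else g1_runs
            start, stop = runs[0]
            onset = int(rng.integers(start, stop))

        if left_censor:
            # drop up to half of the first G1 run; onset kept in range
            cut_max = max((g1_runs[0][1] - g1_runs[0][0]) // 2, 0)
            cut = int(rng.integers(0, cut_max + 1)) if cut_max else 0
            if onset is not None:
                cut = min(cut, onset)
            labels = labels[cut:]
            if onset is not None:
                onset -= cut

        sequences.append(
            PhaseStateSequence(
                cell_id=f"{identity}{c:03d}",
                identity=identity,
                labels=labels,
                frame_interval=frame_interval,
                onset_frame=onset,
            )
        )
    return sequences


def gen_tracks(
    n_leaders: int,
    n_followers: int,
    cfg: GeneratorConfig | None = None,
    n_frames: int = 192,
    frame_interval: float = 5.0,
    seed: int = 0,
    arena_width: float = 50.0,
) -> pd.DataFrame:
    """Biased-random-walk tracks at imaging cadence, as a tidy track table.

    Every cell starts at the dorsal edge (y = 0).  Per frame the heading
    is ``ventral_bias * (0, 1) + heading_noise * eta`` (eta standard
    normal, renormalised) and the step is the cell's speed times the frame
    interval.  Leaders are configured faster, straighter and more
    ventrally biased than followers.
    """
    cfg = cfg or GeneratorConfig()
    if n_leaders < 0 or n_followers < 0:
        raise ConfigurationError("cell counts must be >= 0")
    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames)
    t = frames * frame_interval
    tables = []
    cell_idx = 0
    for identity, count in (("leader", n_leaders), ("follower", n_followers)):
        spec: TrackSpec = cfg.tracks[identity]
        for _ in range(count):
            speed = (
                float(_trunc_normal(spec.speed_mean, spec.speed_sd, 1, rng)[0])
                if spec.speed_sd > 0
                else spec.speed_mean
            )
            bias = spec.ventral_bias
            if spec.bias_sd > 0:
                bias = float(
                    np.clip(rng.normal(spec.ventral_bias, spec.bias_sd), 0.0, 1.0)
                )
            step_len = speed * frame_interval / 60.0
            dirs = bias * np.array([0.0, 1.0]) + (
                spec.heading_noise * rng.standard_normal((n_frames - 1, 2))
                if spec.heading_noise > 0
                else 0.0
            )
            dirs = np.atleast_2d(dirs)
            if dirs.shape[0] == 1:
                dirs = np.repeat(dirs, n_frames - 1, axis=0)
            norms = np.linalg.norm(dirs, axis=1, keepdims=True)
            zero = norms[:, 0] < 1e-12
            if zero.any():
                angles = rng.uniform(0, 2 * np.pi, int(zero.sum()))
                dirs[zero] = np.stack([np.cos(angles), np.sin(angles)], axis=1)
                norms = np.linalg.norm(dirs, axis=1, keepdims=True)
            steps = step_len * dirs / norms
            start = np.array([rng.uniform(0, arena_width), 0.0])
            xy = np.vstack([start, start + np.cumsum(steps, axis=0)])
            tables.append(
                pd.DataFrame(
                    {
                        "cell_id": f"{identity[0].upper()}{cell_idx:03d}",
                        "identity": identity,
                        "frame": frames,
                        "t_min": t,
                        "x_um": xy[:, 0],
                        "y_um": xy[:, 1],
                        "z_um": 0.0,
                    }
                )
            )
            cell_idx += 1
    if not tables:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(tables, ignore_index=True)[TRACK_COLUMNS]


def gen_division_areas(
    kind: str,
    n_pairs: int,
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired daughter-cell areas (um^2) for one division mode.

    ``asym``: the larger daughter (future leader) and smaller sibling
    (future follower) are drawn from their respective distributions;
    ``sym``: both daughters from the common follower-pair distribution.
    """
    cfg = cfg or GeneratorConfig()
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    if kind == "asym":
        a_spec = cfg.areas["asym"]["leader"]
        b_spec = cfg.areas["asym"]["follower"]
    elif kind == "sym":
        a_spec = b_spec = cfg.areas["sym"]
    else:
        raise ConfigurationError("kind must be 'asym' or 'sym'")
    a = _trunc_normal(a_spec.mean, a_spec.sd, n_pairs, rng)
    b = _trunc_normal(b_spec.mean, b_spec.sd, n_pairs, rng)
    return pd.DataFrame(
        {
            "pair_id": np.arange(n_pairs),
            "kind": kind,
            "daughter_a_um2": a,
            "daughter_b_um2": b,
        }
    )
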