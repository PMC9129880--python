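"""Cell-cycle quantification from per-frame phase-state sequences.

Live reporters (PCNA-GFP nuclear patterns, FUCCI colours) yield, per cell,
an ordered sequence of phase labels (G1, S, G2, M, with unknown gaps) at a
fixed frame interval.  This module extracts phase durations and total cycle
length, classifies the phase at migration onset into the two FUCCI colour
classes, fits one- vs two-component Gaussian mixtures to duration samples
(bimodality of the follower population), and applies the normality-gated
test-selection procedure used for all group comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .errors import InsufficientSampleError, ValidationError

__all__ = [
    "PHASES",
    "PhaseStateSequence",
    "PhaseDurations",
    "MixtureFit",
    "durations_from_states",
    "onset_phase",
    "fit_mixture",
    "auto_compare",
    "dispersion_ratio",
]

PHASES = ("G1", "S", "G2", "M")
_NEXT = {"G1": "S", "S": "G2", "G2": "M", "M": "G1"}
UNKNOWN = "unknown"


@dataclass
class PhaseStateSequence:
    """Per-frame phase labels for one cell."""

    cell_id: str
    identity: str
    labels: list[str]
    frame_interval: float = 5.0  # minutes
    onset_frame: int | None = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        valid = set(PHASES) | {UNKNOWN}
        for t, lab in enumerate(self.labels):
            if lab not in valid:
                raise ValidationError(f"unknown phase label {lab!r} at frame {t}")
        self._check_cyclic_order()

    def _check_cyclic_order(self) -> None:
        """Adjacent known labels must be the same phase or its successor;
        across unknown gaps any forward progression is accepted."""
        prev = None
        prev_t = None
        for t, lab in enumerate(self.labels):
            if lab == UNKNOWN:
                continue
            if prev is not None and prev_t == t - 1:
                if lab != prev and lab != _NEXT[prev]:
                    raise ValidationError(
                        f"labels violate cyclic phase order at frame {t}: "
                        f"{prev} -> {lab}"
                    )
            prev, prev_t = lab, t


@dataclass
class PhaseDurations:
    """Fully observed phase durations (hours) for one cell.

    A phase run counts only when bounded on both sides by a different
    known phase; partially observed runs are censored (excluded).  The
    total cycle length is the time between two M-to-G1 transitions, when
    two are observed.
    """

    cell_id: str
    identity: str
    durations: dict[str, float] = field(default_factory=dict)  # phase -> hours
    total: float | None = None


def _runs(labels: list[str]) -> list[tuple[str, int, int]]:
    """Maximal runs of identical labels as (label, start, stop-exclusive)."""
    runs = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            runs.append((labels[start], start, t))
            start = t
    return runs


def durations_from_states(seq: PhaseStateSequence) -> PhaseDurations:
    """Extract phase durations and total cycle length from one sequence.

    Duration of a run = (number of its frames) x frame_interval.  The
    first fully observed run of each phase is reported.
    """
    runs = _runs(seq.labels)
    hours_per_frame = seq.frame_interval / 60.0
    out = PhaseDurations(cell_id=seq.cell_id, identity=seq.identity)
    for k, (lab, start, stop) in enumerate(runs):
        if lab == UNKNOWN or lab in out.durations:
            continue
        left_ok = k > 0 and runs[k - 1][0] != UNKNOWN and runs[k - 1][0] != lab
        right_ok = (
            k < len(runs) - 1
            and runs[k + 1][0] != UNKNOWN
            and runs[k + 1][0] != lab
        )
        if left_ok and right_ok:
            out.durations[lab] = (stop - start) * hours_per_frame

    # M -> G1 transitions between adjacent known runs
    transitions = [
        runs[k + 1][1]
        for k in range(len(runs) - 1)
        if runs[k][0] == "M" and runs[k + 1][0] == "G1"
    ]
    if len(transitions) >= 2:
        out.total = (transitions[1] - transitions[0]) * hours_per_frame
    return out


def onset_phase(seq: PhaseStateSequence, onset_frame: int | None = None) -> str:
    """Two-colour FUCCI class of the phase at migration onset.

    Returns ``"G1"`` or ``"S_or_G2"`` (M is grouped with S/G2, matching
    the geminin reporter staying on through mitosis), or
    ``"unclassifiable"`` when the label at onset is unknown.
    """
    frame = onset_frame if onset_frame is not None else seq.onset_frame
    if frame is None:
        raise ValidationError("no onset frame given")
    if not (0 <= frame < len(seq.labels)):
        raise ValidationError(
            f"onset frame {frame} outside sequence of {len(seq.labels)} frames"
        )
    lab = seq.labels[frame]
    if lab == UNKNOWN:
        return "unclassifiable"
    return "G1" if lab == "G1" else "S_or_G2"


@dataclass
class MixtureFit:
    """Gaussian mixture fit to a duration sample with BIC model selection."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bic: dict[int, float]
    minor_weight: float | None  # smaller component weight when k = 2


def fit_mixture(
    durations, kmax: int = 2, seed: int = 0, variance_floor: float = 1e-3
) -> MixtureFit:
    """Fit Gaussian mixtures for k = 1..kmax and select k by BIC.

    EM with 10 seeded restarts; ``variance_floor`` (h^2) guards against
    degenerate components.  Components are reported in increasing-mean
    order; ``minor_weight`` is the smaller weight of a two-component fit.
    """
    x = np.asarray(durations, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise InsufficientSampleError("mixture fitting needs n >= 10")
    fits, bic = {}, {}
    for k in range(1, kmax + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=10,
            reg_covar=variance_floor,
            random_state=seed,
            max_iter=500,
        )
        gm.fit(x)
        fits[k] = gm
        bic[k] = float(gm.bic(x))
    best = min(bic, key=lambda k: (bic[k], k))
    gm = fits[best]
    order = np.argsort(gm.means_.ravel())
    weights = gm.weights_[order]
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.reshape(best)[order])
    minor = float(weights.min()) if best == 2 else None
    return MixtureFit(
        k=best, weights=weights, means=means, sds=sds, bic=bic, minor_weight=minor
    )


def _is_normal(sample: np.ndarray, alpha: float) -> bool:
    """Normality gate: d'Agostino-Pearson followed by Shapiro-Wilk.

    The omnibus test requires n >= 8 (its skewness component is undefined
    below that); smaller samples are gated on Shapiro-Wilk alone.
    """
    if len(sample) >= 8:
        if stats.normaltest(sample).pvalue <= alpha:
            return False
    return stats.shapiro(sample).pvalue > alpha


def auto_compare(*samples, alpha: float = 0.05, welch_anova: bool = False) -> dict:
    """Group comparison with the normality-gated test choice.

    Every sample is tested for normality (d'Agostino-Pearson, then
    Shapiro-Wilk, at ``alpha``).  If all pass: unpaired two-tailed t-test
    (two groups) or one-way ANOVA (more).  Otherwise: Mann-Whitney U (two
    groups) or Kruskal-Wallis (more; Welch's ANOVA on request via
    ``welch_anova``).  Returns the branch that fired with its statistic
    and p-value.
    """
    if len(samples) == 1 and isinstance(samples[0], (list, tuple)) and not np.isscalar(
        samples[0][0]
    ):
        samples = tuple(samples[0])
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2:
        raise ValidationError("need at least two samples")
    for g in groups:
        if len(g) < 3:
            raise InsufficientSampleError("each sample needs n >= 3")
    normal = all(_is_normal(g, alpha) for g in groups)
    if len(groups) == 2:
        if normal:
            res = stats.ttest_ind(groups[0], groups[1])
            name = "t-test"
        else:
            res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            name = "mann-whitney"
    else:
        if normal:
            res = stats.f_oneway(*groups)
            name = "anova"
        elif welch_anova:
            # Welch's heteroscedastic ANOVA
            k = len(groups)
            ns = np.array([len(g) for g in groups], dtype=float)
            means = np.array([g.mean() for g in groups])
            vs = np.array([g.var(ddof=1) for g in groups])
            w = ns / vs
            mw = float((w * means).sum() / w.sum())
            lam = 3.0 / (k**2 - 1) * float(
                ((1 - w / w.sum()) ** 2 / (ns - 1)).sum()
            )
            f = float(
                ((w * (means - mw) ** 2).sum() / (k - 1))
                / (1 + 2 * lam * (k - 2) / 3)
            )
            p = float(stats.f.sf(f, k - 1, 1.0 / lam))
            return {
                "test_name": "welch-anova",
                "statistic": f,
                "p": p,
                "normal": False,
                "n": [len(g) for g in groups],
            }
        else:
            res = stats.kruskal(*groups)
            name = "kruskal-wallis"
    return {
        "test_name": name,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "normal": bool(normal),
        "n": [len(g) for g in groups],
    }


def dispersion_ratio(sd_before: float, sd_after: float) -> float:
    """Ratio of standard deviations after/before a perturbation."""
    if sd_before <= 0 or sd_after <= 0:
        raise ValueError("standard deviations must be > 0")
    return sd_after / sd_before
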