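"""Fisher linear discriminant analysis of migratory identity.

Separates leaders from followers on a feature table (in vivo: ventral
distance, mean speed, directionality; in silico: the model parameter
levels) and ranks which features carry the separation.  With two classes
there is a single discriminant axis and the solution has the closed form

    w  ∝  Σ_w^{-1} (μ_leader − μ_follower)

with Σ_w the pooled within-class covariance (ridge-regularised for the
small samples typical of tracking data).  Because the features mix
heterogeneous units (um, um/hr, dimensionless), importance is defined on
coefficients of z-scored features; raw-scale coefficients are reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["LDAModel", "fit_lda", "rank_features", "random_control", "separation_statistic"]


@dataclass
class LDAModel:
    features: list[str]
    classes: list[str]
    coef_raw: np.ndarray  # discriminant direction on original feature scale
    coef_standardized: np.ndarray  # direction on z-scored features
    class_means: pd.DataFrame
    projections: np.ndarray  # rows projected on the standardized axis
    labels: np.ndarray
    separation: float  # between/within scatter ratio along the axis

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "coef_raw": self.coef_raw,
                "coef_standardized": self.coef_standardized,
            }
        )


def _validate_table(table: pd.DataFrame, label_col: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if label_col not in table.columns:
        raise ValidationError(f"label column {label_col!r} missing")
    features = [c for c in table.columns if c != label_col]
    if not features:
        raise ValidationError("need at least one feature column")
    X = table[features].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("feature table contains missing values")
    y = table[label_col].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError(f"exactly two classes required, got {list(classes)}")
    if counts.min() < 2:
        raise ValidationError("need at least two rows per class")
    return X, y, features


def _fisher_direction(X: np.ndarray, y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    n, p = X.shape
    mus = [X[y == c].mean(axis=0) for c in classes]
    Sw = np.zeros((p, p))
    for c, mu in zip(classes, mus):
        d = X[y == c] - mu
        Sw += d.T @ d
    Sw /= max(n - 2, 1)
    ridge = 1e-6 * np.trace(Sw) / p
    Sw_reg = Sw + max(ridge, 1e-12) * np.eye(p)
    try:
        w = np.linalg.solve(Sw_reg, mus[0] - mus[1])
    except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge prevents this
        corr = np.corrcoef(X, rowvar=False)
        collinear = [
            i for i in range(p) if np.any(np.abs(np.delete(corr[i], i)) > 0.999)
        ]
        raise ValidationError(
            f"within-class scatter singular; collinear features at {collinear}"
        ) from exc
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def fit_lda(table: pd.DataFrame, label_col: str = "identity") -> LDAModel:
    """Fit a two-class Fisher discriminant to a feature table.

    Features are z-scored before fitting; the raw-scale direction is
    recovered by dividing by the feature SDs.  The axis is oriented so the
    first class (alphabetically) projects positive on average.
    """
    X, y, features = _validate_table(table, label_col)
    classes = np.unique(y)
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd_safe
    w_std = _fisher_direction(Z, y, classes)
    # orient the axis so the leader class (else the first class) projects
    # positive on average
    ref = "leader" if "leader" in classes else classes[0]
    proj = Z @ w_std
    if proj[y == ref].mean() < 0:
        w_std = -w_std
        proj = -proj
    w_raw = w_std / sd_safe
    w_raw_norm = np.linalg.norm(w_raw)
    if w_raw_norm > 0:
        w_raw = w_raw / w_raw_norm

    # Fisher criterion value along the fitted axis
    m0, m1 = proj[y == classes[0]].mean(), proj[y == classes[1]].mean()
    within = sum(proj[y == c].var(ddof=1) * (np.sum(y == c) - 1) for c in classes)
    within /= max(len(y) - 2, 1)
    separation = float((m0 - m1) ** 2 / within) if within > 0 else float("inf")

    class_means = pd.DataFrame(
        [X[y == c].mean(axis=0) for c in classes], index=classes, columns=features
    )
    return LDAModel(
        features=features,
        classes=[str(c) for c in classes],
        coef_raw=w_raw,
        coef_standardized=w_std,
        class_means=class_means,
        projections=proj,
        labels=y,
        separation=separation,
    )


def rank_features(model: LDAModel) -> list[str]:
    """Features sorted by |standardized coefficient|, ties alphabetical."""
    order = sorted(
        range(len(model.features)),
        key=lambda i: (-abs(model.coef_standardized[i]), model.features[i]),
    )
    return [model.features[i] for i in order]


def separation_statistic(table: pd.DataFrame, label_col: str = "identity") -> float:
    """Between/within scatter ratio of the fitted discriminant axis."""
    return fit_lda(table, label_col).separation


def random_control(
    table: pd.DataFrame, seed: int, label_col: str = "identity"
) -> pd.DataFrame:
    """Random dataset control: i.i.d. standard-normal features, labels kept.

    Preserves the shape, column names and label proportions of ``table``
    so a fit on the control shows what the coefficients look like in the
    absence of any class structure.
    """
    rng = np.random.default_rng(seed)
    features = [c for c in table.columns if c != label_col]
    out = pd.DataFrame(
        rng.standard_normal((len(table), len(features))), columns=features
    )
    out[label_col] = table[label_col].to_numpy()
    return out[list(table.columns)]
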