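"""Three-class intensity classification and DAB positive-particle counting.

The intensity classifier is deliberately simple and auditable: the training
pool's mean μ and sample SD σ (n−1 denominator) define thresholds μ±σ; a cell
is **low** if its intensity is strictly below μ−σ, **high** if strictly above
μ+σ, **medium** otherwise. Boundary values are medium — the verbal class
definitions ("one SD or less below" / "one SD or more above") overlap at the
boundaries, and strict inequalities for low/high make the rule total and
deterministic; the degenerate σ=0 case then classifies everything medium.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.linear_model import LogisticRegression

from .detect import CellTable

CLASS_NAMES = ("low", "medium", "high")


class DegenerateClassifierWarning(UserWarning):
    pass


@dataclass
class IntensityClassifier:
    """Mean±SD three-class thresholds for one channel/compartment."""

    channel: str
    compartment: str
    mu: float
    sd: float
    n_train: int
    sd_denominator: str = "n-1"

    @property
    def t_low(self) -> float:
        return self.mu - self.sd

    @property
    def t_high(self) -> float:
        return self.mu + self.sd

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0

    def predict(self, intensities) -> np.ndarray:
        """Class label per intensity; boundaries (exactly μ±σ) are medium,
        and a degenerate classifier (σ=0) labels everything medium."""
        x = np.asarray(intensities, dtype=float)
        out = np.full(x.shape, "medium", dtype=object)
        if not self.degenerate:
            out[x < self.t_low] = "low"
            out[x > self.t_high] = "high"
        return out.astype(str)

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "channel": self.channel,
            "compartment": self.compartment,
            "mu": self.mu,
            "sd": self.sd,
            "t_low": self.t_low,
            "t_high": self.t_high,
            "n_train": self.n_train,
            "sd_denominator": self.sd_denominator,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=1))
        return payload

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "IntensityClassifier":
        if not isinstance(source, dict):
            source = json.loads(Path(source).read_text())
        return cls(
            channel=source["channel"],
            compartment=source["compartment"],
            mu=float(source["mu"]),
            sd=float(source["sd"]),
            n_train=int(source["n_train"]),
            sd_denominator=source.get("sd_denominator", "n-1"),
        )


def _resolve_intensities(
    cells, channel: str, compartment: str, corrected: bool
) -> np.ndarray:
    if isinstance(cells, CellTable):
        df = cells.df
    elif isinstance(cells, pd.DataFrame):
        df = cells
    else:  # plain array-like of intensities
        return np.asarray(cells, dtype=float)
    col = f"{channel}_corrected" if corrected else f"{channel}_{compartment}"
    if col not in df.columns:
        raise ValueError(f"missing intensity column {col!r}")
    return df[col].to_numpy(dtype=float)


def fit_intensity_classifier(
    cells,
    channel: str = "signal",
    compartment: str = "nuclear",
    corrected: bool = False,
) -> IntensityClassifier:
    """Fit μ (arithmetic mean of the per-cell intensities), σ (sample SD,
    n−1 denominator) and the μ±σ thresholds on the training pool.

    ``cells`` may be a :class:`CellTable`, a DataFrame, or a bare array of
    intensities. Requires ≥2 finite values; zero variance yields σ=0 with a
    degenerate-classifier warning.
    """
    values = _resolve_intensities(cells, channel, compartment, corrected)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValueError("need at least 2 cells with finite intensities")
    mu = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        warnings.warn(
            "zero-variance training pool: degenerate classifier (all medium)",
            DegenerateClassifierWarning,
            stacklevel=2,
        )
    return IntensityClassifier(
        channel=channel,
        compartment=compartment,
        mu=mu,
        sd=sd,
        n_train=int(len(values)),
    )


def classify_cells(
    classifier: IntensityClassifier,
    cells,
    corrected: bool = False,
    allow_degenerate: bool = True,
) -> "CellTable | pd.DataFrame | np.ndarray":
    """Assign low/medium/high labels. For a CellTable/DataFrame the ``class``
    column is set in place and the container returned; for a bare array the
    label array is returned."""
    if classifier.degenerate and not allow_degenerate:
        raise ValueError("degenerate classifier (sd=0) and override not allowed")
    values = _resolve_intensities(
        cells, classifier.channel, classifier.compartment, corrected
    )
    labels = classifier.predict(values)
    if isinstance(cells, CellTable):
        cells.df["class"] = labels
        return cells
    if isinstance(cells, pd.DataFrame):
        cells["class"] = labels
        return cells
    return labels


# ---------------------------------------------------------------------------
# pixel classification (DAB)


@dataclass
class PixelClassifier:
    """Probabilistic pixel classifier on multi-scale features.

    Features per pixel: the image smoothed at each scale plus the Gaussian
    gradient magnitude at each scale. The decision model is a transparent
    L2-regularized logistic regression; the probability cutoff (default 0.5)
    binarizes the probability map.
    """

    scales: tuple[float, ...] = (1.0, 2.0, 4.0)
    cutoff: float = 0.5
    model: LogisticRegression | None = None
    feature_means: np.ndarray | None = None
    feature_stds: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.scales) < 1:
            raise ValueError("need at least one feature scale")
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must be in (0, 1)")

    @property
    def trained(self) -> bool:
        return self.model is not None

    def features(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float)
        feats = []
        for s in self.scales:
            feats.append(ndi.gaussian_filter(img, s))
            feats.append(ndi.gaussian_gradient_magnitude(img, s))
        return np.stack([f.ravel() for f in feats], axis=1)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise ValueError("pixel classifier is untrained")
        X = (self.features(image) - self.feature_means) / self.feature_stds
        p = self.model.predict_proba(X)[:, 1]
        return p.reshape(np.asarray(image).shape)

    def summary(self) -> dict:
        out = {"scales": list(self.scales), "cutoff": self.cutoff}
        if self.trained:
            out["weights"] = self.model.coef_.ravel().tolist()
            out["intercept"] = float(self.model.intercept_[0])
        return out


def train_pixel_classifier(
    images: list[np.ndarray],
    label_masks: list[dict[str, np.ndarray]],
    scales: tuple[float, ...] = (1.0, 2.0, 4.0),
    cutoff: float = 0.5,
) -> PixelClassifier:
    """Train on sparse pixel annotations from one or more images.

    ``label_masks[i]`` holds boolean masks ``{"positive": ..., "negative":
    ...}`` over ``images[i]``. Both classes must be annotated somewhere.
    Training is deterministic for fixed inputs.
    """
    if len(images) < 1 or len(images) != len(label_masks):
        raise ValueError("need >= 1 image with a matching annotation dict")
    clf = PixelClassifier(scales=tuple(scales), cutoff=cutoff)
    X_parts, y_parts = [], []
    for img, masks in zip(images, label_masks):
        feats = clf.features(img)
        pos = np.asarray(masks["positive"], dtype=bool).ravel()
        neg = np.asarray(masks["negative"], dtype=bool).ravel()
        X_parts.append(feats[pos])
        y_parts.append(np.ones(pos.sum(), dtype=int))
        X_parts.append(feats[neg])
        y_parts.append(np.zeros(neg.sum(), dtype=int))
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if len(np.unique(y)) < 2:
        raise ValueError("annotations must include both positive and negative pixels")
    clf.feature_means = X.mean(axis=0)
    clf.feature_stds = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    Xs = (X - clf.feature_means) / clf.feature_stds
    model = LogisticRegression(C=10.0, tol=1e-10, max_iter=5000)
    model.fit(Xs, y)
    clf.model = model
    return clf


def count_positive_particles(
    image: np.ndarray,
    model: PixelClassifier,
    min_size_px: int = 5,
) -> tuple[int, list[int]]:
    """Count immunopositive particles: probability map → binarize at the
    cutoff → 8-connected components → keep areas strictly greater than
    ``min_size_px`` (the default 5 px means a 6-px particle counts, a 5-px
    one does not). Returns (count, kept particle areas)."""
    if not model.trained:
        raise ValueError("pixel classifier is untrained")
    prob = model.predict_proba(image)
    binary = prob >= model.cutoff
    labels, n = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0, []
    areas = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    kept = sorted(int(a) for a in areas if a > min_size_px)
    return len(kept), kept
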