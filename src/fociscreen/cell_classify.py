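"""Three-class single-cell phenotype classification.

Cells are sorted into ``foci_positive`` (green reporter expressed, damage
foci present), ``foci_negative`` (reporter expressed, diffuse green only)
and ``non_signaling`` (no detectable reporter).  Separating non-signaling
cells matters because they would otherwise be mistaken for healthy diffuse
cells and bias the %-foci-positive readout; they are excluded from its
denominator downstream.

Two trainable backends share one estimator contract:

* ``feature_baseline`` (default) — multinomial logistic regression on a
  fixed, documented feature vector (:func:`featurize`).  Deterministic,
  trains in seconds.
* ``conv_small`` — a small convolutional network implemented in numpy
  (im2col convolution, ReLU, max-pool, dense softmax head, Adam), trainable
  on one CPU in minutes.

Ground-truth labels come from :func:`label_truth`: zero expression gain is
non-signaling; otherwise a cell is foci-positive iff its true foci count
reaches the (configurable) positivity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import kurtosis
from skimage.morphology import disk, opening, white_tophat
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from fociscreen.foci_quant import FociDetector
from fociscreen.segmentation import CellCrop

__all__ = [
    "CLASSES",
    "FEATURE_NAMES",
    "label_truth",
    "featurize",
    "CellClassifier",
    "CellRecord",
    "TrainingSet",
    "train_classifier",
    "classify",
    "evaluate",
]

#: Fixed class order; also the tie-break order on equal probabilities
#: (argmax returns the first maximum).
CLASSES = ("non_signaling", "foci_negative", "foci_positive")

#: Default true-foci count at or above which an expressing cell is labeled
#: foci-positive.  A free modeling choice, surfaced in config and recorded
#: in provenance wherever metrics are reported.
DEFAULT_POSITIVITY_THRESHOLD = 5


def label_truth(
    expression_gain: float,
    foci_count: int,
    positivity_threshold: int = DEFAULT_POSITIVITY_THRESHOLD,
) -> str:
    """Deterministic truth labeling rule for generated cells."""
    if positivity_threshold < 0:
        raise ValueError("positivity_threshold must be >= 0")
    if foci_count < 0:
        raise ValueError("foci_count must be >= 0")
    if expression_gain == 0:
        return "non_signaling"
    return "foci_positive" if foci_count >= positivity_threshold else "foci_negative"


#: Documented fixed feature order of :func:`featurize`.
FEATURE_NAMES = (
    "raw_green_mean",
    "anchor_spread",
    "norm_variance",
    "norm_kurtosis",
    "tophat_energy",
    "foci_count",
    "foci_prominence_sum",
    "granularity_r1",
    "granularity_r2",
    "granularity_r4",
    "mask_area",
)

_GRANULARITY_RADII = (1, 2, 4)


def featurize(crop: CellCrop, detector: FociDetector | None = None) -> np.ndarray:
    """Fixed-order feature vector for one normalized crop.

    Signal presence is carried by the *raw* green mean and the raw anchor
    spread (normalization-invariant shape features cannot see it); shape is
    carried by intranuclear variance/kurtosis of the normalized channel,
    top-hat energy, threshold-backend foci count and summed prominence, and
    a 3-scale granularity spectrum (fraction of masked intensity removed by
    openings of increasing radius).  Deterministic.
    """
    if crop.green_norm is None:
        raise ValueError("crop must be normalized (anchors retained) first")
    if crop.mask is None or not crop.mask.any():
        raise ValueError("crop nucleus mask missing or empty")
    det = detector or FociDetector()
    mask = crop.mask
    norm = crop.green_norm
    inside = norm[mask]
    var = float(inside.var())
    kurt = float(kurtosis(inside, fisher=True, bias=True))
    if not np.isfinite(kurt):
        kurt = 0.0
    inside_med = float(np.median(inside))
    work = np.where(mask, norm, inside_med)
    th = white_tophat(work, footprint=disk(det._validate()))
    tophat_energy = float(th[mask].sum())
    detection = det.detect(crop)
    foci_count = float(detection.foci_count)
    prom = float(sum(f.prominence for f in detection.foci))
    total = float(work[mask].sum()) + 1e-9
    gran = []
    prev = work
    for r in _GRANULARITY_RADII:
        opened = opening(work, footprint=disk(r))
        gran.append(float((prev[mask] - opened[mask]).sum()) / total)
        prev = opened
    return np.array(
        [
            crop.raw_green_mean,
            crop.p_high_value - crop.p_low_value,
            var,
            kurt,
            tophat_energy,
            foci_count,
            prom,
            *gran,
            float(mask.sum()),
        ],
        dtype=np.float64,
    )


@dataclass
class CellRecord:
    """Per-cell classification output."""

    plate: str
    well: str
    field: int
    cell_id: int
    predicted_class: str
    probabilities: tuple[float, float, float]  # CLASSES order
    raw_green_mean: float
    foci_count: int | None = None


@dataclass
class TrainingSet:
    """Labeled crops with disjoint split tags and labeling provenance."""

    crops: list[CellCrop]
    labels: list[str]
    split: list[str]  # "train" | "val" | "test" per crop
    provenance: dict = dc_field(default_factory=dict)

    def subset(self, tag: str) -> tuple[list[CellCrop], list[str]]:
        idx = [i for i, s in enumerate(self.split) if s == tag]
        return [self.crops[i] for i in idx], [self.labels[i] for i in idx]


# ---------------------------------------------------------------------------
# conv_small: a compact convolutional network in numpy
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(n, h, w, c) -> (n, h-k+1, w-k+1, k*k*c) patch matrix (valid conv)."""
    n, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    s = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, k, k, c), strides=(s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return patches.reshape(n, oh, ow, k * k * c)


class _ConvSmallNet:
    """conv(8@5x5) + ReLU + maxpool(4) + dense(32) + ReLU + softmax(3).

    Input: 32x32x3 tensors (mean-pooled normalized green, nucleus mask and a
    constant raw-brightness plane).  Trained with Adam on weighted
    cross-entropy.
    """

    def __init__(self, rng: np.random.Generator, n_filters=8, ksize=5, hidden=32):
        self.k = ksize
        self.n_filters = n_filters
        c_in = 3
        fan1 = ksize * ksize * c_in
        self.W1 = rng.normal(0, np.sqrt(2.0 / fan1), size=(fan1, n_filters))
        self.b1 = np.zeros(n_filters)
        self.pool = 4
        side = (32 - ksize + 1) // self.pool  # 7
        flat = side * side * n_filters
        self.W2 = rng.normal(0, np.sqrt(2.0 / flat), size=(flat, hidden))
        self.b2 = np.zeros(hidden)
        self.W3 = rng.normal(0, np.sqrt(2.0 / hidden), size=(hidden, 3))
        self.b3 = np.zeros(3)
        self._adam = {}
        self._t = 0

    def _forward(self, x: np.ndarray, cache: bool = False):
        cols = _im2col(x, self.k)  # (n, oh, ow, fan)
        conv = cols @ self.W1 + self.b1  # (n, oh, ow, f)
        relu1 = np.maximum(conv, 0.0)
        n, oh, ow, f = relu1.shape
        p = self.pool
        ph, pw = oh // p, ow // p
        # window-major layout (n, ph, pw, p*p, f) so the pool is one argmax
        windows = (
            relu1[:, : ph * p, : pw * p, :]
            .reshape(n, ph, p, pw, p, f)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, ph, pw, p * p, f)
        )
        pooled = windows.max(axis=3)  # (n, ph, pw, f)
        flat = pooled.reshape(n, -1)
        z2 = flat @ self.W2 + self.b2
        relu2 = np.maximum(z2, 0.0)
        logits = relu2 @ self.W3 + self.b3
        logits -= logits.max(axis=1, keepdims=True)
        ez = np.exp(logits)
        probs = ez / ez.sum(axis=1, keepdims=True)
        if not cache:
            return probs
        return probs, (cols, conv, windows, pooled, flat, z2, relu2)

    def _backward(self, x, y_onehot, weights):
        probs, (cols, conv, windows, pooled, flat, z2, relu2) = self._forward(
            x, cache=True
        )
        n, oh, ow, f = conv.shape
        p = self.pool
        ph, pw = oh // p, ow // p
        wsum = weights.sum() + 1e-12
        dlogits = (probs - y_onehot) * weights[:, None] / wsum
        gW3 = relu2.T @ dlogits
        gb3 = dlogits.sum(axis=0)
        dz2 = (dlogits @ self.W3.T) * (z2 > 0)
        gW2 = flat.T @ dz2
        gb2 = dz2.sum(axis=0)
        dpooled = (dz2 @ self.W2.T).reshape(pooled.shape)
        # route the max-pool gradient to each window's argmax position
        amax = windows.argmax(axis=3)  # (n, ph, pw, f)
        dwindows = np.zeros_like(windows)
        np.put_along_axis(
            dwindows, amax[:, :, :, None, :], dpooled[:, :, :, None, :], axis=3
        )
        drelu1 = np.zeros_like(conv)
        drelu1[:, : ph * p, : pw * p, :] = (
            dwindows.reshape(n, ph, pw, p, p, f)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, ph * p, pw * p, f)
        )
        dconv = drelu1 * (conv > 0)
        gW1 = cols.reshape(-1, cols.shape[-1]).T @ dconv.reshape(-1, self.n_filters)
        gb1 = dconv.sum(axis=(0, 1, 2))
        return {
            "W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2, "W3": gW3, "b3": gb3,
        }

    def _step(self, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        for name, g in grads.items():
            m, v = self._adam.get(name, (np.zeros_like(g), np.zeros_like(g)))
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g * g
            self._adam[name] = (m, v)
            mhat = m / (1 - beta1**self._t)
            vhat = v / (1 - beta2**self._t)
            setattr(
                self, name, getattr(self, name) - lr * mhat / (np.sqrt(vhat) + eps)
            )

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        out = [self._forward(x[i : i + batch]) for i in range(0, len(x), batch)]
        return np.vstack(out) if out else np.zeros((0, 3))


def _conv_inputs(crops: list[CellCrop]) -> np.ndarray:
    """Stack crops into (n, 32, 32, 3) tensors: 2x2 mean-pooled normalized
    green, nucleus mask and a constant squashed raw-brightness plane."""
    xs = []
    for crop in crops:
        if crop.green_norm is None:
            raise ValueError("crops must be normalized")
        g = crop.green_norm
        m = crop.mask.astype(np.float64)
        h, w = g.shape
        if h != 64 or w != 64:
            raise ValueError(
                f"conv_small expects 64x64 crops, got {h}x{w}"
            )
        g2 = g.reshape(32, 2, 32, 2).mean(axis=(1, 3))
        m2 = m.reshape(32, 2, 32, 2).mean(axis=(1, 3))
        bright = np.full((32, 32), np.tanh(crop.raw_green_mean / 500.0))
        xs.append(np.stack([g2, m2, bright], axis=-1))
    return np.asarray(xs) if xs else np.zeros((0, 32, 32, 3))


class CellClassifier(ClassifierMixin, BaseEstimator):
    """Three-class single-cell classifier with exchangeable backends.

    ``fit(crops, y)`` takes normalized :class:`CellCrop` objects and string
    labels from :data:`CLASSES`.  ``predict_proba`` returns probability
    triples in fixed :data:`CLASSES` order (rows sum to 1); ``predict``
    takes the argmax, which on exact ties resolves in that same order
    (non_signaling < foci_negative < foci_positive).

    Class imbalance is handled by weights inversely proportional to class
    support (non-signaling cells may be rare).
    """

    def __init__(
        self,
        backend: str = "feature_baseline",
        C: float = 1.0,
        max_iter: int = 2000,
        epochs: int = 8,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ) -> None:
        self.backend = backend
        self.C = C
        self.max_iter = max_iter
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _check_labels(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=object)
        counts = {c: int((y == c).sum()) for c in CLASSES}
        missing = [c for c, n in counts.items() if n == 0]
        if missing:
            raise ValueError(
                f"classes absent from the training split: {missing}; class counts {counts}"
            )
        bad = set(y) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        return y

    def fit(self, crops: list[CellCrop], y) -> "CellClassifier":
        if self.backend not in ("feature_baseline", "conv_small"):
            raise ValueError(f"unknown backend {self.backend!r}")
        y = self._check_labels(y)
        self.classes_ = np.asarray(CLASSES, dtype=object)
        codes = np.array([CLASSES.index(lbl) for lbl in y])
        if self.backend == "feature_baseline":
            X = np.vstack([featurize(c) for c in crops])
            self.model_ = make_pipeline(
                StandardScaler(),
                LogisticRegression(
                    C=self.C,
                    max_iter=self.max_iter,
                    class_weight="balanced",
                    random_state=self.random_state,
                ),
            )
            self.model_.fit(X, codes)
        else:
            X = _conv_inputs(crops)
            rng = np.random.default_rng(self.random_state)
            net = _ConvSmallNet(rng)
            n = len(X)
            onehot = np.eye(3)[codes]
            support = np.bincount(codes, minlength=3).astype(float)
            cw = n / (3.0 * np.clip(support, 1.0, None))
            weights = cw[codes]
            for _ in range(self.epochs):
                order = rng.permutation(n)
                for i in range(0, n, self.batch_size):
                    idx = order[i : i + self.batch_size]
                    grads = net._backward(X[idx], onehot[idx], weights[idx])
                    net._step(grads, lr=self.learning_rate)
            self.model_ = net
        self.n_features_in_ = len(crops)
        return self

    def predict_proba(self, crops: list[CellCrop]) -> np.ndarray:
        check_is_fitted(self, "model_")
        if len(crops) == 0:
            return np.zeros((0, 3))
        if self.backend == "feature_baseline":
            X = np.vstack([featurize(c) for c in crops])
            probs = self.model_.predict_proba(X)
        else:
            probs = self.model_.predict_proba(_conv_inputs(crops))
        return probs / probs.sum(axis=1, keepdims=True)

    def predict(self, crops: list[CellCrop]) -> np.ndarray:
        probs = self.predict_proba(crops)
        return self.classes_[probs.argmax(axis=1)] if len(probs) else np.asarray([], dtype=object)


def train_classifier(
    training_set: TrainingSet,
    config: dict | None = None,
    seed: int = 0,
) -> CellClassifier:
    """Train a classifier on the ``train`` split and record validation
    metrics on the ``val`` split (if present) in ``model.validation_``."""
    config = dict(config or {})
    backend = config.pop("backend", "feature_baseline")
    clf = CellClassifier(backend=backend, random_state=seed, **config)
    crops, labels = training_set.subset("train")
    if not crops:
        raise ValueError("training set has no 'train' split")
    clf.fit(crops, labels)
    vcrops, vlabels = training_set.subset("val")
    if vcrops:
        clf.validation_ = evaluate(clf, vcrops, vlabels)
    clf.provenance_ = dict(training_set.provenance)
    clf.provenance_.update({"backend": backend, "seed": seed})
    return clf


def classify(
    model: CellClassifier,
    crops: list[CellCrop],
    foci_counts: list[int] | None = None,
) -> list[CellRecord]:
    """One :class:`CellRecord` per crop, order preserved."""
    probs = model.predict_proba(crops)
    records = []
    for i, crop in enumerate(crops):
        p = probs[i]
        records.append(
            CellRecord(
                plate=crop.plate,
                well=crop.well,
                field=crop.field,
                cell_id=crop.cell_id,
                predicted_class=str(CLASSES[int(np.argmax(p))]),
                probabilities=(float(p[0]), float(p[1]), float(p[2])),
                raw_green_mean=float(crop.raw_green_mean),
                foci_count=None if foci_counts is None else int(foci_counts[i]),
            )
        )
    return records


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    rows = [
        {
            "plate": r.plate,
            "well": r.well,
            "field": r.field,
            "cell_id": r.cell_id,
            "class": r.predicted_class,
            "p_nonsig": r.probabilities[0],
            "p_neg": r.probabilities[1],
            "p_pos": r.probabilities[2],
            "raw_green_mean": r.raw_green_mean,
            "foci_count": r.foci_count,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "plate", "well", "field", "cell_id", "class",
            "p_nonsig", "p_neg", "p_pos", "raw_green_mean", "foci_count",
        ],
    )


def evaluate(model: CellClassifier, crops: list[CellCrop], labels) -> dict:
    """Confusion matrix, per-class precision/recall and macro accuracy.

    The confusion matrix has truth on rows (row sums = class support) in
    :data:`CLASSES` order; all metrics derive from the matrix alone.
    Macro accuracy is the unweighted mean of per-class recalls.
    """
    y_true = np.asarray(labels, dtype=object)
    y_pred = model.predict(crops)
    cm = confusion_matrix(y_true, y_pred, labels=list(CLASSES))
    support = cm.sum(axis=1)
    pred_tot = cm.sum(axis=0)
    recall = {
        c: (cm[i, i] / support[i] if support[i] else float("nan"))
        for i, c in enumerate(CLASSES)
    }
    precision = {
        c: (cm[i, i] / pred_tot[i] if pred_tot[i] else float("nan"))
        for i, c in enumerate(CLASSES)
    }
    recalls = [r for r in recall.values() if np.isfinite(r)]
    return {
        "confusion_matrix": pd.DataFrame(cm, index=list(CLASSES), columns=list(CLASSES)),
        "precision": precision,
        "recall": recall,
        "macro_accuracy": float(np.mean(recalls)) if recalls else float("nan"),
        "accuracy": float((y_true == y_pred).mean()) if len(y_true) else float("nan"),
        "n": int(len(y_true)),
    }
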