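"""A surrogate locked linear classifier on variance-stabilized panel counts.

The production classifier this stands in for is proprietary: a locked machine
learning model mapping 190-gene counts to a continuous score on a ~7-unit
display scale and a binary UIP / non-UIP call at a fixed decision boundary.
The surrogate is L2-penalized logistic regression on VST features — an affine
decision function reproduces every property the verification battery
measures (score SDs, boundary crossings, mixture monotonicity) without
claiming the real weights.

Locked means locked: after :func:`train_classifier` the model is a frozen
value object; scoring is a pure function of (model, sample) and is identical
in any batch order. To make single-sample scoring well defined, the model
freezes its normalization reference at training time (per-gene log geometric
means of the normalized training counts) and new samples receive
median-of-ratios size factors against that reference.

Score calibration: the 1st-99th percentile range of training scores is mapped
to a 7-unit span, centered so the logistic decision threshold sits at 0.
UIP is the positive direction; a score exactly on the boundary calls non-UIP
(the assay is built to resist false positives, so ties go to the negative
class).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .preprocess import estimate_dispersion, estimate_size_factors, vst_inverse, vst_transform

__all__ = [
    "ClassifierModel",
    "ScoredSample",
    "train_classifier",
    "train_pipeline",
    "score_sample",
    "score_counts",
    "cross_validated_scores",
    "evaluate_cv",
    "tilt_counts",
]

UIP = "UIP"
NON_UIP = "non-UIP"


@dataclass(frozen=True)
class ScoredSample:
    sample_id: str
    score: float
    call: str


@dataclass(frozen=True)
class ClassifierModel:
    """Frozen linear decision function on the VST scale, with calibration."""

    gene_ids: tuple[str, ...]
    weights: np.ndarray  # one per panel gene, VST scale
    intercept: float
    scale: float  # display units per raw logistic unit
    decision_boundary: float = 0.0
    dispersion: float = 0.0  # alpha used for the VST
    reference_genes: tuple[str, ...] = ()
    log_reference: np.ndarray = field(default_factory=lambda: np.empty(0))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "log_reference", np.asarray(self.log_reference, dtype=float))
        if len(self.weights) != len(self.gene_ids):
            raise ValueError("one weight per panel gene required")

    # -- scoring ---------------------------------------------------------

    def score_transformed(self, x) -> float:
        """Display score of one variance-stabilized sample vector."""
        x = np.asarray(x, dtype=float)
        if x.shape != self.weights.shape:
            raise ValueError(
                f"expected a vector of length {len(self.weights)}, got {x.shape}"
            )
        return float(self.scale * (self.weights @ x + self.intercept))

    def call_of(self, score: float) -> str:
        return UIP if score > self.decision_boundary else NON_UIP

    def size_factor(self, counts: np.ndarray) -> float:
        """Median-of-ratios size factor of one library vs the frozen reference."""
        if self.log_reference.size == 0:
            return 1.0
        idx = [self.gene_ids.index(g) for g in self.reference_genes]
        c = np.asarray(counts, dtype=float)[idx]
        pos = c > 0
        if not pos.any():
            raise ValueError("no reference gene has positive counts in this sample")
        return float(np.exp(np.median(np.log(c[pos]) - self.log_reference[pos])))

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_ids": list(self.gene_ids),
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "scale": self.scale,
                "decision_boundary": self.decision_boundary,
                "dispersion": self.dispersion,
                "reference_genes": list(self.reference_genes),
                "log_reference": self.log_reference.tolist(),
                "metadata": self.metadata,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        return cls(
            gene_ids=tuple(d["gene_ids"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            scale=float(d["scale"]),
            decision_boundary=float(d["decision_boundary"]),
            dispersion=float(d["dispersion"]),
            reference_genes=tuple(d["reference_genes"]),
            log_reference=np.asarray(d["log_reference"], dtype=float),
            metadata=d.get("metadata", {}),
        )


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present in the training data")
    if set(classes) != {UIP, NON_UIP}:
        raise ValueError(f"labels must be {{{UIP!r}, {NON_UIP!r}}}, got {classes}")
    if counts.min() < 3:
        raise ValueError("need at least 3 training samples per class")
    return y


def train_classifier(
    transformed: pd.DataFrame,
    labels,
    penalty: float = 1.0,
    seed: int = 0,
    dispersion: float = 0.0,
) -> ClassifierModel:
    """Fit the surrogate locked classifier on a VST matrix (genes x samples).

    ``penalty`` is the L2 regularization strength (sklearn C = 1/penalty).
    The fit is deterministic for fixed inputs; ``seed`` is recorded in the
    model metadata and fixes any downstream derived randomness.
    """
    y = _check_labels(labels)
    if transformed.shape[1] != len(y):
        raise ValueError("one label per sample column required")
    X = transformed.to_numpy(dtype=float).T
    # default penalty is ridge (L2); C = 1/strength
    clf = LogisticRegression(C=1.0 / penalty, solver="lbfgs", max_iter=10_000, tol=1e-8)
    clf.fit(X, (y == UIP).astype(int))
    w = clf.coef_.ravel()
    b = float(clf.intercept_[0])
    raw = X @ w + b
    p1, p99 = np.percentile(raw, [1, 99])
    span = p99 - p1
    scale = 7.0 / span if span > 0 else 1.0
    n_uip = int((y == UIP).sum())
    return ClassifierModel(
        gene_ids=tuple(transformed.index),
        weights=w,
        intercept=b,
        scale=scale,
        dispersion=dispersion,
        metadata={
            "n_uip": n_uip,
            "n_nonuip": int(len(y) - n_uip),
            "penalty": penalty,
            "seed": seed,
        },
    )


def train_pipeline(
    counts: pd.DataFrame, labels, penalty: float = 1.0, seed: int = 0
) -> ClassifierModel:
    """Full training contract: size factors -> pooled dispersion -> VST -> fit.

    Also freezes the normalization reference (log geometric means of the
    normalized counts over genes positive in all training samples) so that
    the locked model can score single new libraries.
    """
    sf = estimate_size_factors(counts)
    alpha = estimate_dispersion(counts, sf)
    transformed = vst_transform(counts, sf, alpha)
    model = train_classifier(transformed, labels, penalty=penalty, seed=seed,
                             dispersion=alpha)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy(dtype=float)
    positive = np.all(norm > 0, axis=1)
    ref_genes = tuple(np.asarray(counts.index)[positive])
    log_ref = np.log(norm[positive]).mean(axis=1)
    return ClassifierModel(
        gene_ids=model.gene_ids,
        weights=model.weights,
        intercept=model.intercept,
        scale=model.scale,
        dispersion=alpha,
        reference_genes=ref_genes,
        log_reference=log_ref,
        metadata=model.metadata,
    )


def score_sample(model: ClassifierModel, transformed_vector, sample_id: str = "") -> ScoredSample:
    """Score one variance-stabilized sample vector: pure, never mutates the model."""
    s = model.score_transformed(transformed_vector)
    return ScoredSample(sample_id=sample_id, score=s, call=model.call_of(s))


def score_counts(model: ClassifierModel, counts) -> pd.DataFrame:
    """Score raw count libraries through the locked pipeline.

    ``counts`` is a genes x samples DataFrame (or a single vector). Each
    sample is normalized against the model's frozen reference, transformed
    with the model's dispersion, and scored. Returns a DataFrame with
    ``score`` and ``call`` per sample.
    """
    if isinstance(counts, pd.DataFrame):
        cols = list(counts.columns)
        mat = counts.reindex(list(model.gene_ids)).to_numpy(dtype=float)
        if np.isnan(mat).any():
            raise ValueError("count matrix is missing panel genes")
    else:
        cols = ["sample"]
        mat = np.asarray(counts, dtype=float).reshape(-1, 1)
        if mat.shape[0] != len(model.gene_ids):
            raise ValueError("count vector length does not match the panel")
    rows = []
    for j, sid in enumerate(cols):
        sf = model.size_factor(mat[:, j])
        x = vst_transform(mat[:, j] / sf, alpha=model.dispersion)
        s = model.score_transformed(x)
        rows.append({"sample_id": sid, "score": s, "call": model.call_of(s)})
    return pd.DataFrame(rows).set_index("sample_id")


def cross_validated_scores(
    transformed: pd.DataFrame, labels, folds: int = 5, seed: int = 0, penalty: float = 1.0
) -> pd.Series:
    """Out-of-fold display scores from stratified k-fold cross validation."""
    y = _check_labels(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, class_counts = np.unique(y, return_counts=True)
    if folds > class_counts.min():
        raise ValueError("folds may not exceed the size of the smaller class")
    X = transformed
    out = pd.Series(np.nan, index=transformed.columns, name="score")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X.T, y):
        m = train_classifier(X.iloc[:, train_idx], y[train_idx], penalty=penalty, seed=seed)
        for j in test_idx:
            out.iloc[j] = m.score_transformed(X.iloc[:, j].to_numpy())
    return out


def evaluate_cv(
    transformed: pd.DataFrame, labels, folds: int = 5, seed: int = 0, penalty: float = 1.0
) -> tuple[float, float]:
    """Stratified cross-validated (sensitivity, specificity) of the surrogate.

    Sensitivity is the fraction of UIP samples called UIP out of fold;
    specificity the fraction of non-UIP samples called non-UIP.
    """
    y = np.asarray(labels)
    scores = cross_validated_scores(transformed, labels, folds=folds, seed=seed, penalty=penalty)
    calls = np.where(scores.to_numpy() > 0.0, UIP, NON_UIP)
    sens = float(np.mean(calls[y == UIP] == UIP))
    spec = float(np.mean(calls[y == NON_UIP] == NON_UIP))
    return sens, spec


def tilt_counts(model: ClassifierModel, counts: np.ndarray, delta_score: float) -> np.ndarray:
    """Tilt a count vector along the classifier direction by ``delta_score``.

    The vector is moved on the VST scale by ``(delta/scale) * w / ||w||^2``,
    which shifts the display score by exactly ``delta_score`` before
    renormalization, then mapped back through the inverse VST and rounded.
    This is how score-scale run/lab/replicate effects are realized in counts.
    """
    w = model.weights
    x = vst_transform(np.asarray(counts, dtype=float), alpha=model.dispersion)
    x = x + (delta_score / model.scale) * w / (w @ w)
    q = vst_inverse(np.clip(x, 0.0, None), alpha=model.dispersion)
    return np.round(np.clip(q, 0.0, None)).astype(np.int64)
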