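"""Quality validation of generated WBC images.

Four complementary checks, mirroring how synthetic medical image sets are
vetted before release:

1. classify-generated: a trained classifier labels the generated images; a
   faithful generator yields near-diagonal confusion.
2. train-on-generated / test-on-real: a fresh classifier trained only on
   generated images is evaluated only on real ones.
3. cosine-similarity gap: per class, the mean pairwise cosine similarity
   among original images is compared with the mean original-vs-generated
   similarity; the absolute difference, in percentage points, is a fidelity
   statistic (small gap = generated images sit in the originals'
   neighborhood).
4. blinded-rater scoring: the confusion matrix and accuracy of a human
   expert classifying a mixed original/generated set, with a per-source
   error breakdown.

Images are flattened row-major, channel-last before cosine computation;
cosine similarity is invariant to a global rescaling of all images (raw
0-255 vs normalized [0,1]) but not to per-image normalization, so the
normalization state is recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import CLASS_NAMES, LabeledDataset, canonical_class
from .evaluation import (ConfusionMatrix, MetricsReport, classification_metrics,
                         confusion_matrix)
from .models import BuiltModel, build_wnet
from .training import TrainingConfig, train_model

__all__ = ["SimilarityReport", "cosine_similarity", "similarity_gap",
           "classify_generated", "generative_train_eval", "rater_scoring",
           "RaterAnswer"]

PAIR_BUDGET = 100_000


@dataclass
class SimilarityReport:
    """Per-class cosine-similarity statistics, gaps in percentage points."""

    within_original: dict[str, float]
    original_vs_generated: dict[str, float]
    gap_percent: dict[str, float]
    mean_gap_percent: float
    normalization_state: str = "unspecified"

    def __post_init__(self):
        for d in (self.within_original, self.original_vs_generated):
            for v in d.values():
                if not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
                    raise ValueError("cosine similarity outside [-1, 1]")
        if any(g < 0 for g in self.gap_percent.values()):
            raise ValueError("gaps must be nonnegative")


def cosine_similarity(u, v) -> float:
    """u.v / (|u||v|); raises on zero vectors or length mismatch."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _unit_rows(images: list[np.ndarray]) -> np.ndarray:
    x = np.stack([np.asarray(im, dtype=np.float64).ravel() for im in images])
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("zero image in similarity computation")
    return x / norms


def _mean_within(u: np.ndarray, rng: np.random.Generator) -> float:
    """Mean cosine over the full n x n comparison ("n vs n", self-pairs
    included, seeded subsample above the pair budget).  Including the
    diagonal makes the statistic coincide with the cross-score when the two
    sets are identical (gap exactly 0); its contribution is O(1/n)."""
    n = u.shape[0]
    if n * n <= PAIR_BUDGET:
        return float((u @ u.T).mean())
    i = rng.integers(0, n, size=PAIR_BUDGET)
    j = rng.integers(0, n, size=PAIR_BUDGET)
    return float(np.einsum("ij,ij->i", u[i], u[j]).mean())


def _mean_cross(u: np.ndarray, v: np.ndarray, rng: np.random.Generator) -> float:
    n, m = u.shape[0], v.shape[0]
    if n * m <= PAIR_BUDGET:
        return float((u @ v.T).mean())
    i = rng.integers(0, n, size=PAIR_BUDGET)
    j = rng.integers(0, m, size=PAIR_BUDGET)
    return float(np.einsum("ij,ij->i", u[i], v[j]).mean())


def similarity_gap(originals: LabeledDataset, generated: LabeledDataset,
                   per_class: bool = True, seed: int = 0,
                   normalization_state: str = "unspecified"
                   ) -> SimilarityReport:
    """Per-class |within-original − original-vs-generated| cosine gap.

    The within score averages the full originals-vs-originals comparison
    (n x n, self-pairs included); the cross score averages all original x
    generated pairs; both are seeded-subsampled above a 1e5-pair budget.
    Gaps are reported in percentage points; identical sets give gap 0.
    """
    rng = np.random.default_rng(seed)
    o_counts, g_counts = originals.counts, generated.counts
    classes = [c for c in CLASS_NAMES if o_counts[c] or g_counts[c]]
    for c in classes:
        if not (o_counts[c] and g_counts[c]):
            raise ValueError(f"class {c!r} present in only one of the two sets")
    within, cross, gaps = {}, {}, {}
    for c in classes:
        u = _unit_rows([r.pixels for r in originals.restrict_to_class(c)])
        v = _unit_rows([r.pixels for r in generated.restrict_to_class(c)])
        if u.shape[0] < 2:
            raise ValueError(f"need at least 2 originals of class {c!r}")
        within[c] = _mean_within(u, rng)
        cross[c] = _mean_cross(u, v, rng)
        gaps[c] = abs(within[c] - cross[c]) * 100.0
    return SimilarityReport(
        within_original=within, original_vs_generated=cross,
        gap_percent=gaps,
        mean_gap_percent=float(np.mean(list(gaps.values()))),
        normalization_state=normalization_state)


def classify_generated(model: BuiltModel, generated: LabeledDataset
                       ) -> tuple[ConfusionMatrix, MetricsReport]:
    """Label generated images with a trained classifier; standard inference."""
    x = generated.pixel_stack().astype(np.float32)
    scores = model.forward(x)
    pred = scores.argmax(axis=1)
    cm = confusion_matrix(generated.label_indices(), pred)
    report = classification_metrics(cm, scores=scores,
                                    true_labels=generated.label_indices())
    return cm, report


def generative_train_eval(generated: LabeledDataset, real: LabeledDataset,
                          config: TrainingConfig,
                          model: BuiltModel | None = None) -> MetricsReport:
    """Train a fresh classifier on generated images only; evaluate on real only."""
    model = model if model is not None else build_wnet(seed=config.seed)
    model, _ = train_model(model, generated, config)
    x = real.pixel_stack().astype(np.float32)
    scores = model.forward(x)
    cm = confusion_matrix(real.label_indices(), scores.argmax(axis=1))
    return classification_metrics(cm, scores=scores,
                                  true_labels=real.label_indices())


@dataclass(frozen=True)
class RaterAnswer:
    """One answer-sheet item: the item's truth and the rater's call."""

    true_class: str
    true_source: str  # 'original' | 'generated'
    predicted_class: str

    def __post_init__(self):
        if self.true_source not in ("original", "generated"):
            raise ValueError("true_source must be 'original' or 'generated'")


def rater_scoring(answers: list[RaterAnswer]
                  ) -> tuple[ConfusionMatrix, float, dict[str, dict[str, int]]]:
    """Score a blinded rater's answer sheet.

    Returns (confusion matrix, overall accuracy, per-source breakdown with
    'correct'/'wrong' counts for original and generated items).
    """
    if not answers:
        raise ValueError("empty answer sheet")
    true = [canonical_class(a.true_class) for a in answers]
    pred = [canonical_class(a.predicted_class) for a in answers]
    cm = confusion_matrix(true, pred)
    breakdown = {s: {"correct": 0, "wrong": 0} for s in ("original", "generated")}
    for a, t, p in zip(answers, true, pred):
        breakdown[a.true_source]["correct" if t == p else "wrong"] += 1
    return cm, cm.accuracy, breakdown
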