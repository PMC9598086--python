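"""t-SNE embedding of normalized mark coordinates with the square-root
perplexity rule, plus DBSCAN labelling of the 2D embedding.

Feature space is the normalized 3D position only (x / bone length, y and z
by their axis extents); mark type and context are carried as labels for
colouring, never as features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE

from .core import BoneTemplate, MarkRecord, marks_positions
from .errors import ValidationError


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (n, 2)
    perplexity: float
    iterations: int
    seed: int | None
    labels: np.ndarray | None = None  # DBSCAN labels, -1 = noise
    eps: float | None = None
    min_pts: int | None = None


def optimal_perplexity(n: int) -> int:
    """Ceiling of the square root of the sample size."""
    if n < 4:
        raise ValidationError("need n >= 4 for a meaningful perplexity")
    p = math.ceil(math.sqrt(n))
    if p >= n / 3:
        warnings.warn(
            f"perplexity {p} is large relative to n={n} (>= n/3); "
            "embedding may be unstable"
        )
    return p


def mark_features(marks: Iterable[MarkRecord], template: BoneTemplate) -> np.ndarray:
    """Per-mark (x/L, y/extent, z/extent) normalized coordinates."""
    pos = marks_positions(marks)
    extents = template.points.max(axis=0) - template.points.min(axis=0)
    return (pos - template.points.min(axis=0)) / extents


def tsne_embed(
    features: np.ndarray,
    iterations: int = 1000,
    perplexity: float | None = None,
    seed: int | None = 0,
) -> EmbeddingResult:
    """Deterministic (given seed) 2D t-SNE embedding of a feature matrix."""
    features = np.asarray(features, dtype=float)
    n = len(features)
    if n < 8:
        raise ValidationError("need >= 8 marks to embed")
    if perplexity is None:
        perplexity = optimal_perplexity(n)
    if n < 3 * perplexity:
        raise ValidationError(
            f"fewer marks ({n}) than 3 x perplexity ({3 * perplexity}); "
            f"reduce perplexity to <= {n // 3} or collect more marks"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=float(perplexity),
        max_iter=int(iterations),
        init="random",
        learning_rate="auto",
        random_state=seed,
    )
    coords = tsne.fit_transform(features)
    return EmbeddingResult(
        coordinates=np.asarray(coords, dtype=float),
        perplexity=float(perplexity),
        iterations=int(iterations),
        seed=seed,
    )


def tsne_restarts(
    features: np.ndarray,
    restarts: int,
    iterations: int = 1000,
    perplexity: float | None = None,
    seed: int = 0,
) -> list[EmbeddingResult]:
    """Repeated t-SNE runs with derived seeds; each result records the seed
    that reproduces it."""
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(restarts)
    return [
        tsne_embed(features, iterations, perplexity, seed=int(s) % (2 ** 31))
        for s in seeds
    ]


def dbscan_cluster(
    embedding: EmbeddingResult | np.ndarray,
    eps: float = 3.0,
    min_pts: int = 4,
) -> np.ndarray:
    """Density-based labels on the 2D embedding; -1 marks noise."""
    if eps <= 0:
        raise ValidationError("eps must be > 0")
    coords = (
        embedding.coordinates if isinstance(embedding, EmbeddingResult) else
        np.asarray(embedding, dtype=float)
    )
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(coords)
    if isinstance(embedding, EmbeddingResult):
        embedding.labels = labels
        embedding.eps = eps
        embedding.min_pts = min_pts
    return labels


def embed_marks(
    marks: Sequence[MarkRecord],
    template: BoneTemplate,
    iterations: int = 1000,
    perplexity: float | None = None,
    eps: float = 3.0,
    min_pts: int = 4,
    seed: int | None = 0,
) -> EmbeddingResult:
    """Convenience pipeline: features -> t-SNE -> DBSCAN."""
    result = tsne_embed(mark_features(marks, template), iterations, perplexity, seed)
    dbscan_cluster(result, eps=eps, min_pts=min_pts)
    return result
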