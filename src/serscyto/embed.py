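"""t-SNE model selection: perplexity sweep, KL replicate pick, DBI choice.

t-SNE is stochastic, so replicate embeddings at one perplexity differ; the
replicate with the lowest final Kullback-Leibler divergence is the most
faithful fit of that perplexity.  Across perplexities, the best replicate's
Davies-Bouldin index (computed in the 2-D embedding with the known class
labels; lower means tighter, better separated clusters) decides the final
perplexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .synthetic import MARKERS

__all__ = [
    "EmbeddingFit",
    "EmbeddingSelection",
    "DEFAULT_PERPLEXITIES",
    "tsne_sweep",
    "select_by_kl",
    "davies_bouldin",
    "select_perplexity",
]

#: Default sweep: 12 perplexities spanning 5-300, five replicates each (60 fits).
DEFAULT_PERPLEXITIES: tuple[float, ...] = (5, 10, 20, 30, 45, 60, 90, 120, 150, 200, 250, 300)


@dataclass
class EmbeddingFit:
    """One t-SNE run: 2-D coordinates plus the final KL divergence."""

    perplexity: float
    replicate: int
    coordinates: np.ndarray  # (n_cells, 2)
    kl_divergence: float
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding coordinates must be finite")
        if self.kl_divergence < 0:
            raise ValueError("KL divergence must be >= 0")


@dataclass
class EmbeddingSelection:
    """Audit trail of the full sweep plus the DBI-chosen embedding."""

    best_fits: dict[float, EmbeddingFit]  # perplexity -> lowest-KL replicate
    dbi: dict[float, float]  # perplexity -> DBI of that best fit
    chosen_perplexity: float
    chosen_fit: EmbeddingFit
    all_fits: list[EmbeddingFit] = field(repr=False, default_factory=list)


def _as_features(profiles: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(profiles, pd.DataFrame):
        return profiles[list(MARKERS)].to_numpy(dtype=float)
    return np.asarray(profiles, dtype=float)


def tsne_sweep(
    profiles: pd.DataFrame | np.ndarray,
    perplexities: Sequence[float] = DEFAULT_PERPLEXITIES,
    n_replicates: int = 5,
    seed: int | None = None,
) -> list[EmbeddingFit]:
    """Fit ``n_replicates`` t-SNE embeddings per perplexity.

    Every replicate gets a distinct derived seed and records the final KL
    divergence of its optimisation.  Other hyperparameters stay at the
    scikit-learn defaults.
    """
    X = _as_features(profiles)
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 cells, got {n}")
    for p in perplexities:
        if p >= n:
            raise ValueError(f"perplexity {p} must be < number of cells ({n})")
    rng = np.random.default_rng(seed)
    fit_seeds = rng.integers(0, 2**31 - 1, size=(len(perplexities), n_replicates))
    fits = []
    for i, perp in enumerate(perplexities):
        for rep in range(n_replicates):
            s = int(fit_seeds[i, rep])
            tsne = TSNE(n_components=2, perplexity=perp, random_state=s)
            coords = tsne.fit_transform(X)
            fits.append(
                EmbeddingFit(
                    perplexity=float(perp),
                    replicate=rep,
                    coordinates=coords,
                    kl_divergence=float(tsne.kl_divergence_),
                    seed=s,
                )
            )
    return fits


def select_by_kl(fits: Sequence[EmbeddingFit]) -> EmbeddingFit:
    """The lowest-KL fit among replicates of one perplexity (ties: lowest index)."""
    if not fits:
        raise ValueError("no fits given")
    perps = {f.perplexity for f in fits}
    if len(perps) > 1:
        raise ValueError(f"fits mix perplexities: {sorted(perps)}")
    return min(fits, key=lambda f: (f.kl_divergence, f.replicate))


def davies_bouldin(points: np.ndarray, labels: Sequence) -> float:
    """Davies-Bouldin index: mean over clusters of the worst-case
    (sigma_i + sigma_j) / d(c_i, c_j), with c_i the cluster centroid, sigma_i
    the mean Euclidean member-to-centroid distance and d the centroid
    distance.  Lower is better; 0 when every cluster is a single point.
    """
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 labelled clusters")
    centroids = np.array([points[labels == c].mean(axis=0) for c in classes])
    scatters = np.array(
        [np.linalg.norm(points[labels == c] - centroids[k], axis=1).mean() for k, c in enumerate(classes)]
    )
    k = classes.size
    worst = np.zeros(k)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(centroids[i] - centroids[j])
            if d == 0:
                raise ValueError(
                    f"clusters {classes[i]!r} and {classes[j]!r} have coincident centroids"
                )
            worst[i] = max(worst[i], (scatters[i] + scatters[j]) / d)
    return float(worst.mean())


def select_perplexity(
    profiles: pd.DataFrame | np.ndarray,
    labels: Sequence,
    perplexities: Sequence[float] = DEFAULT_PERPLEXITIES,
    n_replicates: int = 5,
    seed: int | None = None,
) -> EmbeddingSelection:
    """Full selection: sweep, per-perplexity KL pick, DBI argmin across picks."""
    fits = tsne_sweep(profiles, perplexities, n_replicates, seed)
    best_fits: dict[float, EmbeddingFit] = {}
    dbi: dict[float, float] = {}
    for perp in perplexities:
        group = [f for f in fits if f.perplexity == float(perp)]
        best = select_by_kl(group)
        best_fits[float(perp)] = best
        dbi[float(perp)] = davies_bouldin(best.coordinates, labels)
    chosen = min(dbi, key=lambda p: (dbi[p], p))
    return EmbeddingSelection(
        best_fits=best_fits,
        dbi=dbi,
        chosen_perplexity=chosen,
        chosen_fit=best_fits[chosen],
        all_fits=fits,
    )
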