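"""Latent-space analysis: 2D neighborhood embedding and anisotropy ratio.

The 64-dimensional penultimate activations of a trained classifier are
summarized two ways: a t-SNE embedding for visual inspection, and the
anisotropy ratio λ2/λ1 of the feature covariance eigenvalues.  A ratio near
1 means the feature cloud spreads evenly across its leading principal
components (isotropic); near 0 means it is stretched along one direction
(anisotropic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE

from .errors import DegenerateInputError, ValidationError
from .models import penultimate_features

_RATIO_EPS = 1e-12


def embed_2d(features, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """Deterministic (seeded) t-SNE embedding of an n × d feature matrix."""
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ValidationError(
            f"t-SNE needs n > 3 × perplexity; got n={n}, perplexity={perplexity}"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=seed)
    return tsne.fit_transform(X)


def covariance_eigenvalues(features) -> np.ndarray:
    """Eigenvalues of the sample covariance (n−1 denominator), descending."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValidationError("need an n × d matrix with n ≥ 3 and d ≥ 2")
    cov = np.cov(X, rowvar=False)
    w = np.linalg.eigvalsh(cov)[::-1]
    return np.clip(w, 0.0, None)


def anisotropy_ratio(features) -> float:
    """λ2/λ1 of the feature covariance; in [0, 1].

    Raises :class:`DegenerateInputError` when the covariance has no spread
    (all feature rows identical).
    """
    w = covariance_eigenvalues(features)
    if w[0] <= _RATIO_EPS:
        raise DegenerateInputError("feature covariance is rank 0 (constant features)")
    return float(w[1] / w[0])


@dataclass
class LatentReport:
    features: np.ndarray      # n × 64
    embedding: np.ndarray     # n × 2
    labels: np.ndarray        # n class ids
    eigenvalues: np.ndarray   # descending
    anisotropy_ratio: float
    perplexity: float
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "n_samples": int(len(self.labels)),
            "feature_dim": int(self.features.shape[1]),
            "eigenvalues": self.eigenvalues.tolist(),
            "anisotropy_ratio": self.anisotropy_ratio,
            "perplexity": self.perplexity,
            "seed": self.seed,
        })

    def embedding_to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "x": self.embedding[:, 0],
            "y": self.embedding[:, 1],
            "label": self.labels,
        }).to_csv(path, index=False)


def latent_report(model, X, labels, perplexity: float = 30.0,
                  seed: int = 0) -> LatentReport:
    """Penultimate features, 2D embedding and anisotropy for a dataset.

    ``X`` must already be shaped for the model ((n, 13, 3) for the GCN,
    (n, 39) for the FFNN).
    """
    feats = np.atleast_2d(penultimate_features(model, X))
    labels = np.asarray(labels)
    if len(labels) != len(feats):
        raise ValidationError("labels and features have different lengths")
    try:
        ratio = anisotropy_ratio(feats)
        eig = covariance_eigenvalues(feats)
    except DegenerateInputError as exc:
        raise DegenerateInputError(
            f"model produced constant penultimate features ({exc}); "
            "is the model trained?"
        ) from exc
    emb = embed_2d(feats, perplexity=perplexity, seed=seed)
    return LatentReport(feats, emb, labels, eig, ratio, perplexity, seed)
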