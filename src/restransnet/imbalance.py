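"""Class-imbalance strategies: oversampling, reverse loss re-weighting, and
the gradient penalty.

The gradient penalty targets the overfitting introduced by oversampling: the
minority-class duplicates produce near-identical per-sample gradients.  For a
batch with flattened per-sample gradients g_1..g_n, pairwise cosine
similarities cos(theta_ij) = g_i.g_j / (||g_i|| ||g_j||) are computed and every
sample that participates in an above-threshold pair (cos > epsilon) has its
gradient shrunk by a multiplicative factor in (0, 1] before the batch
aggregate is formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STRATEGIES = ("none", "oversample", "reweight", "gradient_penalty")


@dataclass
class PenaltyConfig:
    epsilon: float = 0.9        # cosine-similarity threshold
    lambda_shrink: float = 0.5  # shrink factor applied to penalised samples
    per_pair: bool = False      # lambda ** (#above-threshold pairs) variant

    def __post_init__(self):
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")
        if not 0 < self.lambda_shrink <= 1:
            raise ValueError("lambda_shrink must be in (0, 1]")


def oversample(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Index sequence with minority-class samples resampled (with
    replacement) so both classes contribute the majority count per epoch."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling needs both classes present")
    n_max = counts.max()
    idx_parts = []
    for cls, count in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        if count < n_max:
            idx = np.concatenate([idx, rng.choice(idx, n_max - count, replace=True)])
        idx_parts.append(idx)
    out = np.concatenate(idx_parts)
    return out[rng.permutation(len(out))]


def reverse_weights(class_counts: np.ndarray) -> np.ndarray:
    """Class-distribution-reverse weights w_k proportional to 1/count_k,
    normalised to average 1 (head class down-weighted, tail up-weighted)."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if (counts <= 0).any():
        raise ValueError("all class counts must be positive")
    w = 1.0 / counts
    return w * len(w) / w.sum()


def cosine_similarity_matrix(gradients: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities of per-sample gradient vectors (n, P).

    Zero gradient vectors get similarity 0 with everything (and with
    themselves), so they are never penalised.
    """
    g = np.asarray(gradients, dtype=np.float64)
    if not np.isfinite(g).all():
        raise ValueError("gradients must be finite")
    norms = np.linalg.norm(g, axis=1)
    sims = g @ g.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = sims / np.outer(norms, norms)
    sims[~np.isfinite(sims)] = 0.0
    nz = norms > 0
    np.fill_diagonal(sims, np.where(nz, 1.0, 0.0))
    return np.clip(sims, -1.0, 1.0)


def penalty_factors(similarity: np.ndarray, epsilon: float = 0.9,
                    lambda_shrink: float = 0.5,
                    per_pair: bool = False) -> np.ndarray:
    """Multiplicative factors f_i in (0, 1]: samples with any off-diagonal
    cosine above epsilon shrink by lambda (or lambda^#pairs when per_pair)."""
    PenaltyConfig(epsilon=epsilon, lambda_shrink=lambda_shrink)  # validate
    s = np.asarray(similarity)
    off = s.copy()
    np.fill_diagonal(off, -np.inf)
    exceed = off > epsilon
    if per_pair:
        return lambda_shrink ** exceed.sum(axis=1).astype(float)
    return np.where(exceed.any(axis=1), lambda_shrink, 1.0)


def apply_gradient_penalty(gradients: np.ndarray,
                           factors: np.ndarray) -> np.ndarray:
    """Aggregate gradient (1/n) sum_i f_i g_i; with all f_i = 1 this equals
    the plain batch-mean gradient exactly."""
    g = np.asarray(gradients)
    f = np.asarray(factors)
    if len(f) != len(g):
        raise ValueError("one factor per sample required")
    return (g * f[:, None]).mean(axis=0)


def gradient_penalty_factors(gradients: np.ndarray,
                             config: PenaltyConfig | None = None) -> np.ndarray:
    """Convenience: cosine matrix -> penalty factors in one call."""
    config = config or PenaltyConfig()
    sims = cosine_similarity_matrix(gradients)
    return penalty_factors(sims, config.epsilon, config.lambda_shrink,
                           config.per_pair)
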