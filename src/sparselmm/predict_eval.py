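"""Phenotype prediction for held-out individuals and evaluation metrics.

Prediction combines the posterior-mean sparse effects with a BLUP-style
transfer of the random effect through the train/test cross-kinship block:

    y_hat = mu + X_test beta + s K_cross (s K_train + I)^{-1} (y - 1 mu - X_train beta)

with ``s`` the posterior-mean random-effect variance scale.  Binary (0/1)
traits are fitted as quantitative; predictions are interpreted as case
probabilities (clamped to [0, 1]) for the Brier score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .geno_io import GenotypeMatrix, Kinship
from .mcmc import PosteriorSamples

__all__ = [
    "PredictionResult",
    "predict",
    "rpg",
    "rmse",
    "correlation",
    "auc",
    "brier",
    "liability_correction",
]


@dataclass
class PredictionResult:
    y_hat: np.ndarray
    mean: float
    sparse_part: np.ndarray
    random_part: np.ndarray


def _blup_transfer(
    sigma_b2: float,
    k_cross: np.ndarray,
    kin_train: Kinship,
    resid: np.ndarray,
) -> np.ndarray:
    """``s K_cross (s K_train + I)^{-1} resid`` via the cached eigenbasis."""
    if sigma_b2 <= 0.0:
        return np.zeros(k_cross.shape[0])
    U = kin_train.eigenvectors
    d = 1.0 / (sigma_b2 * kin_train.eigenvalues + 1.0)
    return sigma_b2 * (k_cross @ (U @ (d * (U.T @ resid))))


def predict(
    samples: PosteriorSamples,
    g_train: GenotypeMatrix,
    y_train: np.ndarray,
    kin_train: Kinship,
    g_test: GenotypeMatrix,
    k_cross: np.ndarray,
    average: str = "means",
) -> PredictionResult:
    """Predict test phenotypes from a fitted chain.

    ``g_test`` must be centered with the *training* column means and carry
    the same marker list; ``k_cross`` is the test x train kinship block on
    the same scale as ``kin_train``.  ``average='means'`` (default) plugs
    in posterior means; ``average='draws'`` averages the full predictor
    over kept draws (requires the chain to have recorded effects).
    """
    if g_test.marker_ids != g_train.marker_ids:
        bad = [a for a, b in zip(g_test.marker_ids, g_train.marker_ids)
               if a != b] or ["(length mismatch)"]
        raise ValueError(f"train/test marker mismatch: {bad[:5]}")
    if average not in ("means", "draws"):
        raise ValueError("average must be 'means' or 'draws'")
    y_train = np.asarray(y_train, dtype=float)

    if average == "means":
        mu = float(np.mean(samples.mu))
        beta = samples.beta_mean()
        sb2 = float(np.mean(samples.sigma_b2))
        sparse = g_test.dosages @ beta
        resid = y_train - mu - g_train.dosages @ beta
        random_part = _blup_transfer(sb2, k_cross, kin_train, resid)
        return PredictionResult(
            y_hat=mu + sparse + random_part, mean=mu,
            sparse_part=sparse, random_part=random_part,
        )

    if samples.effects is None:
        raise ValueError("draw-averaged prediction needs record_effects=True")
    n_test = g_test.n
    acc_sparse = np.zeros(n_test)
    acc_random = np.zeros(n_test)
    acc_mu = 0.0
    m = samples.n_kept
    for i in range(m):
        gidx, bdraw = samples.effects[i]
        mu_i = samples.mu[i]
        sb2_i = samples.sigma_b2[i]
        sparse_i = (g_test.dosages[:, gidx] @ bdraw) if gidx.size else 0.0
        fit_i = (g_train.dosages[:, gidx] @ bdraw) if gidx.size else 0.0
        resid_i = y_train - mu_i - fit_i
        acc_sparse += sparse_i
        acc_random += _blup_transfer(sb2_i, k_cross, kin_train, resid_i)
        acc_mu += mu_i
    mu = acc_mu / m
    sparse = acc_sparse / m
    random_part = acc_random / m
    return PredictionResult(y_hat=mu + sparse + random_part, mean=mu,
                            sparse_part=sparse, random_part=random_part)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("rmse needs two equal-length vectors (n >= 2)")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def correlation(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("correlation needs two equal-length vectors (n >= 2)")
    a = y_true - y_true.mean()
    b = y_pred - y_pred.mean()
    va, vb = float(a @ a), float(b @ b)
    if va == 0.0 or vb == 0.0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float((a @ b) / math.sqrt(va * vb))


def rpg(y_true, y_pred, y_opt) -> float:
    """Relative predictive gain: MSE standardized between the mean
    predictor (0) and the best-possible predictor (1); can be negative."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    y_opt = np.asarray(y_opt, float)
    if not (y_true.shape == y_pred.shape == y_opt.shape):
        raise ValueError("rpg needs three equal-length vectors")
    mse_null = float(np.mean((y_true - y_true.mean()) ** 2))
    mse_pred = float(np.mean((y_true - y_pred) ** 2))
    mse_opt = float(np.mean((y_true - y_opt) ** 2))
    denom = mse_null - mse_opt
    if denom == 0.0:
        raise ValueError("rpg undefined: optimal predictor no better than mean")
    return (mse_null - mse_pred) / denom


def auc(labels, scores) -> float:
    """Mann-Whitney AUC with half-credit for tied scores."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    if labels.shape != scores.shape:
        raise ValueError("labels/scores length mismatch")
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("auc needs both classes present")
    r = rankdata(scores)
    u = float(r[pos].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def brier(labels, probs) -> float:
    labels = np.asarray(labels, float)
    probs = np.clip(np.asarray(probs, float), 0.0, 1.0)
    if labels.shape != probs.shape:
        raise ValueError("labels/probs length mismatch")
    return float(np.mean((probs - labels) ** 2))


def liability_correction(
    pve_observed: float, prevalence: float, case_fraction: float
) -> float:
    """Convert observed-scale PVE of a 0/1 trait to the liability scale.

    Multiplies by ``K^2 (1-K)^2 / (z^2 P (1-P))`` where ``K`` is the
    population prevalence, ``P`` the sample case fraction and ``z`` the
    standard normal density at the ``K``-upper-tail threshold.  The result
    is clamped to [0, 1].
    """
    K, P = prevalence, case_fraction
    if not (0.0 < K < 1.0 and 0.0 < P < 1.0):
        raise ValueError("prevalence and case_fraction must be in (0, 1)")
    if pve_observed < 0.0:
        raise ValueError("pve_observed must be non-negative")
    z = norm.pdf(norm.isf(K))
    factor = K ** 2 * (1.0 - K) ** 2 / (z ** 2 * P * (1.0 - P))
    out = pve_observed * factor
    if out > 1.0:
        import warnings

        warnings.warn("liability-scale PVE exceeded 1; clamped")
        out = 1.0
    return float(out)
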