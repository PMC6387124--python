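"""Weighted relevance vector machine (sparse Bayesian kernel classifier).

The second-layer classifier is a relevance vector machine: a kernel-basis
logistic model whose basis coefficients carry independent zero-mean Gaussian
priors with per-basis precisions.  Type-II maximum likelihood drives most
precisions to infinity, pruning their bases; the surviving training points
are the *relevance vectors* — typically a small fraction of the training
set, which is the practical argument for the RVM over an SVM.  Unlike an
SVM the output is a posterior probability, so the 50% decision rule has a
direct Bayesian reading.

The kernel is an anisotropic Gaussian whose squared distance scales each
feature axis by its I-RELIEF contribution weight,

    K(x, y) = exp( - sum_j w_j (x_j - y_j)^2 / (2 * width^2) ),

so features that carry no class information are effectively removed from
the metric.  With uniform weights (w_j = 1/d) this reduces to a plain RBF.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import (
    FeatureConfig,
    NormalizationStats,
    apply_normalization,
    image_feature_table,
)
from .imaging import as_rgb_image, tile_blocks

log = logging.getLogger(__name__)

DEFAULT_KERNEL_WIDTH = 0.5
DEFAULT_MAX_EM_ITER = 200
DEFAULT_PRUNE_THRESHOLD = 1e9

TARGET_LABEL = 0  # label convention: 0 = target (fruit), 1 = non-target
MODEL_SCHEMA_VERSION = 1


def weighted_kernel(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, width: float = DEFAULT_KERNEL_WIDTH
) -> np.ndarray | float:
    """Anisotropic Gaussian kernel with per-feature weights.

    ``x`` and ``y`` may be single vectors or 2-D sample blocks; the result
    broadcasts to the corresponding Gram block.  Always in (0, 1] and
    symmetric in its arguments.
    """
    if width <= 0:
        raise ValueError("kernel width must be > 0")
    X = np.atleast_2d(np.asarray(x, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    w = np.asarray(w, dtype=np.float64)
    diff = X[:, None, :] - Y[None, :, :]
    d2 = np.einsum("ijk,k->ij", diff**2, w)
    K = np.exp(-d2 / (2.0 * width**2))
    if np.ndim(x) == 1 and np.ndim(y) == 1:
        return float(K[0, 0])
    return K


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class RvmModel:
    """Trained weighted-RVM second-layer classifier.

    ``relevance_vectors`` are the retained normalized training vectors;
    ``mu`` holds the posterior-mean coefficient for each retained basis
    (index 0 is the bias).  ``basis_precisions`` are the surviving prior
    precisions; the prior's pruning of large precisions is what makes the
    model sparse.
    """

    relevance_vectors: np.ndarray  # (M, d) normalized feature vectors
    mu: np.ndarray  # (M + 1,) coefficients, bias first
    basis_precisions: np.ndarray  # (M + 1,) prior precisions, bias first
    kernel_width: float
    feature_weights: np.ndarray  # (d,) I-RELIEF weights
    normalization: NormalizationStats
    feature_config: FeatureConfig
    n_train: int
    converged: bool = True

    # ---------------------------------------------------------- persistence
    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "model": "weighted-rvm",
            "relevance_vectors": self.relevance_vectors.tolist(),
            "mu": self.mu.tolist(),
            "basis_precisions": self.basis_precisions.tolist(),
            "kernel_width": self.kernel_width,
            "feature_weights": self.feature_weights.tolist(),
            "normalization": self.normalization.to_dict(),
            "feature_config": self.feature_config.to_dict(),
            "n_train": self.n_train,
            "converged": self.converged,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RvmModel":
        d = json.loads(Path(path).read_text())
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {d.get('schema_version')!r}"
            )
        return cls(
            relevance_vectors=np.asarray(d["relevance_vectors"], dtype=np.float64),
            mu=np.asarray(d["mu"], dtype=np.float64),
            basis_precisions=np.asarray(d["basis_precisions"], dtype=np.float64),
            kernel_width=float(d["kernel_width"]),
            feature_weights=np.asarray(d["feature_weights"], dtype=np.float64),
            normalization=NormalizationStats.from_dict(d["normalization"]),
            feature_config=FeatureConfig.from_dict(d["feature_config"]),
            n_train=int(d["n_train"]),
            converged=bool(d["converged"]),
        )

    def checksum(self, path: str | Path | None = None) -> str:
        payload = (
            Path(path).read_bytes()
            if path is not None
            else json.dumps(self.to_dict()).encode()
        )
        return hashlib.sha256(payload).hexdigest()


def _laplace_fit(
    Phi: np.ndarray, t: np.ndarray, alpha: np.ndarray, mu0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Newton/IRLS mode finding for the Bernoulli likelihood + Gaussian prior.

    Returns the posterior mode ``mu`` and covariance ``Sigma`` (Laplace
    approximation at the mode).
    """
    mu = mu0.copy()
    A = np.diag(alpha)
    for _ in range(50):
        z = Phi @ mu
        p = _sigmoid(z)
        g = Phi.T @ (t - p) - alpha * mu
        B = np.clip(p * (1.0 - p), 1e-12, None)
        H = (Phi.T * B) @ Phi + A
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # backtracking on the penalised log-likelihood
        def objective(m: np.ndarray) -> float:
            zz = Phi @ m
            ll = np.sum(t * zz - np.logaddexp(0.0, zz))
            return float(ll - 0.5 * np.sum(alpha * m**2))

        obj0 = objective(mu)
        lam = 1.0
        for _ in range(20):
            cand = mu + lam * step
            if objective(cand) >= obj0:
                break
            lam *= 0.5
        mu = mu + lam * step
        if float(np.max(np.abs(lam * step))) < 1e-8:
            break
    z = Phi @ mu
    p = _sigmoid(z)
    B = np.clip(p * (1.0 - p), 1e-12, None)
    H = (Phi.T * B) @ Phi + np.diag(alpha)
    Sigma = np.linalg.inv(H)
    return mu, Sigma


def train_rvm(
    X: np.ndarray,
    y: np.ndarray,
    feature_weights: np.ndarray,
    kernel_width: float = DEFAULT_KERNEL_WIDTH,
    max_em_iter: int = DEFAULT_MAX_EM_ITER,
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
    seed: int | None = None,
    normalization: NormalizationStats | None = None,
    feature_config: FeatureConfig | None = None,
) -> RvmModel:
    """Train the sparse Bayesian classifier on normalized labelled samples.

    ``y`` uses the 0 = target / 1 = non-target convention; internally the
    target class is mapped to 1 so the model's probability is directly the
    probability of *target*.  The evidence updates
    ``alpha_i <- (1 - alpha_i * Sigma_ii) / mu_i^2`` alternate with Laplace
    refits; bases whose precision exceeds ``prune_threshold`` are removed.
    The bias basis is never pruned.

    The fit is deterministic; ``seed`` exists so callers can thread one
    reproducibility interface through every stage.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("both classes must be present in the training set")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate training set: all feature vectors identical")
    n, d = X.shape
    w = np.asarray(feature_weights, dtype=np.float64)
    t = (y == TARGET_LABEL).astype(np.float64)  # target -> positive class

    K = weighted_kernel(X, X, w, kernel_width)
    Phi_full = np.hstack([np.ones((n, 1)), K])  # bias column first
    active = np.arange(n + 1)
    alpha = np.full(n + 1, 1e-2)
    mu = np.zeros(n + 1)

    converged = False
    for _ in range(max_em_iter):
        Phi = Phi_full[:, active]
        mu, Sigma = _laplace_fit(Phi, t, alpha, mu)
        gamma_i = 1.0 - alpha * np.diag(Sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_new = gamma_i / np.clip(mu**2, 1e-300, None)
        alpha_new = np.clip(alpha_new, 1e-12, 1e12)

        keep = alpha_new < prune_threshold
        keep[active == 0] = True  # bias survives
        # poorly-determined bases (gamma ~ 0) shrink towards pruning at a
        # slow geometric rate; convergence is judged on the rest
        informative = keep & (gamma_i > 1e-3)
        delta = (
            float(np.max(np.abs(np.log(alpha_new[informative]) - np.log(alpha[informative]))))
            if informative.any()
            else 0.0
        )
        active = active[keep]
        alpha = alpha_new[keep]
        mu = mu[keep]
        gamma_i = gamma_i[keep]
        if delta < 1e-3:
            converged = True
            break
    if not converged:
        log.warning(
            "RVM evidence maximisation stopped at max_em_iter "
            "(common on cleanly separable data); returning last iterate"
        )

    # finish the slow prunes: a basis whose coefficient is not
    # distinguishable from zero (gamma ~ 0) carries no information
    final_keep = (gamma_i > 1e-3) | (active == 0)
    active = active[final_keep]
    alpha = alpha[final_keep]
    mu = mu[final_keep]

    # final refit on the surviving bases
    Phi = Phi_full[:, active]
    mu, _ = _laplace_fit(Phi, t, alpha, mu)

    rv_idx = active[active > 0] - 1  # drop bias, map to sample indices
    has_bias = active[0] == 0
    mu_out = np.concatenate([[mu[0] if has_bias else 0.0], mu[1:] if has_bias else mu])
    alpha_out = np.concatenate(
        [[alpha[0] if has_bias else np.inf], alpha[1:] if has_bias else alpha]
    )
    if normalization is None:
        normalization = NormalizationStats(
            minima=np.zeros(d), maxima=np.ones(d), degenerate=np.zeros(d, bool)
        )
    if feature_config is None:
        feature_config = FeatureConfig()
    return RvmModel(
        relevance_vectors=X[rv_idx],
        mu=mu_out,
        basis_precisions=alpha_out,
        kernel_width=kernel_width,
        feature_weights=w,
        normalization=normalization,
        feature_config=feature_config,
        n_train=n,
        converged=converged,
    )


def predict_prob(model: RvmModel, x: np.ndarray, normalized: bool = False) -> np.ndarray | float:
    """Posterior probability that a block is target.

    Raw feature vectors are min-max scaled with the model's stored training
    statistics first; non-finite feature values (the defensive handling of
    invalid extractions) are replaced by 0 after normalization, with a log
    notice, instead of crashing.
    """
    X = np.atleast_2d(np.asarray(x, dtype=np.float64))
    d = model.relevance_vectors.shape[1] if model.relevance_vectors.size else model.feature_weights.size
    if X.shape[1] != d:
        raise ValueError(f"expected {d} features, got {X.shape[1]}")
    if not normalized:
        X = apply_normalization(X, model.normalization)
    bad = ~np.isfinite(X)
    if bad.any():
        log.warning("replacing %d non-finite feature values with 0", int(bad.sum()))
        X = np.where(bad, 0.0, X)
    z = np.full(X.shape[0], model.mu[0])
    if model.relevance_vectors.size:
        K = weighted_kernel(X, model.relevance_vectors, model.feature_weights, model.kernel_width)
        z = z + K @ model.mu[1:]
    p = _sigmoid(z)
    return float(p[0]) if np.ndim(x) == 1 else p


def classify_block(model: RvmModel, x: np.ndarray, normalized: bool = False) -> bool | np.ndarray:
    """Strict 50% rule: target iff predicted probability exceeds 0.5.

    A probability of exactly 0.5 is non-target (the rule is "over 50%").
    """
    p = predict_prob(model, x, normalized=normalized)
    return p > 0.5


def second_layer_mask(img: np.ndarray, model: RvmModel) -> np.ndarray:
    """Block-wise RVM mask over the whole image.

    Every block is classified independently of the first layer (the two
    strategies deliberately never see each other's output); all pixels of a
    target block are set to 255.
    """
    rgb = as_rgb_image(img)
    table = image_feature_table(rgb, model.feature_config)
    feats = table[list(table.columns[2:])].to_numpy()
    decisions = classify_block(model, feats)
    mask = np.zeros(rgb.shape[:2], dtype=np.uint8)
    for blk, hit in zip(tile_blocks(rgb), decisions):
        if hit:
            mask[blk.slice()] = 255
    return mask
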