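"""Nonlinear PCA of stacked C-matrix columns via a rectified-linear auto-encoder.

A two-hidden-unit network (relu hidden layer with bias, untied linear
decoder) is fit by L-BFGS to reconstruct the batch of selected C-matrix
columns at each frame, warm-started from the previous frame so the
unit-to-stream assignment stays consistent over time. The rectified
decoder weights, normalized across units, are the per-(rate, channel)
stream masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .config import ClusterConfig


@dataclass
class AEWeights:
    encoder: np.ndarray          # (K, M)
    encoder_bias: np.ndarray     # (K,)
    decoder: np.ndarray          # (M, K)

    def __post_init__(self):
        K, M = self.encoder.shape
        if self.encoder_bias.shape != (K,) or self.decoder.shape != (M, K):
            raise ValueError("inconsistent auto-encoder weight shapes")

    @property
    def n_units(self) -> int:
        return self.encoder.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.encoder.shape[1]

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.encoder.ravel(), self.encoder_bias, self.decoder.ravel()]
        )

    @classmethod
    def unflatten(cls, theta: np.ndarray, K: int, M: int) -> "AEWeights":
        We = theta[: K * M].reshape(K, M)
        be = theta[K * M : K * M + K]
        Wd = theta[K * M + K :].reshape(M, K)
        return cls(We, be, Wd)

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """Relu hidden activations for a batch of columns (M, B) -> (K, B)."""
        return np.maximum(self.encoder @ X + self.encoder_bias[:, None], 0.0)

    def copy(self) -> "AEWeights":
        return AEWeights(self.encoder.copy(), self.encoder_bias.copy(),
                         self.decoder.copy())


@dataclass
class MaskSet:
    """Per-stream weights over (rate, channel), summing to one everywhere."""

    masks: np.ndarray            # (K, R, D) in [0, 1]
    foreground: int              # index of the foreground stream
    scores: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def labels(self) -> dict:
        return {k: ("foreground" if k == self.foreground else "background")
                for k in range(self.masks.shape[0])}


@dataclass
class FitInfo:
    converged: bool
    n_iter: int
    loss: float
    warning: Optional[str] = None
    n_revived: int = 0


def init_weights(K: int, M: int, seed: int = 0) -> AEWeights:
    """Nonnegative uniform(0, 0.01) start, reproducible given the seed."""
    rng = np.random.default_rng(seed)
    return AEWeights(
        rng.uniform(0.0, 0.01, size=(K, M)),
        rng.uniform(0.0, 0.01, size=K),
        rng.uniform(0.0, 0.01, size=(M, K)),
    )


def init_from_columns(columns: np.ndarray, K: int) -> AEWeights:
    """Deterministic data-driven start: paired +/- principal directions.

    The leading left singular vectors of the column batch define the rays
    the rectified units should split between (anti-correlated sources live
    on opposite signs of one direction). Each direction u contributes a
    (+u, -u) unit pair; L-BFGS then refines. Power iteration from a fixed
    start keeps the whole run deterministic with no dependence on a random
    seed.
    """
    X = np.asarray(columns, dtype=np.float64)
    scale = np.abs(X).max()
    if scale > 0:
        X = X / scale
    M, B = X.shape
    G = X.T @ X                                   # (B, B) Gram

    def leading(G):
        w = np.ones(B)
        sigma = 0.0
        for _ in range(100):
            w_new = G @ w
            sigma = np.linalg.norm(w_new)
            if sigma < 1e-30:
                return None, 0.0
            w_new /= sigma
            if np.linalg.norm(w_new - w) < 1e-12:
                w = w_new
                break
            w = w_new
        u = X @ w
        nu = np.linalg.norm(u)
        return (u / nu if nu > 0 else u), np.sqrt(sigma)

    # collect a few principal directions, preferring the first strongly
    # sign-mixed one: anti-correlated sources live on opposite signs of
    # the contrast direction, while a single-signed direction is the
    # common mode of a fused pair
    dirs = []
    for _ in range(3):
        u, sigma = leading(G)
        if u is None:
            break
        dirs.append((u, sigma))
        w = X.T @ u
        nw = np.linalg.norm(w)
        if nw < 1e-30:
            break
        w /= nw
        G = G - np.outer(w, w) * float(w @ G @ w)

    def mixedness(u):
        pos = np.abs(u[u > 0]).sum()
        neg = np.abs(u[u < 0]).sum()
        total = pos + neg + 1e-30
        return min(pos, neg) / total

    chosen = None
    if dirs:
        sigma1 = dirs[0][1]
        for u, sigma in dirs:
            if sigma >= 0.2 * sigma1 and mixedness(u) >= 0.1:
                chosen = u
                break
        if chosen is None:
            chosen = dirs[0][0]
    else:
        chosen = np.ones(M) / np.sqrt(M)

    # seed only the (+u, -u) contrast pair; any further units start at
    # zero and are brought in by dead-unit revival only if the two-unit
    # reconstruction leaves a real residual (extra units stay silent on
    # two-source input)
    We = np.zeros((K, M))
    We[0] = chosen
    if K > 1:
        We[1] = -chosen
    return AEWeights(We, np.zeros(K), We.T.copy())


def _loss_grad(theta: np.ndarray, X: np.ndarray, K: int, l2: float,
               l1h: float = 0.0):
    M, B = X.shape
    We = theta[: K * M].reshape(K, M)
    be = theta[K * M : K * M + K]
    Wd = theta[K * M + K :].reshape(M, K)
    Z = We @ X + be[:, None]
    H = np.maximum(Z, 0.0)
    E = Wd @ H - X                           # (M, B)
    loss = float(np.sum(E * E) / B
                 + l2 * (np.sum(We * We) + np.sum(Wd * Wd))
                 + l1h * np.sum(H) / B)
    gWd = (2.0 / B) * (E @ H.T) + 2 * l2 * Wd
    dH = (2.0 / B) * (Wd.T @ E) + l1h / B    # dL/dH
    dZ = np.where(Z > 0, dH, 0.0)
    gWe = dZ @ X.T + 2 * l2 * We
    gbe = dZ.sum(axis=1)
    return loss, np.concatenate([gWe.ravel(), gbe, gWd.ravel()])


def _minimize(X, w0, cfg, max_iter):
    K, M = w0.n_units, w0.n_inputs
    res = minimize(
        _loss_grad, w0.flatten(), args=(X, K, cfg.l2, cfg.activity_l1),
        jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": cfg.gtol, "maxls": 40},
    )
    weights = AEWeights.unflatten(res.x, K, M)
    return weights, FitInfo(bool(res.success), int(res.nit), float(res.fun),
                            None if res.success else str(res.message))


def fit_autoencoder(columns: np.ndarray, init: Optional[AEWeights] = None,
                    config: Optional[ClusterConfig] = None, seed: int = 0,
                    max_iter: Optional[int] = None, revive: bool = True,
                    ) -> tuple[AEWeights, FitInfo]:
    """Minimize the mean-squared reconstruction error over a column batch.

    ``columns`` is (M, B): B stacked C-matrix columns of dimension M = R*D.
    The batch is scaled to unit peak before optimization (the relu network
    is approximately scale-equivariant, so warm starts remain valid), and
    weights are returned in those normalized units; masks are ratios of
    decoder weights and unaffected. Dead-unit local minima (a unit whose
    relu gate closed while input remains unexplained) are escaped by
    re-seeding the unit from the residual and refitting.
    """
    cfg = config or ClusterConfig()
    X = np.asarray(columns, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("columns must be an (M, B) batch with B >= 1")
    M, B = X.shape
    K = cfg.n_streams
    scale = np.abs(X).max()
    if scale > 0:
        X = X / scale
    if init is not None:
        w0 = init
    elif cfg.init == "pca":
        w0 = init_from_columns(X, K)
    else:
        w0 = init_weights(K, M, seed)
    if w0.n_inputs != M or w0.n_units != K:
        raise ValueError("init weights incompatible with batch shape")
    weights, info = _minimize(X, w0, cfg, max_iter or cfg.max_iter)
    n_revived = 0
    if revive:
        for _ in range(K):
            weights, revived = revive_dead_units(weights, X)
            if not revived:
                break
            weights, info = _minimize(X, weights, cfg, cfg.max_iter)
            n_revived += 1
    info.n_revived = n_revived
    return weights, info


def revive_dead_units(w: AEWeights, columns: np.ndarray,
                      dead_ratio: float = 0.05,
                      resid_frac: float = 0.05) -> tuple[AEWeights, bool]:
    """Re-seed hidden units that have shut off while input remains unexplained.

    A relu unit whose encoder and decoder have decayed to zero receives no
    gradient and cannot recover on its own (e.g. a unit that idled through
    a single-source stretch before a second source appeared). When a unit's
    decoder norm is negligible and the reconstruction residual is not, the
    unit is re-seeded from the largest residual column, the relu analog of
    k-means empty-cluster re-seeding. Deterministic.
    """
    X = columns / (np.abs(columns).max() or 1.0)
    E = w.decoder @ w.hidden(X) - X
    if np.sum(E * E) < resid_frac * np.sum(X * X):
        return w, False
    norms = np.linalg.norm(w.decoder, axis=0)
    # a unit is dead if its decoder is negligible on the normalized scale
    # (covers the all-units-dead collapse after a sign transition as well)
    if norms.min() > dead_ratio * max(norms.max(), 0.1):
        return w, False
    out = w.copy()
    j = int(np.argmax(np.linalg.norm(E, axis=0)))
    res = -E[:, j]                        # unexplained part of that column
    rn2 = float(res @ res)
    if rn2 == 0:
        return w, False
    k = int(np.argmin(norms))
    out.decoder[:, k] = res
    out.encoder[k] = res / rn2
    out.encoder_bias[k] = 0.0
    return out, True


def align_units(new: AEWeights, ref: AEWeights) -> AEWeights:
    """Permute hidden units of ``new`` to best match ``ref``'s decoder columns.

    Used after a unit revival so that re-seeded units do not swap the
    stream labels carried across frames by the warm start.
    """
    from scipy.optimize import linear_sum_assignment

    a, b = new.decoder, ref.decoder
    na = np.linalg.norm(a, axis=0) + 1e-30
    nb = np.linalg.norm(b, axis=0) + 1e-30
    sim = (a / na).T @ (b / nb)              # (K_new, K_ref)
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty_like(rows)
    perm[cols] = rows
    return AEWeights(new.encoder[perm], new.encoder_bias[perm],
                     new.decoder[:, perm])


def step_frame(columns: np.ndarray, prev: Optional[AEWeights],
               config: Optional[ClusterConfig] = None, seed: int = 0,
               ) -> tuple[AEWeights, FitInfo]:
    """One per-frame update: warm-started fit on this frame's columns.

    Warm starting from the previous frame's weights keeps the stream
    labels of the two hidden units consistent over time. If a unit has
    died while the residual is large, it is re-seeded and the frame refit.
    """
    cfg = config or ClusterConfig()
    max_iter = cfg.max_iter if prev is None else cfg.warm_max_iter
    if columns.shape[1] < 64:
        # small (anchored) batches cost next to nothing per iteration but
        # need more of them to converge; give them the full budget
        max_iter = cfg.max_iter
    weights, info = fit_autoencoder(columns, init=prev, config=cfg, seed=seed,
                                    max_iter=max_iter)
    if info.n_revived and prev is not None:
        weights = align_units(weights, prev)
    return weights, info


def masks_from_weights(w: AEWeights, n_rates: int, n_channels: int,
                       anchor_indices: Optional[np.ndarray] = None,
                       unit_variance: Optional[np.ndarray] = None,
                       unit_activity: Optional[np.ndarray] = None,
                       eps: float = 1e-8,
                       mask_source: str = "decoder") -> MaskSet:
    """Normalize rectified decoder (or encoder) weights into stream masks.

    ``unit_activity`` (RMS hidden activation per unit on the frame's batch)
    scales each unit's rectified weights first: a unit only claims mask
    weight in proportion to its actual reconstruction contribution, so a
    unit whose relu gate is closed cannot dilute the masks. Foreground is
    the unit with greater rectified weight overlap on the anchor channels
    when an anchor is given, else the unit with greater explained variance
    (``unit_variance``). Entries where every unit is inactive fall back to
    1/K.
    """
    if mask_source == "decoder":
        raw = w.decoder                       # (M, K)
    else:
        raw = w.encoder.T
    K = raw.shape[1]
    pos = np.maximum(raw, 0.0).reshape(n_rates, n_channels, K)
    if unit_activity is not None:
        act = np.asarray(unit_activity, dtype=float)
        total = act.max()
        if total > 0:
            pos = pos * (act / total)[None, None, :]
    denom = pos.sum(axis=2, keepdims=True)
    masks = np.where(denom > eps, pos / np.maximum(denom, eps), 1.0 / K)
    masks = np.transpose(masks, (2, 0, 1))    # (K, R, D)
    if anchor_indices is not None and len(anchor_indices) > 0:
        scores = pos[:, anchor_indices, :].sum(axis=(0, 1))
    elif unit_variance is not None:
        scores = np.asarray(unit_variance, dtype=float)
    else:
        scores = pos.sum(axis=(0, 1))
    return MaskSet(masks, int(np.argmax(scores)), scores)


def explained_unit_variance(w: AEWeights, X: np.ndarray) -> np.ndarray:
    """Per-unit contribution ||Wd_k||^2 * sum_b h_k(b)^2 on a batch."""
    H = w.hidden(X / (np.abs(X).max() or 1.0))
    return np.sum(H ** 2, axis=1) * np.sum(w.decoder ** 2, axis=0)


def store_template(weight_history: Sequence[AEWeights]) -> AEWeights:
    """Time-average auto-encoder weights from a clean-source run (memory prior)."""
    if not weight_history:
        raise ValueError("cannot build a template from an empty history")
    enc = np.mean([w.encoder for w in weight_history], axis=0)
    bias = np.mean([w.encoder_bias for w in weight_history], axis=0)
    dec = np.mean([w.decoder for w in weight_history], axis=0)
    return AEWeights(enc, bias, dec)


def apply_template(template: AEWeights, columns: np.ndarray,
                   config: Optional[ClusterConfig] = None,
                   mode: str = "fixed") -> tuple[AEWeights, FitInfo]:
    """Use stored template weights on a new batch: fixed, or as warm init."""
    if template.n_inputs != columns.shape[0]:
        raise ValueError(
            f"template dimension {template.n_inputs} does not match "
            f"columns ({columns.shape[0]})"
        )
    if mode == "fixed":
        cfg = config or ClusterConfig()
        X = columns / (np.abs(columns).max() or 1.0)
        loss, _ = _loss_grad(template.flatten(), X, template.n_units, cfg.l2)
        return template.copy(), FitInfo(True, 0, loss)
    if mode == "init":
        return fit_autoencoder(columns, init=template, config=config)
    raise ValueError("mode must be 'fixed' or 'init'")
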