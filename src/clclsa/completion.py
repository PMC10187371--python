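"""Cross-omics bridges: latent-space imputation of missing omics layers.

For every ordered pair of omics (i, k), i != k, a bridge network
h_ik = dec_i(enc_k(.)) maps the latent block of omics k to a prediction of
the latent block of omics i.  Bridges are fitted only on subjects where
both omics are observed, by a summed squared-error reconstruction loss in
which the target latent is treated as a constant (no gradient flows into
the encoder through the target) — otherwise minimizing the reconstruction
loss alone collapses all omics latents onto a single point.  At imputation
time a missing latent is replaced by the mean of the bridge predictions
from all observed source omics.
"""

from __future__ import annotations

import numpy as np

from .attention import LatentBlock
from .nn import Module, Tensor, build_mlp

__all__ = [
    "BridgeBank",
    "predict_latent",
    "pair_reconstruction_loss",
    "total_reconstruction_loss",
    "impute_missing",
]


class BridgeBank(Module):
    """All M(M-1) ordered cross-omics autoencoders, keyed by (target, source)."""

    def __init__(self, n_views: int, layer_spec: str, rng: np.random.Generator):
        super().__init__()
        if n_views < 1:
            raise ValueError("need at least one view")
        self.n_views = n_views
        self.layer_spec = layer_spec
        self.bridges = {}
        for i in range(n_views):
            for k in range(n_views):
                if i != k:
                    self.bridges[(i, k)] = build_mlp(layer_spec, rng)

    @classmethod
    def default(cls, n_views: int, latent_dim: int, rng: np.random.Generator):
        """Bottleneck autoencoder D-64-BN-ReLU-32-ReLU-64-BN-ReLU-D (scaled down
        for small D)."""
        h1, h2 = min(64, latent_dim), min(32, latent_dim)
        spec = f"{latent_dim}-{h1}-BN-ReLU-{h2}-ReLU-{h1}-BN-ReLU-{latent_dim}"
        return cls(n_views, spec, rng)

    def children(self):
        return [self.bridges[key] for key in sorted(self.bridges)]

    def __getitem__(self, key):
        try:
            return self.bridges[key]
        except KeyError:
            raise LookupError(
                f"no bridge for (target, source) pair {key}; "
                f"valid pairs are ordered (i, k) with i != k < {self.n_views}"
            ) from None

    def pairs(self):
        return sorted(self.bridges)


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def predict_latent(z_k, bridge: Module, training: bool = False) -> Tensor:
    """Run one bridge: dec_i(enc_k(z_k)).

    In eval mode (default) batch-norm layers use running statistics, so the
    map is deterministic subject-by-subject.
    """
    bridge.set_training(training)
    return bridge(_as_t(z_k))


def pair_reconstruction_loss(pred, target) -> Tensor:
    """Sum over subjects of squared L2 distance between latents."""
    pred, target = _as_t(pred), _as_t(target)
    if pred.data.shape != target.data.shape:
        raise ValueError(f"shape mismatch {pred.data.shape} vs {target.data.shape}")
    return ((pred - target) ** 2).sum()


def total_reconstruction_loss(latents, bank: BridgeBank, mask: np.ndarray) -> Tensor:
    """Fully connected cross-omics reconstruction loss.

    Sums the pairwise loss over all ordered pairs (i, k), i != k, restricted
    to subjects where both omics are observed.  Targets are detached.  With
    M = 2 this reduces to the two-directional bi-view loss.
    """
    zs = latents.latents if isinstance(latents, LatentBlock) else latents
    zs = [_as_t(z) for z in zs]
    m = len(zs)
    if m < 2:
        raise ValueError("cross-omics reconstruction needs at least two views")
    mask = np.asarray(mask, dtype=bool)
    total = Tensor(0.0)
    for i in range(m):
        for k in range(m):
            if i == k:
                continue
            rows = np.flatnonzero(mask[:, i] & mask[:, k])
            if rows.size == 0:
                continue
            pred = bank[(i, k)](zs[k][rows])
            total = total + pair_reconstruction_loss(pred, zs[i][rows].detach())
    return total


def impute_missing(latents, bank: BridgeBank, mask: np.ndarray) -> LatentBlock:
    """Complete a latent block: observed latents pass through, missing ones are
    replaced by the mean bridge prediction over all observed source omics.

    Bridges run in eval mode (running batch-norm statistics).  Gradients may
    flow through the imputed values into both the bridges and the source
    encoders, so the classification loss can shape the completion end-to-end.
    """
    block = latents if isinstance(latents, LatentBlock) else LatentBlock(list(latents))
    zs = [_as_t(z) for z in block.latents]
    mask = np.asarray(mask, dtype=bool)
    n, m = mask.shape
    if not mask.any(axis=1).all():
        raise ValueError("a subject with no observed omics cannot be imputed")
    bank.set_training(False)
    out = []
    for i in range(m):
        missing = np.flatnonzero(~mask[:, i])
        if missing.size == 0:
            out.append(zs[i])
            continue
        d = zs[i].data.shape[1]
        acc = Tensor(np.zeros((n, d)))
        counts = np.zeros((n, 1))
        for k in range(m):
            if k == i:
                continue
            rows = np.flatnonzero(~mask[:, i] & mask[:, k])
            if rows.size == 0:
                continue
            pred = bank[(i, k)](zs[k][rows])
            scatter = np.zeros((n, rows.size))
            scatter[rows, np.arange(rows.size)] = 1.0
            acc = acc + Tensor(scatter) @ pred
            counts[rows] += 1.0
        observed_col = mask[:, i:i + 1].astype(float)
        imputed = acc / Tensor(np.maximum(counts, 1.0))
        out.append(zs[i] * Tensor(observed_col) + imputed * Tensor(1.0 - observed_col))
    return LatentBlock(out, block.omics_scores, block.feature_scores)
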