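"""Cross-omics contrastive objective based on a joint probability table.

Two omics latent matrices are compared by (1) mapping each subject's latent
row to a probability vector with a row softmax, (2) averaging the outer
products of paired rows over subjects into a D x D joint table P (then
symmetrizing and renormalizing), and (3) scoring

    L(P) = - sum_{d,d'} P_dd' * ln( P_dd' / (P_d^{a+1} * P_d'^{a+1}) )

where P_d, P_d' are the marginals and alpha >= 0 trades mutual information
against per-omics entropy.  At alpha = 0 this is exactly -MI(P): minimizing
it maximizes the mutual information between the two omics representations;
alpha > 0 additionally rewards high marginal entropy, which counteracts
representation collapse.

The total loss sums the pairwise term over all ordered omics pairs,
restricted to subjects where both omics are observed (imputed latents are
excluded, so the bridges cannot be rewarded for self-consistency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .attention import LatentBlock
from .nn import Tensor, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastiveConfig",
    "JointDistribution",
    "joint_distribution",
    "joint_distribution_t",
    "contrastive_pair_loss",
    "contrastive_pair_loss_t",
    "contrastive_total",
    "contrastive_total_t",
]


@dataclass
class ContrastiveConfig:
    """alpha balances entropy vs mutual information; epsilon floors the logs.

    alpha defaults to 9, the value used by the contrastive objective this
    loss is adopted from; it is deliberately surfaced here because the
    choice materially changes the loss landscape.
    """

    alpha: float = 9.0
    epsilon: float = 1e-8

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")


@dataclass
class JointDistribution:
    """Symmetrized joint probability table with its marginals."""

    P: np.ndarray
    row_marginals: np.ndarray
    col_marginals: np.ndarray


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def joint_distribution_t(z_i, z_k, normalize_rows: bool = True) -> Tensor:
    """Differentiable joint table from two N x D latent matrices.

    Rows are softmax-normalized into probability vectors (set
    ``normalize_rows=False`` if they already are), averaged as outer
    products, symmetrized and renormalized to sum to one.
    """
    z_i, z_k = _as_t(z_i), _as_t(z_k)
    n = z_i.data.shape[0]
    if n == 0:
        raise ValueError("joint distribution needs at least one subject")
    if z_k.data.shape[0] != n:
        raise ValueError("latent matrices must pair the same subjects")
    if normalize_rows:
        z_i, z_k = softmax(z_i), softmax(z_k)
    P = (z_i.T @ z_k) / float(n)
    P = (P + P.T) * 0.5
    return P / P.sum()


def joint_distribution(z_i, z_k, normalize_rows: bool = True) -> JointDistribution:
    """Numpy-facing wrapper of :func:`joint_distribution_t`."""
    P = joint_distribution_t(z_i, z_k, normalize_rows).data
    return JointDistribution(P=P, row_marginals=P.sum(axis=1), col_marginals=P.sum(axis=0))


def contrastive_pair_loss_t(P: Tensor, alpha: float, epsilon: float = 1e-8) -> Tensor:
    """Differentiable pairwise contrastive loss on a joint table."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    P = _as_t(P)
    Pc = P.clip_min(epsilon)
    pd = P.sum(axis=1, keepdims=True).clip_min(epsilon)
    pdp = P.sum(axis=0, keepdims=True).clip_min(epsilon)
    log_ratio = Pc.log() - (alpha + 1.0) * pd.log() - (alpha + 1.0) * pdp.log()
    return -(P * log_ratio).sum()


def contrastive_pair_loss(P, alpha: float, epsilon: float = 1e-8) -> float:
    """Pairwise contrastive loss of a joint table (accepts JointDistribution,
    numpy array or Tensor)."""
    if isinstance(P, JointDistribution):
        P = P.P
    return float(contrastive_pair_loss_t(_as_t(P), alpha, epsilon).data)


def contrastive_total_t(
    latents, mask: np.ndarray, cfg: ContrastiveConfig | None = None
) -> Tensor:
    """Sum of pairwise contrastive losses over all ordered omics pairs.

    Each pair uses only the subjects where both omics are observed; a pair
    with no jointly observed subject contributes zero (with a warning).
    With a single omics layer the loss is identically zero.
    """
    cfg = cfg or ContrastiveConfig()
    zs = latents.latents if isinstance(latents, LatentBlock) else latents
    zs = [_as_t(z) for z in zs]
    m = len(zs)
    if m < 2:
        return Tensor(0.0)
    mask = np.asarray(mask, dtype=bool)
    total = Tensor(0.0)
    for i in range(m):
        for k in range(m):
            if i == k:
                continue
            rows = np.flatnonzero(mask[:, i] & mask[:, k])
            if rows.size == 0:
                logger.warning(
                    "omics pair (%d, %d) has no jointly observed subjects; "
                    "its contrastive term is 0",
                    i,
                    k,
                )
                continue
            P = joint_distribution_t(zs[i][rows], zs[k][rows])
            total = total + contrastive_pair_loss_t(P, cfg.alpha, cfg.epsilon)
    return total


def contrastive_total(latents, mask, cfg: ContrastiveConfig | None = None) -> float:
    return float(contrastive_total_t(latents, mask, cfg).data)
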