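"""Self-attention gating and multi-omics fusion.

The per-omics encoding pipeline is: a feature-level attention network f_i
scores every raw feature with a sigmoid gate in (0, 1); the gated features
are embedded by an omics-specific MLP emb_i (linear -> ReLU -> dropout); an
omics-level attention network g_i produces one sigmoid scalar per subject
that rescales the whole latent block; the gated latent blocks of all omics
are finally concatenated, in view order, into the fused representation fed
to the classifier.

All operations accept and return autodiff Tensors so the gates train
end-to-end; plain numpy arrays are wrapped on entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import Module, Tensor, build_mlp, concat

__all__ = [
    "AttentionConfig",
    "LatentBlock",
    "feature_attention",
    "embed_omics",
    "omics_attention",
    "apply_omics_attention",
    "fuse",
]


@dataclass
class AttentionConfig:
    """Layer strings for the attention/embedding stacks of each omics.

    ``feature_att[i]`` maps V_i -> V_i, ``embed[i]`` maps V_i -> D (shared
    latent dimension, identical across omics) and ``omics_att[i]`` maps
    D -> 1.  Strings follow the tabular grammar of :func:`clclsa.nn.build_mlp`,
    e.g. ``"200-300-ReLU-DP"``.
    """

    feature_att: list
    embed: list
    omics_att: list
    latent_dim: int
    dropout: float = 0.5

    @classmethod
    def default(cls, view_dims, latent_dim: int = 64, dropout: float = 0.5):
        """Standard stack: f_i V->V, emb_i V->D-ReLU-DP, g_i D->1."""
        return cls(
            feature_att=[f"{v}-{v}" for v in view_dims],
            embed=[f"{v}-{latent_dim}-ReLU-DP" for v in view_dims],
            omics_att=[f"{latent_dim}-1" for _ in view_dims],
            latent_dim=latent_dim,
            dropout=dropout,
        )


@dataclass
class LatentBlock:
    """Gated per-omics latents plus the attention scores that produced them."""

    latents: list  # M tensors, each N x D
    omics_scores: list = field(default_factory=list)  # M tensors, N x 1
    feature_scores: list = field(default_factory=list)  # M tensors, N x V_i


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def feature_attention(x: "Tensor | np.ndarray", f_net: Module) -> Tensor:
    """Sigmoid feature-level attention scores, elementwise in (0, 1)."""
    x = _as_t(x)
    scores = f_net(x).sigmoid()
    if scores.data.shape != x.data.shape:
        raise ValueError(
            f"feature-attention net must preserve shape; got {scores.data.shape} "
            f"for input {x.data.shape}"
        )
    return scores


def embed_omics(
    x: "Tensor | np.ndarray",
    fatt: "Tensor | np.ndarray",
    emb_net: Module,
    training: bool = False,
) -> Tensor:
    """Embed sigmoid-gated features: emb_i(x * fatt)."""
    x, fatt = _as_t(x), _as_t(fatt)
    if x.data.shape != fatt.data.shape:
        raise ValueError(f"x {x.data.shape} and fatt {fatt.data.shape} must agree")
    if ((fatt.data < 0) | (fatt.data > 1)).any():
        warnings.warn(
            "feature-attention scores fall outside [0, 1]; they should come "
            "from feature_attention (sigmoid outputs)",
            stacklevel=2,
        )
    emb_net.set_training(training)
    return emb_net(x * fatt)


def omics_attention(x_hat: "Tensor | np.ndarray", g_net: Module) -> Tensor:
    """One sigmoid importance scalar per subject for a whole omics block."""
    x_hat = _as_t(x_hat)
    scores = g_net(x_hat).sigmoid()
    if scores.data.shape[1] != 1:
        raise ValueError(f"omics-attention net must map to one scalar, got {scores.data.shape}")
    return scores


def apply_omics_attention(
    x_hat: "Tensor | np.ndarray", matt: "Tensor | np.ndarray"
) -> Tensor:
    """Rescale a latent block by its per-subject scalar gate (broadcast over D)."""
    x_hat, matt = _as_t(x_hat), _as_t(matt)
    if matt.data.ndim != 2 or matt.data.shape != (x_hat.data.shape[0], 1):
        raise ValueError(
            f"matt must have shape ({x_hat.data.shape[0]}, 1), got {matt.data.shape}"
        )
    return x_hat * matt


def fuse(latents: list) -> Tensor:
    """Concatenate the M gated latent blocks along features, in view order."""
    latents = [_as_t(z) for z in latents]
    n = {z.data.shape[0] for z in latents}
    if len(n) > 1:
        raise ValueError(f"latent blocks disagree on subject count: {sorted(n)}")
    if len(latents) == 1:
        return latents[0]
    return concat(latents, axis=1)


class OmicsEncoder(Module):
    """The full gated encoder of one omics layer: x -> z_hat (N x D).

    Bundles f_i, emb_i and g_i; ``forward`` returns the gated latent and
    ``encode`` additionally returns both attention score sets.  When
    ``use_attention`` is off, both gates are bypassed (constant 1), which is
    the "plain" configuration of the component ablation.
    """

    def __init__(
        self,
        view_dim: int,
        cfg: AttentionConfig,
        index: int,
        rng: np.random.Generator,
        use_attention: bool = True,
    ):
        super().__init__()
        self.view_dim = view_dim
        self.use_attention = use_attention
        self.f_net = build_mlp(cfg.feature_att[index], rng, cfg.dropout)
        self.emb_net = build_mlp(cfg.embed[index], rng, cfg.dropout)
        self.g_net = build_mlp(cfg.omics_att[index], rng, cfg.dropout)

    def children(self):
        return [self.f_net, self.emb_net, self.g_net]

    def encode(self, x: "Tensor | np.ndarray"):
        x = _as_t(x)
        n = x.data.shape[0]
        if self.use_attention:
            fatt = feature_attention(x, self.f_net)
            x_hat = self.emb_net(x * fatt)
            matt = omics_attention(x_hat, self.g_net)
            z_hat = apply_omics_attention(x_hat, matt)
        else:
            fatt = Tensor(np.ones_like(x.data))
            x_hat = self.emb_net(x)
            matt = Tensor(np.ones((n, 1)))
            z_hat = x_hat
        return z_hat, matt, fatt

    def forward(self, x):
        return self.encode(x)[0]
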