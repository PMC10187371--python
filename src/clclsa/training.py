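"""Model assembly, loss functions, two-phase training and grid search.

The classifier couples three mechanisms around a softmax head on the fused
latent representation:

* per-omics auxiliary heads whose cross-entropy, together with a squared
  penalty tying the omics-level attention gate to the auxiliary head's
  true-class probability, regularizes the gates (weight ``lambda_al``);
* cross-omics bridges trained by latent reconstruction on complete
  subjects (weight ``lambda_co``) and used to impute missing latents;
* the contrastive mutual-information loss between omics latents
  (weight ``lambda_cl``).

Each epoch runs two full-batch phases: subjects with complete omics update
every component (including all bridges); subjects with missing omics get
their absent latents imputed by the trained bridges and contribute to the
classification and auxiliary losses only.  Optimization is Adam at an
initial learning rate of 1e-4 with step decay (x0.2 every 500 epochs) and
a fixed epoch cap — no early stopping.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .attention import AttentionConfig, LatentBlock, OmicsEncoder, fuse
from .completion import BridgeBank, impute_missing, total_reconstruction_loss
from .contrastive import ContrastiveConfig, contrastive_total_t
from .data_model import OmicsDataset, split_dataset
from .nn import Adam, Module, Tensor, build_mlp

__all__ = [
    "LossWeights",
    "LossBundle",
    "TrainConfig",
    "Architecture",
    "CLCLSAModel",
    "TrainingDivergenceError",
    "classification_loss",
    "auxiliary_loss",
    "total_loss",
    "train",
    "predict",
    "grid_search",
    "LAMBDA_GRID",
]

#: hyperparameter grid explored by grid_search for each loss weight
LAMBDA_GRID = (0.0, 0.01, 0.02, 0.05, 0.1, 1.0)

_LOG_EPS = 1e-12


class TrainingDivergenceError(RuntimeError):
    """A loss component became non-finite during training."""


@dataclass
class LossWeights:
    """Non-negative weights of the auxiliary, reconstruction and contrastive
    terms in the total objective."""

    lambda_al: float = 0.1
    lambda_co: float = 0.1
    lambda_cl: float = 0.01

    def __post_init__(self):
        for name in ("lambda_al", "lambda_co", "lambda_cl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class LossBundle:
    """Named loss components and the weighted total of one training step."""

    l_clf: float
    l_al: float
    l_co: float
    l_cl: float
    total: float

    def as_dict(self):
        return asdict(self)


@dataclass
class TrainConfig:
    """Optimization settings.

    Defaults are the reference regime: Adam, initial learning rate 1e-4,
    2500-epoch cap, learning rate multiplied by ``lr_decay`` every
    ``decay_every`` epochs, full-batch updates.  :meth:`desk_scale` gives
    the shorter schedule used throughout the synthetic benchmark.
    """

    epochs: int = 2500
    lr: float = 1e-4
    lr_decay: float = 0.2
    decay_every: int = 500
    weights: LossWeights = field(default_factory=LossWeights)
    contrastive: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    latent_dim: int = 64
    dropout: float = 0.5
    use_attention: bool = True
    imputation: str = "bridge"  # "bridge" | "zero"
    confidence: str = "tcp"  # "tcp" | "max"
    detach_imputed: bool = False  # stop classifier gradients at imputed latents

    @classmethod
    def desk_scale(cls, epochs: int = 300, **kwargs) -> "TrainConfig":
        """Shortened schedule for desk-size synthetic runs.

        Fewer epochs at a proportionally larger learning rate keep the
        total Adam parameter displacement (roughly lr x epochs) near the
        reference regime's 1e-4 x 2500 while fitting interactive budgets.
        """
        kwargs.setdefault("lr", 1e-3)
        return cls(epochs=epochs, **kwargs)


@dataclass
class Architecture:
    """Layer strings for every sub-network of the model."""

    attention: AttentionConfig
    bridge_spec: str
    aux_heads: list
    final_head: str
    n_classes: int
    view_dims: tuple

    @classmethod
    def default(cls, view_dims, n_classes, latent_dim: int = 64, dropout: float = 0.5):
        att = AttentionConfig.default(view_dims, latent_dim, dropout)
        h1, h2 = min(64, latent_dim), min(32, latent_dim)
        bridge = f"{latent_dim}-{h1}-BN-ReLU-{h2}-ReLU-{h1}-BN-ReLU-{latent_dim}"
        return cls(
            attention=att,
            bridge_spec=bridge,
            aux_heads=[f"{latent_dim}-{n_classes}-Softmax" for _ in view_dims],
            final_head=f"{len(view_dims) * latent_dim}-{n_classes}-Softmax",
            n_classes=n_classes,
            view_dims=tuple(view_dims),
        )


# ---------------------------------------------------------------------------
# losses


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size and labels.max() >= n_classes:
        raise IndexError(f"label {labels.max()} out of range for {n_classes} classes")
    eye = np.zeros((labels.size, n_classes))
    eye[np.arange(labels.size), labels] = 1.0
    return eye


def classification_loss(probs, labels) -> Tensor:
    """Summed cross-entropy -sum_j ln p_j[y_j] on probability rows."""
    probs = _as_t(probs)
    onehot = _onehot(labels, probs.data.shape[1])
    return -(probs.clip_min(_LOG_EPS).log() * Tensor(onehot)).sum()


def auxiliary_loss(matts, aux_probs, labels, confidence: str = "tcp") -> Tensor:
    """Confidence-alignment plus auxiliary cross-entropy, summed over omics.

    For each omics the per-subject scalar gate is pulled toward the
    auxiliary head's confidence — its true-class probability (``tcp``,
    default) or its maximum softmax probability (``max``) — with the
    confidence treated as a constant in the squared term; the head itself is
    trained by standard cross-entropy against the labels.
    """
    labels = np.asarray(labels, dtype=np.int64)
    total = Tensor(0.0)
    for matt, probs in zip(matts, aux_probs):
        matt, probs = _as_t(matt), _as_t(probs)
        n = probs.data.shape[0]
        if matt.data.shape != (n, 1):
            raise ValueError(f"gate shape {matt.data.shape} != ({n}, 1)")
        if confidence == "tcp":
            conf = probs.data[np.arange(n), labels][:, None]
        elif confidence == "max":
            conf = probs.data.max(axis=1, keepdims=True)
        else:
            raise ValueError(f"unknown confidence notion {confidence!r}")
        total = total + ((matt - Tensor(conf)) ** 2).sum()
        total = total + classification_loss(probs, labels)
    return total


def total_loss(l_clf, l_al, l_co, l_cl, weights: LossWeights):
    """Weighted total objective; returns (Tensor total, LossBundle of floats)."""
    parts = {"l_clf": l_clf, "l_al": l_al, "l_co": l_co, "l_cl": l_cl}
    for name, part in parts.items():
        value = part.data if isinstance(part, Tensor) else part
        if not np.all(np.isfinite(value)):
            raise TrainingDivergenceError(f"loss component {name} is non-finite")
    total = (
        _as_t(l_clf)
        + weights.lambda_al * _as_t(l_al)
        + weights.lambda_co * _as_t(l_co)
        + weights.lambda_cl * _as_t(l_cl)
    )
    bundle = LossBundle(
        l_clf=float(_as_t(l_clf).data),
        l_al=float(_as_t(l_al).data),
        l_co=float(_as_t(l_co).data),
        l_cl=float(_as_t(l_cl).data),
        total=float(total.data),
    )
    return total, bundle


# ---------------------------------------------------------------------------
# the model


class CLCLSAModel(Module):
    """All learned sub-networks plus their configuration and seed."""

    def __init__(self, arch: Architecture, cfg: TrainConfig, seed: int):
        super().__init__()
        self.arch = arch
        self.cfg = cfg
        self.seed = int(seed)
        # per-view standardization fitted on observed training rows
        self.scaler_mean = [np.zeros(v) for v in arch.view_dims]
        self.scaler_sd = [np.ones(v) for v in arch.view_dims]
        rng = np.random.default_rng(seed)
        self.encoders = [
            OmicsEncoder(v, arch.attention, i, rng, use_attention=cfg.use_attention)
            for i, v in enumerate(arch.view_dims)
        ]
        self.bank = (
            BridgeBank(len(arch.view_dims), arch.bridge_spec, rng)
            if len(arch.view_dims) > 1
            else None
        )
        self.aux_heads = [build_mlp(s, rng, cfg.dropout) for s in arch.aux_heads]
        self.final_head = build_mlp(arch.final_head, rng, cfg.dropout)
        self.history: list[LossBundle] = []

    def children(self):
        kids = list(self.encoders) + list(self.aux_heads) + [self.final_head]
        if self.bank is not None:
            kids.append(self.bank)
        return kids

    # -- forward passes ----------------------------------------------------
    def fit_scaler(self, ds: OmicsDataset) -> None:
        """Fit per-view feature standardization on observed training rows."""
        for i, view in enumerate(ds.views):
            rows = ds.mask[:, i]
            self.scaler_mean[i] = view[rows].mean(axis=0)
            sd = view[rows].std(axis=0)
            self.scaler_sd[i] = np.where(sd > 1e-12, sd, 1.0)

    def encode_views(self, views, training: bool) -> LatentBlock:
        latents, matts, fatts = [], [], []
        for i, (enc, x) in enumerate(zip(self.encoders, views)):
            x = (np.asarray(x) - self.scaler_mean[i]) / self.scaler_sd[i]
            enc.set_training(training)
            z, matt, fatt = enc.encode(x)
            latents.append(z)
            matts.append(matt)
            fatts.append(fatt)
        return LatentBlock(latents, matts, fatts)

    def complete_latents(self, block: LatentBlock, mask: np.ndarray) -> LatentBlock:
        """Fill missing latents by bridge imputation (or zeros, per config)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.all() or len(self.encoders) == 1:
            return block
        if self.cfg.imputation == "bridge" and self.bank is not None:
            return impute_missing(block, self.bank, mask)
        zeroed = [
            z * Tensor(mask[:, i:i + 1].astype(float))
            for i, z in enumerate(block.latents)
        ]
        return LatentBlock(zeroed, block.omics_scores, block.feature_scores)

    def forward_probs(self, views, mask, training: bool = False):
        """Fused class probabilities; returns (probs, completed LatentBlock)."""
        block = self.encode_views(views, training)
        block = self.complete_latents(block, mask)
        self.final_head.set_training(training)
        probs = self.final_head(fuse(block.latents))
        return probs, block

    def predict_proba(self, ds: OmicsDataset) -> np.ndarray:
        if ds.view_dims != self.arch.view_dims:
            raise ValueError(
                f"dataset views {ds.view_dims} do not match model {self.arch.view_dims}"
            )
        probs, _ = self.forward_probs(ds.views, ds.mask, training=False)
        return probs.data

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = dict(self.state_dict())
        for i in range(len(self.arch.view_dims)):
            arrays[f"scaler_mean_{i}"] = self.scaler_mean[i]
            arrays[f"scaler_sd_{i}"] = self.scaler_sd[i]
        np.savez(path.with_suffix(".npz"), **arrays)
        config = {
            "seed": self.seed,
            "arch": {
                "attention": asdict(self.arch.attention),
                "bridge_spec": self.arch.bridge_spec,
                "aux_heads": list(self.arch.aux_heads),
                "final_head": self.arch.final_head,
                "n_classes": self.arch.n_classes,
                "view_dims": list(self.arch.view_dims),
            },
            "train": {
                **{
                    k: v
                    for k, v in asdict(self.cfg).items()
                    if k not in ("weights", "contrastive")
                },
                "weights": asdict(self.cfg.weights),
                "contrastive": asdict(self.cfg.contrastive),
            },
            "history": [b.as_dict() for b in self.history],
        }
        path.with_suffix(".json").write_text(json.dumps(config, indent=2))

    @classmethod
    def load(cls, path) -> "CLCLSAModel":
        path = Path(path)
        config = json.loads(path.with_suffix(".json").read_text())
        arch_d = config["arch"]
        arch = Architecture(
            attention=AttentionConfig(**arch_d["attention"]),
            bridge_spec=arch_d["bridge_spec"],
            aux_heads=arch_d["aux_heads"],
            final_head=arch_d["final_head"],
            n_classes=arch_d["n_classes"],
            view_dims=tuple(arch_d["view_dims"]),
        )
        train_d = dict(config["train"])
        train_d["weights"] = LossWeights(**train_d["weights"])
        train_d["contrastive"] = ContrastiveConfig(**train_d["contrastive"])
        cfg = TrainConfig(**train_d)
        model = cls(arch, cfg, config["seed"])
        with np.load(path.with_suffix(".npz")) as data:
            state = {k: data[k] for k in data.files}
        model.load_state_dict(state)
        for i in range(len(arch.view_dims)):
            model.scaler_mean[i] = state[f"scaler_mean_{i}"]
            model.scaler_sd[i] = state[f"scaler_sd_{i}"]
        model.history = [LossBundle(**b) for b in config["history"]]
        return model


# ---------------------------------------------------------------------------
# training


def _effective_weights(weights: LossWeights, mask: np.ndarray, n_views: int) -> LossWeights:
    """Reconstruction weight is forced to 0 on complete data or a lone view."""
    if n_views < 2 or np.asarray(mask, dtype=bool).all():
        return replace(weights, lambda_co=0.0)
    return weights


def train(
    ds: OmicsDataset,
    cfg: TrainConfig | None = None,
    arch: Architecture | None = None,
    seed: int = 0,
) -> CLCLSAModel:
    """Fit the full model on a dataset; see the module docstring for the
    two-phase regime.  Deterministic for a fixed seed."""
    if ds.n_subjects == 0:
        raise ValueError("training set is empty")
    cfg = cfg or TrainConfig()
    present = np.unique(ds.labels)
    if len(present) < ds.n_classes:
        raise ValueError(
            f"training labels cover {len(present)}/{ds.n_classes} classes"
        )
    if arch is None:
        arch = Architecture.default(ds.view_dims, ds.n_classes, cfg.latent_dim, cfg.dropout)
    model = CLCLSAModel(arch, cfg, seed)
    model.fit_scaler(ds)

    weights = _effective_weights(cfg.weights, ds.mask, ds.n_views)
    complete = np.flatnonzero(ds.mask.all(axis=1))
    incomplete = np.flatnonzero(~ds.mask.all(axis=1))
    y = ds.labels
    use_bridges = model.bank is not None and (weights.lambda_co > 0 or incomplete.size > 0)

    opt = Adam(model.parameters(), lr=cfg.lr)
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * cfg.lr_decay ** (epoch // cfg.decay_every)
        clf_f = al_f = co_f = cl_f = 0.0

        if complete.size:
            views_c = [v[complete] for v in ds.views]
            block = model.encode_views(views_c, training=True)
            yc = y[complete]
            probs = model.final_head(fuse(block.latents))
            l_clf = classification_loss(probs, yc)
            if weights.lambda_al > 0 and cfg.use_attention:
                aux = [head(z) for head, z in zip(model.aux_heads, block.latents)]
                l_al = auxiliary_loss(block.omics_scores, aux, yc, cfg.confidence)
            else:
                l_al = Tensor(0.0)
            if use_bridges and weights.lambda_co > 0:
                model.bank.set_training(True)
                full = np.ones((complete.size, ds.n_views), dtype=bool)
                l_co = total_reconstruction_loss(block, model.bank, full)
            else:
                l_co = Tensor(0.0)
            if weights.lambda_cl > 0 and ds.n_views > 1:
                full = np.ones((complete.size, ds.n_views), dtype=bool)
                l_cl = contrastive_total_t(block, full, cfg.contrastive)
            else:
                l_cl = Tensor(0.0)
            total, bundle = total_loss(l_clf, l_al, l_co, l_cl, weights)
            opt.zero_grad()
            total.backward()
            opt.step()
            clf_f += bundle.l_clf
            al_f += bundle.l_al
            co_f += bundle.l_co
            cl_f += bundle.l_cl

        if incomplete.size:
            views_i = [v[incomplete] for v in ds.views]
            mask_i = ds.mask[incomplete]
            yi = y[incomplete]
            block = model.encode_views(views_i, training=True)
            if cfg.detach_imputed:
                kept = LatentBlock(
                    [z.detach() for z in block.latents],
                    block.omics_scores,
                    block.feature_scores,
                )
                completed = model.complete_latents(kept, mask_i)
                # observed latents keep their gradient path; imputed ones are constants
                merged = [
                    z * Tensor(mask_i[:, i:i + 1].astype(float))
                    + c.detach() * Tensor(1.0 - mask_i[:, i:i + 1].astype(float))
                    for i, (z, c) in enumerate(zip(block.latents, completed.latents))
                ]
                block = LatentBlock(merged, block.omics_scores, block.feature_scores)
            else:
                block = model.complete_latents(block, mask_i)
            probs = model.final_head(fuse(block.latents))
            l_clf = classification_loss(probs, yi)
            l_al = Tensor(0.0)
            if weights.lambda_al > 0 and cfg.use_attention:
                for i in range(ds.n_views):
                    rows = np.flatnonzero(mask_i[:, i])
                    if rows.size == 0:
                        continue
                    aux_p = model.aux_heads[i](block.latents[i][rows])
                    l_al = l_al + auxiliary_loss(
                        [block.omics_scores[i][rows]], [aux_p], yi[rows], cfg.confidence
                    )
            total, bundle2 = total_loss(l_clf, l_al, 0.0, 0.0, weights)
            opt.zero_grad()
            total.backward()
            opt.step()
            clf_f += bundle2.l_clf
            al_f += bundle2.l_al

        epoch_total = (
            clf_f
            + weights.lambda_al * al_f
            + weights.lambda_co * co_f
            + weights.lambda_cl * cl_f
        )
        if not np.isfinite(epoch_total):
            raise TrainingDivergenceError(f"training diverged at epoch {epoch}")
        model.history.append(LossBundle(clf_f, al_f, co_f, cl_f, epoch_total))

    model.set_training(False)
    return model


def predict(model: CLCLSAModel, ds: OmicsDataset) -> np.ndarray:
    """Class probabilities in eval mode (dropout off, BN running statistics;
    missing views imputed per the model's configuration)."""
    return model.predict_proba(ds)


# ---------------------------------------------------------------------------
# grid search


def grid_search(
    ds: OmicsDataset,
    lambda_grid=LAMBDA_GRID,
    seeds=(0,),
    val_fraction: float = 0.25,
    cfg: TrainConfig | None = None,
    split_seed: int = 0,
):
    """Exhaustive search over the (lambda_al, lambda_co, lambda_cl) grid.

    The reconstruction weight dimension collapses to {0} when the dataset is
    complete.  Returns the best :class:`LossWeights` (argmax mean validation
    accuracy; ties broken by F1 then by smaller weight sum) and the tidy
    score table with one row per configuration and seed.
    """
    from .evaluation import compute_metrics  # local import to avoid a cycle

    if not lambda_grid:
        raise ValueError("lambda_grid must be non-empty")
    cfg = cfg or TrainConfig.desk_scale(150)
    ds_train, ds_val = split_dataset(ds, 1.0 - val_fraction, seed=split_seed)
    co_grid = (0.0,) if ds.mask.all() else tuple(lambda_grid)
    rows = []
    for lam_al, lam_co, lam_cl in product(lambda_grid, co_grid, lambda_grid):
        for seed in seeds:
            run_cfg = replace(
                cfg, weights=LossWeights(lam_al, lam_co, lam_cl)
            )
            model = train(ds_train, run_cfg, seed=seed)
            report = compute_metrics(predict(model, ds_val), ds_val.labels)
            f1 = report.f1 if report.f1 is not None else report.weighted_f1
            rows.append(
                {
                    "lambda_al": lam_al,
                    "lambda_co": lam_co,
                    "lambda_cl": lam_cl,
                    "seed": seed,
                    "acc": report.acc,
                    "f1": f1,
                }
            )
    table = pd.DataFrame(rows)
    agg = (
        table.groupby(["lambda_al", "lambda_co", "lambda_cl"])[["acc", "f1"]]
        .mean()
        .reset_index()
    )
    agg["lam_sum"] = agg.lambda_al + agg.lambda_co + agg.lambda_cl
    agg = agg.sort_values(
        by=["acc", "f1", "lam_sum"], ascending=[False, False, True]
    ).reset_index(drop=True)
    best = agg.iloc[0]
    return LossWeights(best.lambda_al, best.lambda_co, best.lambda_cl), table
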