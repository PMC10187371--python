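"""Classification metrics and the experiment harnesses.

Metrics: accuracy for all tasks; binary tasks additionally report the
positive-class (class 1) F1 and the rank-statistic AUC on class-1 scores;
multiclass tasks report support-weighted and macro-averaged F1.  The
harnesses reproduce the study designs around the method: a missing-rate
sweep, an omics-combination ablation, and a loss-component ablation — each
emitting a tidy table with one row per run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from .data_model import OmicsDataset, make_missing_mask, split_dataset
from .training import LossWeights, TrainConfig, predict, train

__all__ = [
    "MetricReport",
    "UndefinedMetricError",
    "compute_metrics",
    "missing_rate_sweep",
    "omics_combination_ablation",
    "component_ablation",
    "plot_metric_curves",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given labels (e.g. AUC on one class)."""


@dataclass
class MetricReport:
    """Metric values for one evaluation; binary fields are None unless C=2."""

    acc: float
    f1: float | None
    auc: float | None
    weighted_f1: float
    macro_f1: float
    n_test: int

    def as_dict(self):
        return asdict(self)


def compute_metrics(probs: np.ndarray, labels: np.ndarray) -> MetricReport:
    """Score probability predictions against integer labels."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.ndim != 2 or probs.shape[0] != labels.shape[0]:
        raise ValueError(f"probs {probs.shape} do not match {labels.shape[0]} labels")
    n_classes = probs.shape[1]
    if n_classes < 2:
        raise ValueError("need at least two classes")
    pred = probs.argmax(axis=1)
    acc = float(accuracy_score(labels, pred))
    weighted = float(f1_score(labels, pred, average="weighted", zero_division=0))
    macro = float(f1_score(labels, pred, average="macro", zero_division=0))
    f1 = auc = None
    if n_classes == 2:
        f1 = float(f1_score(labels, pred, pos_label=1, zero_division=0))
        if len(np.unique(labels)) < 2:
            raise UndefinedMetricError("AUC is undefined when only one class is present")
        auc = float(roc_auc_score(labels, probs[:, 1]))
    return MetricReport(acc, f1, auc, weighted, macro, n_test=len(labels))


# ---------------------------------------------------------------------------
# harnesses


def _run_once(
    ds: OmicsDataset,
    eta: float,
    seed: int,
    cfg: TrainConfig,
    train_fraction: float,
    split_seed: int,
    mask_test: bool,
) -> MetricReport:
    """Split, mask train (and optionally test) at rate eta, train, evaluate."""
    ds_train, ds_test = split_dataset(ds, train_fraction, seed=split_seed)
    if eta > 0:
        m_train = make_missing_mask(ds_train.n_subjects, ds.n_views, eta, seed=seed)
        ds_train = ds_train.with_mask(m_train)
        if mask_test:
            m_test = make_missing_mask(
                ds_test.n_subjects, ds.n_views, eta, seed=seed + 100_003
            )
            ds_test = ds_test.with_mask(m_test)
    model = train(ds_train, cfg, seed=seed)
    return compute_metrics(predict(model, ds_test), ds_test.labels)


def missing_rate_sweep(
    ds: OmicsDataset,
    etas=tuple(np.round(np.arange(0.1, 0.81, 0.1), 1)),
    seeds=(0,),
    cfg: TrainConfig | None = None,
    train_fraction: float = 0.7,
    split_seed: int = 0,
    mask_test: bool = True,
) -> pd.DataFrame:
    """Train and evaluate at each missing rate; tidy table of metrics.

    By default the test subjects are masked at the same rate as training,
    measuring performance *on* incomplete data; pass ``mask_test=False`` to
    evaluate on complete test data instead.
    """
    cfg = cfg or TrainConfig.desk_scale(150)
    rows = []
    for eta in etas:
        if not 0.0 <= eta < 1.0:
            raise ValueError(f"eta must be in [0, 1), got {eta}")
        for seed in seeds:
            report = _run_once(
                ds, float(eta), seed, cfg, train_fraction, split_seed, mask_test
            )
            rows.append({"eta": float(eta), "seed": seed, **report.as_dict()})
    return pd.DataFrame(rows)


def omics_combination_ablation(
    ds: OmicsDataset,
    combos=None,
    etas=(0.0,),
    seeds=(0,),
    cfg: TrainConfig | None = None,
    train_fraction: float = 0.7,
    split_seed: int = 0,
    mask_test: bool = True,
) -> pd.DataFrame:
    """Train on subsets of omics layers (full set plus all pairs by default)."""
    cfg = cfg or TrainConfig.desk_scale(150)
    if combos is None:
        m = ds.n_views
        combos = [tuple(range(m))] + [c for c in combinations(range(m), 2)] if m > 2 else [
            tuple(range(m))
        ]
    rows = []
    for combo in combos:
        if len(combo) == 0:
            raise ValueError("an omics combination must contain at least one view")
        sub = ds.select_views(combo)
        combo_name = "+".join(sub.view_names)
        combo_cfg = cfg
        if len(combo) == 1:
            combo_cfg = replace(cfg, weights=replace(cfg.weights, lambda_co=0.0))
        for eta in etas:
            for seed in seeds:
                run_eta = float(eta) if len(combo) > 1 else 0.0
                report = _run_once(
                    sub, run_eta, seed, combo_cfg, train_fraction, split_seed, mask_test
                )
                rows.append(
                    {"combo": combo_name, "eta": float(eta), "seed": seed, **report.as_dict()}
                )
    return pd.DataFrame(rows)


def component_ablation(
    ds: OmicsDataset,
    eta: float = 0.3,
    seeds=(0,),
    cfg: TrainConfig | None = None,
    lambda_co: float = 0.1,
    train_fraction: float = 0.7,
    split_seed: int = 0,
    mask_test: bool = True,
    configs=("plain", "ctst", "aux", "ctst+aux"),
) -> pd.DataFrame:
    """Four-way loss-component ablation at a fixed missing rate.

    ``plain`` removes the contrastive loss, the auxiliary loss and both
    attention gates; ``ctst`` keeps only the contrastive loss; ``aux`` keeps
    only the attention gating and its auxiliary loss; ``ctst+aux`` is the
    full model.  The reconstruction weight stays fixed (default 0.1) since
    the bridges are required to handle incomplete data at all.
    """
    cfg = cfg or TrainConfig.desk_scale(150)
    base = cfg.weights
    all_configs = {
        "plain": replace(
            cfg,
            weights=LossWeights(0.0, lambda_co, 0.0),
            use_attention=False,
        ),
        "ctst": replace(
            cfg,
            weights=LossWeights(0.0, lambda_co, base.lambda_cl or 0.01),
            use_attention=False,
        ),
        "aux": replace(
            cfg,
            weights=LossWeights(base.lambda_al or 0.1, lambda_co, 0.0),
            use_attention=True,
        ),
        "ctst+aux": replace(
            cfg,
            weights=LossWeights(
                base.lambda_al or 0.1, lambda_co, base.lambda_cl or 0.01
            ),
            use_attention=True,
        ),
    }
    unknown = set(configs) - set(all_configs)
    if unknown:
        raise ValueError(f"unknown ablation configs: {sorted(unknown)}")
    rows = []
    for name in configs:
        run_cfg = all_configs[name]
        for seed in seeds:
            report = _run_once(
                ds, eta, seed, run_cfg, train_fraction, split_seed, mask_test
            )
            rows.append({"config": name, "eta": eta, "seed": seed, **report.as_dict()})
    return pd.DataFrame(rows)


def plot_metric_curves(table: pd.DataFrame, metric: str = "acc", by: str = "eta", hue=None):
    """Mean-over-seeds curve plot of a harness table; returns the Axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    if hue is None:
        mean = table.groupby(by)[metric].mean()
        ax.plot(mean.index, mean.values, marker="o")
    else:
        for key, group in table.groupby(hue):
            mean = group.groupby(by)[metric].mean()
            ax.plot(mean.index, mean.values, marker="o", label=str(key))
        ax.legend()
    ax.set_xlabel(by)
    ax.set_ylabel(metric)
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    return ax
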