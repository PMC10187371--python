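"""Multi-omics dataset container, CSV I/O, availability masks and splitting.

A dataset is M per-omics feature matrices over the same N subjects, a class
label per subject, and an N x M boolean availability mask recording which
omics layers were measured for each subject.  Missingness is represented
only through the mask: feature matrices stay rectangular with placeholder
zeros in unavailable rows, which are never read while the mask is false.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsDataset",
    "AvailabilityMask",
    "DatasetError",
    "DimensionMismatchError",
    "FeatureParseError",
    "LabelError",
    "StratificationError",
    "read_dataset",
    "read_manifest",
    "write_dataset",
    "make_missing_mask",
    "split_dataset",
]


class DatasetError(ValueError):
    """Base class for dataset construction/validation failures."""


class DimensionMismatchError(DatasetError):
    """Feature files or arrays disagree on the number of subjects."""


class FeatureParseError(DatasetError):
    """A feature cell could not be parsed as a number."""


class LabelError(DatasetError):
    """Labels are not a contiguous set of non-negative class indices."""


class StratificationError(DatasetError):
    """A class is too small to stratify the requested split."""


@dataclass
class AvailabilityMask:
    """N x M boolean availability with its achieved missing rate.

    The missing rate eta is the fraction of subjects lacking at least one
    omics layer (incomplete subjects / N).  Every subject retains at least
    one available layer.
    """

    entries: np.ndarray
    eta: float

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=bool)
        if self.entries.ndim != 2:
            raise DatasetError("mask must be a 2-D subject-by-omics array")
        if not self.entries.any(axis=1).all():
            raise DatasetError("every subject must have at least one available omics layer")
        achieved = float((~self.entries.all(axis=1)).mean()) if len(self.entries) else 0.0
        if abs(achieved - self.eta) > 1e-12:
            raise DatasetError(
                f"declared eta {self.eta} does not match mask ({achieved:.6f})"
            )


@dataclass
class OmicsDataset:
    """M omics views over N shared subjects with labels and availability."""

    views: list
    labels: np.ndarray
    mask: np.ndarray
    view_names: list
    n_classes: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.views = [np.asarray(v, dtype=np.float64) for v in self.views]
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = len(self.labels)
        for name, v in zip(self.view_names, self.views):
            if v.ndim != 2 or v.shape[0] != n:
                raise DimensionMismatchError(
                    f"view {name!r} has shape {v.shape}, expected ({n}, features)"
                )
            if v.shape[1] < 1:
                raise DimensionMismatchError(f"view {name!r} has no features")
        if len(self.view_names) != len(self.views):
            raise DatasetError("view_names length must match number of views")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n, len(self.views)):
            raise DimensionMismatchError(
                f"mask shape {self.mask.shape} != ({n}, {len(self.views)})"
            )
        if n and not self.mask.any(axis=1).all():
            raise DatasetError("every subject needs at least one available omics layer")
        if n:
            if self.labels.min() < 0 or self.labels.max() >= self.n_classes:
                raise LabelError(
                    f"labels must lie in [0, {self.n_classes - 1}], "
                    f"found range [{self.labels.min()}, {self.labels.max()}]"
                )

    # -- basic introspection ----------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def view_dims(self) -> tuple:
        return tuple(v.shape[1] for v in self.views)

    @property
    def eta(self) -> float:
        """Achieved missing rate: fraction of subjects with >=1 missing view."""
        if self.n_subjects == 0:
            return 0.0
        return float((~self.mask.all(axis=1)).mean())

    # -- derived datasets --------------------------------------------------
    def subset(self, indices: np.ndarray) -> "OmicsDataset":
        indices = np.asarray(indices)
        return OmicsDataset(
            views=[v[indices] for v in self.views],
            labels=self.labels[indices],
            mask=self.mask[indices],
            view_names=list(self.view_names),
            n_classes=self.n_classes,
            metadata=dict(self.metadata),
        )

    def select_views(self, view_indices) -> "OmicsDataset":
        """Restrict to a subset of omics layers (for combination ablations).

        Subjects left with no available layer after the restriction are
        dropped, mirroring a study that never enrolled them.
        """
        view_indices = list(view_indices)
        if not view_indices:
            raise DatasetError("at least one view must be selected")
        mask = self.mask[:, view_indices]
        keep = mask.any(axis=1)
        return OmicsDataset(
            views=[self.views[i][keep] for i in view_indices],
            labels=self.labels[keep],
            mask=mask[keep],
            view_names=[self.view_names[i] for i in view_indices],
            n_classes=self.n_classes,
            metadata=dict(self.metadata),
        )

    def with_mask(self, mask: AvailabilityMask) -> "OmicsDataset":
        return OmicsDataset(
            views=[v.copy() for v in self.views],
            labels=self.labels.copy(),
            mask=mask.entries.copy(),
            view_names=list(self.view_names),
            n_classes=self.n_classes,
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# CSV I/O


def _read_feature_csv(path: Path) -> np.ndarray:
    """Read a numeric matrix; optional header row; raise on non-numeric cells."""
    raw = pd.read_csv(path, header=None, dtype=str)
    start = 0
    try:
        raw.iloc[0].astype(np.float64)
    except (ValueError, TypeError):
        start = 1  # header row with feature names
    body = raw.iloc[start:]
    values = np.empty(body.shape, dtype=np.float64)
    for j, col in enumerate(body.columns):
        try:
            values[:, j] = body[col].astype(np.float64)
        except (ValueError, TypeError):
            for i, cell in enumerate(body[col]):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise FeatureParseError(
                        f"{path}: non-numeric value {cell!r} at row {i + start}, column {j}"
                    ) from None
    return values


def read_dataset(
    feature_paths,
    label_path,
    mask_path=None,
    view_names=None,
    n_classes: int | None = None,
) -> OmicsDataset:
    """Load a dataset from per-omics CSV matrices plus a label file.

    Parameters
    ----------
    feature_paths : list of paths, one CSV matrix (subjects x features) per omics.
    label_path : CSV with one integer class index per line.
    mask_path : optional 0/1 CSV (subjects x omics); absent means all-available.
    view_names : optional list of names, defaults to the file stems.
    n_classes : optional class count; inferred as max(label)+1 when omitted.
    """
    feature_paths = [Path(p) for p in feature_paths]
    views = [_read_feature_csv(p) for p in feature_paths]
    counts = {p.name: v.shape[0] for p, v in zip(feature_paths, views)}
    if len(set(counts.values())) > 1:
        raise DimensionMismatchError(f"feature files disagree on subject count: {counts}")

    labels_raw = pd.read_csv(label_path, header=None).iloc[:, 0].to_numpy()
    labels = np.asarray(labels_raw)
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.allclose(labels, np.round(labels)):
            raise LabelError(f"{label_path}: labels must be integers")
        labels = np.round(labels).astype(np.int64)
    if labels.min() < 0:
        raise LabelError(f"{label_path}: negative label {labels.min()}")
    if views[0].shape[0] != len(labels):
        raise DimensionMismatchError(
            f"{label_path}: {len(labels)} labels vs {views[0].shape[0]} subjects"
        )
    if n_classes is None:
        n_classes = int(labels.max()) + 1

    if mask_path is None:
        mask = np.ones((len(labels), len(views)), dtype=bool)
    else:
        mask = pd.read_csv(mask_path, header=None).to_numpy().astype(bool)

    if view_names is None:
        view_names = [p.stem for p in feature_paths]
    return OmicsDataset(views, labels, mask, view_names, n_classes)


def write_dataset(ds: OmicsDataset, out_dir) -> dict:
    """Write feature/label/mask CSVs plus a JSON manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    feature_files = []
    for name, view in zip(ds.view_names, ds.views):
        fname = f"{name}.csv"
        pd.DataFrame(view).to_csv(out_dir / fname, header=False, index=False)
        feature_files.append(fname)
    pd.DataFrame(ds.labels).to_csv(out_dir / "labels.csv", header=False, index=False)
    pd.DataFrame(ds.mask.astype(int)).to_csv(out_dir / "mask.csv", header=False, index=False)
    manifest = {
        "feature_files": feature_files,
        "label_file": "labels.csv",
        "mask_file": "mask.csv",
        "view_names": list(ds.view_names),
        "n_classes": ds.n_classes,
        "n_subjects": ds.n_subjects,
        "eta": ds.eta,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_manifest(manifest_path) -> OmicsDataset:
    """Load a dataset through its JSON manifest (as written by write_dataset)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    return read_dataset(
        [base / f for f in manifest["feature_files"]],
        base / manifest["label_file"],
        base / manifest["mask_file"] if manifest.get("mask_file") else None,
        view_names=manifest.get("view_names"),
        n_classes=manifest.get("n_classes"),
    )


# ---------------------------------------------------------------------------
# masks and splits


def make_missing_mask(
    n_subjects: int, n_views: int, eta: float, seed: int | None = None, rng=None
) -> AvailabilityMask:
    """Draw an availability mask with exactly round(eta * N) incomplete subjects.

    Each incomplete subject is missing a uniform number of views in
    {1, ..., M-1}, themselves chosen uniformly without replacement, so every
    subject keeps at least one layer.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must lie in [0, 1], got {eta}")
    if n_subjects < 1 or n_views < 1:
        raise ValueError("n_subjects and n_views must be positive")
    if n_views == 1 and eta > 0:
        raise ValueError("a single-view dataset cannot have missing views (eta > 0)")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_incomplete = int(round(eta * n_subjects))
    entries = np.ones((n_subjects, n_views), dtype=bool)
    incomplete = rng.choice(n_subjects, size=n_incomplete, replace=False)
    for j in incomplete:
        k = int(rng.integers(1, n_views))  # number of missing views in {1..M-1}
        drop = rng.choice(n_views, size=k, replace=False)
        entries[j, drop] = False
    return AvailabilityMask(entries=entries, eta=n_incomplete / n_subjects)


def split_dataset(
    ds: OmicsDataset, train_fraction: float, seed: int = 0, stratified: bool = True
):
    """Disjoint, exhaustive train/test partition of subjects (masks travel along)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    stratify = None
    if stratified:
        _, counts = np.unique(ds.labels, return_counts=True)
        if counts.min() < 2:
            raise StratificationError(
                f"smallest class has {counts.min()} subject(s); need >=2 to stratify"
            )
        stratify = ds.labels
    idx_train, idx_test = train_test_split(
        np.arange(ds.n_subjects),
        train_size=train_fraction,
        random_state=seed,
        stratify=stratify,
    )
    return ds.subset(np.sort(idx_train)), ds.subset(np.sort(idx_test))
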