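"""Reading and writing molecule tables, latent matrices, metric reports
and model checkpoints.

The on-disk conventions are deliberately plain: comma-separated CSV with a
header row (UTF-8) for molecule tables and latent matrices, `.smi` files as
whitespace-separated ``SMILES [label]`` lines, JSON for metric reports, and
a versioned ``.npz`` archive for checkpoints.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, DataError, EmptyDatasetError,
                     FormatError)

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT_VERSION = 1


class Task(str, Enum):
    classification = "classification"
    regression = "regression"


@dataclass
class QSARDataset:
    """A molecule table: SMILES strings, numeric labels, optional group ids.

    Classification labels must be 0/1.  Groups are opaque identifiers used
    by grouped cross-validation (e.g. one id per isomer pair).
    """

    smiles: list
    labels: list
    task: Task
    groups: list | None = None
    name: str = ""

    def __post_init__(self):
        self.task = Task(self.task)
        if len(self.smiles) != len(self.labels):
            raise DataError("smiles and labels must be the same length")
        if self.groups is not None and len(self.groups) != len(self.smiles):
            raise DataError("groups must align with smiles")
        if self.task is Task.classification:
            bad = set(float(y) for y in self.labels) - {0.0, 1.0}
            if bad:
                raise DataError(f"classification labels must be 0/1, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.smiles)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=float)

    def subset(self, indices) -> "QSARDataset":
        idx = list(indices)
        return QSARDataset(
            smiles=[self.smiles[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            task=self.task,
            groups=None if self.groups is None else [self.groups[i] for i in idx],
            name=self.name,
        )


@dataclass
class LatentMatrix:
    """An n x d real matrix of latent vectors, row-aligned with a dataset."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise FormatError("latent matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise FormatError("latent matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class EvalReport:
    """Per-fold metric values with their mean and standard error."""

    per_fold: list
    metric: str  # "roc_auc" | "r2"
    mean: float = field(default=None)
    sem: float = field(default=None)

    def __post_init__(self):
        folds = np.asarray(self.per_fold, dtype=float)
        if self.mean is None:
            self.mean = float(folds.mean())
        if self.sem is None:
            self.sem = sem(folds)


def sem(values) -> float:
    """Standard error of the mean: sample std (ddof=1) / sqrt(k); 0 for k < 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return 0.0
    return float(v.std(ddof=1) / math.sqrt(v.size))


def _validate_smiles(smiles_list: list) -> list:
    """Return indices of rows whose SMILES parse; import rdkit lazily."""
    from .smiles_aug import is_valid_smiles

    return [i for i, s in enumerate(smiles_list) if is_valid_smiles(s)]


def read_dataset(path, task, smiles_col: str = "smiles",
                 label_col: str = "label", group_col: str | None = None,
                 name: str | None = None) -> QSARDataset:
    """Read a molecule table from CSV or `.smi`, dropping unparsable SMILES.

    Rows whose SMILES fail to parse are dropped with a logged count rather
    than raising: public QSAR tables routinely contain a few bad rows.
    """
    path = Path(path)
    if path.suffix == ".smi":
        rows = []
        for line in path.read_text().splitlines():
            parts = line.split()
            if not parts:
                continue
            rows.append((parts[0], float(parts[1]) if len(parts) > 1 else math.nan))
        df = pd.DataFrame(rows, columns=[smiles_col, label_col])
    else:
        df = pd.read_csv(path)
    for col in [smiles_col, label_col] + ([group_col] if group_col else []):
        if col not in df.columns:
            raise ConfigurationError(f"column {col!r} not found in {path}")
    labels = pd.to_numeric(df[label_col], errors="coerce")
    if labels.isna().any():
        raise FormatError(f"non-numeric labels in column {label_col!r}")
    smiles = df[smiles_col].astype(str).tolist()
    keep = _validate_smiles(smiles)
    dropped = len(smiles) - len(keep)
    if dropped:
        logger.warning("dropped %d rows with invalid SMILES from %s", dropped, path)
    if not keep:
        raise EmptyDatasetError(f"no valid SMILES rows in {path}")
    groups = df[group_col].tolist() if group_col else None
    return QSARDataset(
        smiles=[smiles[i] for i in keep],
        labels=[float(labels.iloc[i]) for i in keep],
        task=task,
        groups=None if groups is None else [groups[i] for i in keep],
        name=name if name is not None else path.stem,
    )


def write_dataset(dataset: QSARDataset, path) -> None:
    data = {"smiles": dataset.smiles, "label": dataset.labels}
    if dataset.groups is not None:
        data["group"] = dataset.groups
    pd.DataFrame(data).to_csv(path, index=False)


def read_latents(path) -> LatentMatrix:
    """Read a headerless numeric CSV as a latent matrix."""
    try:
        values = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as e:
        raise FormatError(f"ragged or non-numeric latent matrix in {path}: {e}") from e
    return LatentMatrix(values)


def write_latents(matrix: LatentMatrix, path) -> None:
    # %.17g round-trips float64 exactly
    np.savetxt(path, matrix.values, delimiter=",", fmt="%.17g")


def write_report(report: EvalReport, path) -> None:
    payload = {
        "metric": report.metric,
        "per_fold": [float(x) for x in report.per_fold],
        "mean": float(report.mean),
        "sem": float(report.sem),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_report(path) -> EvalReport:
    payload = json.loads(Path(path).read_text())
    return EvalReport(per_fold=payload["per_fold"], metric=payload["metric"],
                      mean=payload["mean"], sem=payload["sem"])


def save_checkpoint(path, store, config) -> None:
    """Save model parameters + buffers + config as a versioned npz archive."""
    from .crnn_model import config_to_dict

    arrays = store.state_arrays()
    arrays["__meta__"] = np.frombuffer(
        json.dumps({
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": config_to_dict(config),
        }).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Return (state_arrays, config) from a checkpoint written by save_checkpoint."""
    from .crnn_model import config_from_dict

    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(arrays.pop("__meta__").tobytes().decode())
    if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise FormatError(f"unsupported checkpoint version {meta.get('format_version')}")
    return arrays, config_from_dict(meta["config"])
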