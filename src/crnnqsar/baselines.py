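"""Classical comparison models: SVM on latent vectors, random forest on
circular fingerprints.

Extended-connectivity fingerprints are order-blind by construction — any
spelling of a molecule (and, for the synthetic token analogue, any
permutation of a sequence) maps to the same bit/count vector.  That makes
the fingerprint-based random forest the natural null model for global
(order) features: on a task whose labels depend only on token order it
cannot beat chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC, SVR

from .data_io import Task
from .errors import DataError, InvalidSmilesError

SVM_GRID = {"C": [0.1, 1.0, 10.0, 100.0],
            "gamma": ["scale", 1e-3, 1e-2, 1e-1]}


@dataclass
class FingerprintSpec:
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.n_bits < 1 or self.n_bits & (self.n_bits - 1):
            raise ValueError("n_bits must be a power of two")


def ecfp(smiles: str, spec: FingerprintSpec | None = None) -> np.ndarray:
    """Morgan/ECFP bit vector; identical for every spelling of a molecule."""
    if spec is None:
        spec = FingerprintSpec()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"cannot parse SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=spec.radius,
                                                    fpSize=spec.n_bits)
    return np.asarray(gen.GetFingerprint(mol), dtype=np.uint8)


def token_count_fingerprint(sequences, vocab: int) -> np.ndarray:
    """Order-blind composition fingerprint for synthetic token sequences:
    per-sequence token counts (the sequence-world analogue of a
    composition-only molecular fingerprint)."""
    out = np.zeros((len(sequences), vocab), dtype=float)
    for i, seq in enumerate(sequences):
        counts = np.bincount(np.asarray(seq, dtype=int), minlength=vocab)
        out[i] = counts[:vocab]
    return out


def _check_labels(y: np.ndarray, task: Task) -> None:
    if Task(task) is Task.classification:
        if len(np.unique(y)) < 2:
            raise DataError("classification requires both classes present")
    elif np.var(y) == 0:
        raise DataError("regression labels have zero variance")


def fit_svm(latents: np.ndarray, labels, task: Task, seed: int = 0,
            cv: int = 3, grid: dict | None = None):
    """RBF-kernel SVM with (C, gamma) chosen by inner cross-validated grid search."""
    X = np.asarray(latents, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(y) < 20:
        raise DataError("SVM baseline requires at least 20 samples")
    _check_labels(y, task)
    grid = grid or SVM_GRID
    if Task(task) is Task.classification:
        base = SVC(kernel="rbf", random_state=seed)
        scoring = "roc_auc"
        y = y.astype(int)
    else:
        base = SVR(kernel="rbf")
        scoring = "r2"
    search = GridSearchCV(base, grid, cv=cv, scoring=scoring, n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_


def fit_rf(features: np.ndarray, labels, task: Task, seed: int = 0,
           n_estimators: int = 500):
    """Seeded random forest (500 trees by default) on fingerprint features."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    _check_labels(y, task)
    if Task(task) is Task.classification:
        model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        model.fit(X, y.astype(int))
    else:
        model = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
        model.fit(X, y)
    return model


def predict_scores_sklearn(model, X, task: Task) -> np.ndarray:
    """Class-1 score (classification) or prediction (regression) from a fitted model."""
    if Task(task) is Task.classification:
        if hasattr(model, "predict_proba"):
            return model.predict_proba(X)[:, 1]
        return model.decision_function(X)
    return model.predict(X)
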