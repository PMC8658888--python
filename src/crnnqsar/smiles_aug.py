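"""SMILES canonicalization and enumeration-based training-set augmentation.

One molecule admits many valid SMILES spellings.  Augmentation expands each
training molecule to its canonical SMILES plus `n_extra` randomly enumerated
spellings (default 9, i.e. a tenfold expansion), replicating the label.  The
test partition is never augmented — evaluation code must only pass training
rows here.

Enumeration renumbers the heavy atoms with a seeded random permutation and
writes a non-canonical SMILES from the new atom order (the standard
"SMILES enumeration" construction).  Duplicates among the random spellings
are permitted: small molecules may have fewer distinct spellings than
requested, and the expansion factor is fixed, not the distinct count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger

from .data_io import QSARDataset
from .errors import InvalidSmilesError

RDLogger.DisableLog("rdApp.*")  # silence per-row parse warnings; we report counts


@dataclass
class AugmentedDataset:
    """Expanded SMILES with labels replicated per source molecule.

    ``origin[i]`` is the index of the source molecule of row ``i`` in the
    dataset that was augmented.
    """

    smiles: list
    labels: list
    origin: list

    def __len__(self) -> int:
        return len(self.smiles)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"cannot parse SMILES: {smiles!r}")
    return mol


def is_valid_smiles(smiles: str) -> bool:
    return Chem.MolFromSmiles(smiles) is not None


def canonicalize(smiles: str) -> str:
    """Canonical SMILES under RDKit's canonicalization; deterministic and idempotent."""
    return Chem.MolToSmiles(_mol(smiles))


def enumerate_smiles(smiles: str, n_extra: int, seed: int) -> list:
    """Canonical SMILES followed by `n_extra` random enumerations.

    Every returned string canonicalizes back to the same molecule.  The
    output is a deterministic function of (smiles, n_extra, seed).
    """
    if n_extra < 0:
        raise ValueError("n_extra must be >= 0")
    mol = _mol(smiles)
    out = [Chem.MolToSmiles(mol)]
    n_atoms = mol.GetNumAtoms()
    rng = np.random.default_rng(seed)
    for _ in range(n_extra):
        if n_atoms <= 1:
            out.append(out[0])
            continue
        perm = rng.permutation(n_atoms).tolist()
        shuffled = Chem.RenumberAtoms(mol, perm)
        out.append(Chem.MolToSmiles(shuffled, canonical=False))
    return out


def augment_training_set(dataset: QSARDataset, n_extra: int = 9,
                         seed: int = 0) -> AugmentedDataset:
    """Expand every molecule to 1 + n_extra spellings, replicating labels.

    Must only ever be applied to the training partition.
    """
    if len(dataset) == 0:
        raise ValueError("cannot augment an empty dataset")
    rng = np.random.default_rng(seed)
    smiles, labels, origin = [], [], []
    for i, (s, y) in enumerate(zip(dataset.smiles, dataset.labels)):
        variants = enumerate_smiles(s, n_extra, int(rng.integers(2 ** 31)))
        smiles.extend(variants)
        labels.extend([y] * len(variants))
        origin.extend([i] * len(variants))
    return AugmentedDataset(smiles=smiles, labels=labels, origin=origin)
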