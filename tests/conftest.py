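import numpy as np
import pytest

from crnnqsar.crnn_model import CRNNConfig
from crnnqsar.data_io import QSARDataset, Task

# melting-point isomer pairs used as in-package fixtures: each pair has the
# same atoms (local features) arranged differently (global features)
ISOMER_ROWS = [
    ("CC(O)C(N)=O", 78.0, 0),       # 2-hydroxypropanamide
    ("CC(N)C(=O)O", 292.0, 0),      # alanine (decomposition temperature)
    ("COCCCOC", -82.0, 1),          # 1,3-dimethoxypropane
    ("OCCCCCO", -16.0, 1),          # 1,5-pentanediol
    ("COC(=O)c1ccccc1", -12.0, 2),  # methyl benzoate
    ("O=C(O)Cc1ccccc1", 77.0, 2),   # phenylacetic acid
]


@pytest.fixture
def isomer_dataset() -> QSARDataset:
    return QSARDataset(
        smiles=[r[0] for r in ISOMER_ROWS],
        labels=[r[1] for r in ISOMER_ROWS],
        groups=[r[2] for r in ISOMER_ROWS],
        task=Task.regression,
        name="isomer-melting-points",
    )


@pytest.fixture
def isomer_csv(tmp_path):
    path = tmp_path / "isomers.csv"
    lines = ["smiles,label,group"]
    lines += [f"{s},{y},{g}" for s, y, g in ISOMER_ROWS]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def tiny_config() -> CRNNConfig:
    """Smallest config that exercises the full conv/GRU/dense stack quickly."""
    return CRNNConfig(latent_dim=32, gru_hidden=8, dense_hidden=16)


@pytest.fixture
def tiny_regression_data():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((48, 32))
    y = rng.standard_normal(48)
    return X, y
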