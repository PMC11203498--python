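"""Activity prediction: 2533-feature molecular vectors and per-target
gradient-boosted pXC50 regressors.

The feature vector concatenates, in fixed order:

* a 2048-bit FCFP6 fingerprint (functional-class circular fingerprint,
  radius 3, folded to 2048 bits),
* the 166 MACCS structural keys (bit 0 of the toolkit's 167-bit vector is
  unused and dropped),
* 319 continuous molecular descriptors pinned by the frozen manifest in
  :mod:`targen.qsar_manifest`.

Non-finite descriptor values are replaced by 0.0 (the documented sentinel).
The regressor is LightGBM with library defaults, a fixed seed and a single
thread, which makes training and prediction deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

from .metrics import classify_activity
from .qsar_manifest import DESCRIPTOR_MANIFEST

__all__ = ["N_FEATURES", "QSARModel", "featurize", "train_qsar",
           "predict_and_rank"]

N_FCFP = 2048
N_MACCS = 166
N_DESC = len(DESCRIPTOR_MANIFEST)
N_FEATURES = N_FCFP + N_MACCS + N_DESC  # 2533

_DESC_FUNCS = dict(Descriptors._descList)
_FCFP_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=3, fpSize=N_FCFP,
    atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen())


def _descriptor_values(mol: Chem.Mol) -> np.ndarray:
    mqn = rdMolDescriptors.MQNs_(mol)
    autocorr = rdMolDescriptors.CalcAUTOCORR2D(mol)
    out = np.empty(N_DESC)
    for i, name in enumerate(DESCRIPTOR_MANIFEST):
        if name.startswith("MQN"):
            out[i] = mqn[int(name[3:]) - 1]
        elif name.startswith("AUTOCORR2D_"):
            out[i] = autocorr[int(name[11:]) - 1]
        else:
            try:
                out[i] = _DESC_FUNCS[name](mol)
            except Exception:
                out[i] = np.nan
    out[~np.isfinite(out)] = 0.0
    return out


def featurize(smiles: str) -> np.ndarray:
    """2533-long feature vector: FCFP6 | MACCS(1..166) | descriptors."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    fcfp = np.frombuffer(
        _FCFP_GEN.GetFingerprint(mol).ToBitString().encode(), "u1") - ord("0")
    maccs = np.frombuffer(
        MACCSkeys.GenMACCSKeys(mol).ToBitString().encode(), "u1") - ord("0")
    return np.concatenate([
        fcfp.astype(np.float64),
        maccs[1:].astype(np.float64),     # bit 0 is a placeholder
        _descriptor_values(mol),
    ])


def featurize_many(smiles_list: list[str]) -> np.ndarray:
    return np.vstack([featurize(s) for s in smiles_list])


@dataclass
class QSARModel:
    """One gradient-boosted regressor per target, with training metadata."""

    target_id: int
    regressor: LGBMRegressor
    n_train: int
    seed: int
    hyperparameters: dict = field(default_factory=dict)

    def predict(self, smiles_list: list[str]) -> np.ndarray:
        X = featurize_many(smiles_list)
        with warnings.catch_warnings():
            # the booster records positional feature names at fit time;
            # prediction from a plain array is intentional
            warnings.simplefilter("ignore", UserWarning)
            return self.regressor.predict(X)


def train_qsar(data: pd.DataFrame, target_id: int, seed: int = 0,
               **lgbm_params) -> QSARModel:
    """Fit a pXC50 regressor on a dataframe with smiles and pxc50 columns.

    Requires at least 50 labelled molecules; hyperparameters are library
    defaults unless overridden.
    """
    if len(data) < 50:
        raise ValueError(f"need >= 50 labelled molecules, got {len(data)}")
    if "pxc50" not in data.columns:
        raise ValueError("training data must carry a 'pxc50' column")
    params = {"random_state": seed, "n_jobs": 1, "verbose": -1, **lgbm_params}
    reg = LGBMRegressor(**params)
    X = featurize_many(list(data["smiles"]))
    reg.fit(X, np.asarray(data["pxc50"], dtype=float))
    return QSARModel(target_id=target_id, regressor=reg, n_train=len(data),
                     seed=seed, hyperparameters=params)


def predict_and_rank(model: QSARModel, smiles_list: list[str],
                     top: int | None = None) -> pd.DataFrame:
    """Predicted pXC50 + activity class, sorted by descending activity.

    Ties break by ascending canonical SMILES so rankings are stable.
    """
    preds = model.predict(smiles_list)
    canon = [Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in smiles_list]
    df = pd.DataFrame({"smiles": smiles_list, "canonical": canon,
                       "pxc50": preds})
    df["activity_class"] = [classify_activity(v) for v in df["pxc50"]]
    df = df.sort_values(["pxc50", "canonical"],
                        ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    return df.head(top) if top is not None else df
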