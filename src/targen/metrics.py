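"""Generation-quality arithmetic and physicochemical profiling.

Implements the three headline set metrics — Valid, Unique@k, Novel — the
1-Wasserstein distance used to compare property distributions against a
reference set, per-molecule property profiles (MW, TPSA, LogP, HBD, HBA,
QED, SA), the drug-like "good range" report, and pXC50 activity classes.

Novel here is the *generated-set perspective*: the fraction of valid
generated molecules that never occur in the training set (not the older
training-set-coverage definition).  All duplicate and novelty comparisons
key on canonical SMILES.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, Descriptors, QED, rdMolDescriptors
from scipy.stats import wasserstein_distance

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib synthetic-accessibility scorer)

__all__ = [
    "MetricInputs", "PropertyProfile", "GOOD_RANGES", "ACTIVITY_CLASSES",
    "valid_fraction", "unique_fraction", "novel_fraction", "wasserstein_1d",
    "property_profile", "good_range_report", "classify_activity",
    "evaluate_generation",
]

#: Closed "good" drug-like intervals per property.
GOOD_RANGES: dict[str, tuple[float, float]] = {
    "MW": (200.0, 500.0),
    "TPSA": (20.0, 130.0),
    "LogP": (-1.0, 6.0),
    "HBD": (0.0, 5.0),
    "HBA": (0.0, 10.0),
    "QED": (0.4, 1.0),
    "SA": (1.0, 5.0),
}

#: pXC50 class boundaries: low < 6 ≤ middle < 7 ≤ high < 8 ≤ ultra-high.
ACTIVITY_CLASSES = ("low", "middle", "high", "ultra-high")


@dataclass
class MetricInputs:
    """The named sets of the metric definitions.

    G: all generated strings (a = n(G)); P: the valid subset (b = n(P));
    S: a size-c subsample of P; U: S deduplicated (e = n(U));
    X: the training set (h = n(X)); Z: the members of P absent from X.
    """

    G: list[str]
    P: list[str]
    S: list[str]
    U: list[str]
    X: list[str]
    Z: list[str]


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def valid_fraction(G: list[str]) -> tuple[float, list[str]]:
    """Eq. n(P)/n(G): fraction of generated strings that parse as molecules.

    Validity is toolkit parseability (syntactic + valence checks).  Returns
    the fraction and the valid subset P in generation order.
    """
    if not G:
        raise ValueError("empty generation set")
    P = [s for s in G if Chem.MolFromSmiles(s) is not None]
    return len(P) / len(G), P


def unique_fraction(P: list[str], c: int = 1000, seed: int = 0) -> float:
    """n(U)/n(S) on a size-``c`` random subsample S of the valid set P.

    Deduplication keys on canonical SMILES.  Raises if P has fewer than
    ``c`` members.
    """
    if len(P) < c:
        raise ValueError(f"valid set has {len(P)} < c={c} molecules")
    rng = np.random.default_rng(seed)
    S = [P[i] for i in rng.choice(len(P), size=c, replace=False)]
    U = {_canonical(s) for s in S}
    return len(U) / len(S)


def novel_fraction(P: list[str], X: list[str]) -> float:
    """n(Z)/n(P): fraction of valid generated molecules not in the training
    set, both sides compared by canonical SMILES."""
    if not P:
        raise ValueError("empty valid set")
    train = {_canonical(x) for x in X}
    Z = [p for p in P if _canonical(p) not in train]
    return len(Z) / len(P)


def wasserstein_1d(sample_a, sample_b) -> float:
    """Empirical 1-Wasserstein distance between two 1-D samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    return float(wasserstein_distance(a, b))


@dataclass(frozen=True)
class PropertyProfile:
    """Physicochemical profile of one molecule."""

    MW: float
    TPSA: float
    LogP: float
    HBD: int
    HBA: int
    QED: float
    SA: float


def property_profile(smiles: str) -> PropertyProfile:
    """Toolkit-computed descriptors; deterministic per molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return PropertyProfile(
        MW=float(Descriptors.MolWt(mol)),
        TPSA=float(rdMolDescriptors.CalcTPSA(mol)),
        LogP=float(Crippen.MolLogP(mol)),
        HBD=int(rdMolDescriptors.CalcNumHBD(mol)),
        HBA=int(rdMolDescriptors.CalcNumHBA(mol)),
        QED=float(QED.qed(mol)),
        SA=float(sascorer.calculateScore(mol)),
    )


def good_range_report(profiles: list[PropertyProfile]) -> dict[str, float]:
    """Percentage of molecules inside the closed good interval, per property."""
    if not profiles:
        raise ValueError("empty profile list")
    report = {}
    for prop, (lo, hi) in GOOD_RANGES.items():
        vals = np.array([getattr(p, prop) for p in profiles], dtype=float)
        report[prop] = float(100.0 * np.mean((vals >= lo) & (vals <= hi)))
    return report


def classify_activity(pxc50: float) -> str:
    """pXC50 → class with left-closed boundaries [6,7), [7,8), [8,∞)."""
    if not np.isfinite(pxc50):
        raise ValueError(f"non-finite pXC50 value {pxc50}")
    if pxc50 < 6:
        return "low"
    if pxc50 < 7:
        return "middle"
    if pxc50 < 8:
        return "high"
    return "ultra-high"


def evaluate_generation(generated: list[str], train: list[str],
                        reference: dict[str, list[float]] | None = None,
                        unique_sizes: tuple[int, ...] = (1000,),
                        seed: int = 0) -> dict:
    """Full metric report for a generated SMILES set.

    ``reference`` optionally maps property names to value samples from a
    reference set (e.g. the held-out test split); 1-Wasserstein distances of
    the generated property distributions against it are then included.
    """
    valid, P = valid_fraction(generated)
    report: dict = {"n_generated": len(generated), "valid": valid,
                    "novel": novel_fraction(P, train) if P else None}
    for c in unique_sizes:
        if len(P) >= c:
            report[f"unique@{c}"] = unique_fraction(P, c, seed=seed)
    profiles = [property_profile(s) for s in P if s]
    if profiles:
        report["good_ranges"] = good_range_report(profiles)
        if reference:
            report["wasserstein"] = {
                prop: wasserstein_1d([getattr(p, prop) for p in profiles],
                                     reference[prop])
                for prop in reference
            }
    return report
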