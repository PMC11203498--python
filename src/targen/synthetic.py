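"""Desk-scale synthetic stand-ins for the pre-training corpus and the
target-labelled fine-tuning sets.

The generator exploits the robustness of the string grammar: molecules are
drawn as random symbol sequences, so *every* record decodes to a valid
molecule by construction.  Target-specific sets are produced by biasing the
per-symbol sampling distribution toward a small set of preferred tokens per
target, which makes the three conditional distributions statistically
distinguishable — the property the conditioning-recovery tests rely on.

Per-molecule activity labels emulate pXC50 potencies: a deterministic
function of the preferred-token fraction plus Gaussian noise,

    pxc50 = 4 + 6 · (fraction of tokens in preferred_tokens) + N(0, noise_sd)

clipped to [4, 10], so a molecule made entirely of a target's preferred
tokens anchors at 10 and one containing none anchors at 4, with the midpoint
0.5 landing exactly on the 'high' activity-class boundary of 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import grammar
from .codec import selfies_to_smiles
from .grammar import split_symbols

__all__ = [
    "DEFAULT_ALPHABET", "TargetProfile", "SyntheticDataset",
    "default_profiles", "generate_corpus", "generate_target_sets",
    "synthetic_activity", "token_histogram",
]

#: Default chemical alphabet for random molecules: the common organic atoms
#: with single/double bond variants plus branching and ring formation.
DEFAULT_ALPHABET: tuple[str, ...] = (
    "[C]", "[=C]", "[N]", "[=N]", "[O]", "[=O]",
    "[F]", "[S]", "[Cl]", "[Br]", "[Branch1]", "[Ring1]",
)

#: Default token-length range of random molecules (before specials).
DEFAULT_LENGTH_RANGE: tuple[int, int] = (8, 36)


@dataclass(frozen=True)
class TargetProfile:
    """Sampling profile of one protein target.

    ``bias`` multiplies the probability mass of each preferred token
    relative to the uniform baseline (bias = 1 recovers uniform sampling).
    """

    target_id: int
    preferred_tokens: tuple[str, ...]
    bias: float = 5.0
    n_molecules: int = 300
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET

    def __post_init__(self):
        if self.target_id not in (1, 2, 3):
            raise ValueError("target_id must be 1, 2 or 3")
        if self.bias < 1:
            raise ValueError("bias must be >= 1")
        unknown = set(self.preferred_tokens) - set(self.alphabet)
        if unknown:
            raise ValueError(f"preferred tokens not in alphabet: {unknown}")

    def token_probabilities(self) -> np.ndarray:
        """Closed-form per-token sampling probabilities."""
        w = np.ones(len(self.alphabet))
        for i, t in enumerate(self.alphabet):
            if t in self.preferred_tokens:
                w[i] = self.bias
        return w / w.sum()


def default_profiles() -> list[TargetProfile]:
    """The three default target profiles (ids 1/2/3 ≙ EGFR/HTR1A/S1PR1).

    Set sizes 300/600/150 preserve the relative ordering of the real
    fine-tuning sets (1381/3585/795 molecules) at desk scale; preferred
    tokens are element-distinct so each target leaves a recoverable
    compositional signature.
    """
    return [
        TargetProfile(1, ("[N]", "[=N]"), bias=5.0, n_molecules=300),
        TargetProfile(2, ("[O]", "[=O]"), bias=5.0, n_molecules=600),
        TargetProfile(3, ("[S]", "[Cl]"), bias=5.0, n_molecules=150),
    ]


@dataclass
class SyntheticDataset:
    """Records + provenance for a generated molecule set."""

    records: pd.DataFrame  # columns: smiles, selfies, target [, pxc50], split
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split].reset_index(drop=True)


def _random_selfies(rng: np.random.Generator, alphabet: tuple[str, ...],
                    probs: np.ndarray | None, length_range: tuple[int, int]) -> str:
    lo, hi = length_range
    n = int(rng.integers(lo, hi + 1))
    idx = rng.choice(len(alphabet), size=n, p=probs)
    return "".join(alphabet[i] for i in idx)


def _assign_split(n: int, rng: np.random.Generator,
                  valid_fraction: float = 0.1) -> np.ndarray:
    """9:1 train/valid assignment, honoured within rounding."""
    n_valid = int(round(n * valid_fraction))
    split = np.array(["train"] * n, dtype=object)
    split[rng.choice(n, size=n_valid, replace=False)] = "valid"
    return split


def generate_corpus(n: int = 5000,
                    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
                    alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
                    seed: int = 0) -> SyntheticDataset:
    """Unconditional pre-training corpus of ``n`` random valid molecules.

    Token lengths are uniform on ``length_range`` and tokens i.i.d. uniform
    on ``alphabet``; the same seed reproduces the dataset byte for byte.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not alphabet:
        raise ValueError("alphabet must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        sf = _random_selfies(rng, tuple(alphabet), None, length_range)
        rows.append({"smiles": selfies_to_smiles(sf), "selfies": sf, "target": 0})
    df = pd.DataFrame(rows)
    df["split"] = _assign_split(n, rng)
    return SyntheticDataset(records=df, seed=seed)


def preferred_token_fraction(selfies: str, profile: TargetProfile) -> float:
    """Fraction of preferred tokens in the molecule's *canonical* encoding.

    The raw sampled string may contain tokens the derivation rules discard
    (a saturated chain stops growing), so the label is computed on the
    re-encoding of the decoded molecule: activity is a function of the
    structure, which is what a structure-based activity model must recover.
    """
    mol = grammar.decode_to_mol(split_symbols(selfies))
    if mol is None:
        return 0.0
    effective = grammar.encode_mol(mol)
    return sum(s in profile.preferred_tokens for s in effective) / len(effective)


def synthetic_activity(selfies: str, profile: TargetProfile,
                       noise_sd: float = 0.3,
                       rng: np.random.Generator | None = None) -> float:
    """Emulated pXC50 label; monotone in the preferred-token fraction."""
    frac = preferred_token_fraction(selfies, profile)
    value = 4.0 + 6.0 * frac
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        value += float(rng.normal(0.0, noise_sd))
    return float(np.clip(value, 4.0, 10.0))


def generate_target_sets(profiles: list[TargetProfile] | None = None,
                         seed: int = 0,
                         noise_sd: float = 0.3) -> SyntheticDataset:
    """Target-labelled fine-tuning sets with pXC50 labels.

    Each target's set is drawn from its biased token distribution and split
    9:1 train/valid *per target* before concatenation.
    """
    if profiles is None:
        profiles = default_profiles()
    ids = [p.target_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate target_id in profiles: {ids}")
    rng = np.random.default_rng(seed)
    frames = []
    for profile in profiles:
        probs = profile.token_probabilities()
        rows = []
        for _ in range(profile.n_molecules):
            sf = _random_selfies(rng, profile.alphabet, probs, profile.length_range)
            rows.append({
                "smiles": selfies_to_smiles(sf),
                "selfies": sf,
                "target": profile.target_id,
                "pxc50": synthetic_activity(sf, profile, noise_sd, rng),
            })
        df = pd.DataFrame(rows)
        df["split"] = _assign_split(len(df), rng)
        frames.append(df)
    return SyntheticDataset(records=pd.concat(frames, ignore_index=True), seed=seed)


def token_histogram(selfies_list, alphabet: tuple[str, ...]) -> np.ndarray:
    """Normalised token frequency vector over ``alphabet`` (others ignored)."""
    pos = {t: i for i, t in enumerate(alphabet)}
    counts = np.zeros(len(alphabet))
    for sf in selfies_list:
        for s in split_symbols(sf):
            if s in pos:
                counts[pos[s]] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts
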