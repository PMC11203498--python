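"""SMILES ↔ robust-string conversion, vocabulary and integer tokenization.

The vocabulary reserves three special tokens at fixed indices — PAD (0),
SOS (1), EOS (2) — followed by the chemical symbols of the corpus in
lexicographic order, so the same corpus always yields the same vocabulary.
PAD never appears inside a sequence and is excluded from loss computation
downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

from . import grammar
from .grammar import DecodeError, EncodeError, split_symbols

__all__ = [
    "PAD", "SOS", "EOS", "SPECIALS",
    "ConversionError", "TokenizationError",
    "TokenVocabulary", "TokenSequence",
    "smiles_to_selfies", "selfies_to_smiles", "canonical_smiles",
    "build_vocabulary", "tokenize", "detokenize",
    "read_molecules", "write_molecules",
]

PAD = "<PAD>"
SOS = "<SOS>"
EOS = "<EOS>"
SPECIALS = (PAD, SOS, EOS)

PAD_INDEX = 0
SOS_INDEX = 1
EOS_INDEX = 2


class ConversionError(ValueError):
    """A SMILES record could not be converted to the string grammar."""


class TokenizationError(KeyError):
    """A symbol is not present in the vocabulary."""


def canonical_smiles(smiles: str) -> str | None:
    """Toolkit-canonical SMILES, or None if the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def smiles_to_selfies(smiles: str) -> str:
    """Convert a SMILES string to its grammar representation.

    Raises :class:`ConversionError` naming the offending record when the
    SMILES does not parse or needs features outside the grammar's alphabet.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ConversionError(f"unparsable SMILES: {smiles!r}")
    try:
        return "".join(grammar.encode_mol(mol))
    except EncodeError as exc:
        raise ConversionError(f"cannot encode {smiles!r}: {exc}") from exc


def selfies_to_smiles(selfies: str) -> str:
    """Decode a grammar string to canonical SMILES.

    Never fails on symbol *order* — any sequence of alphabet symbols yields a
    valid molecule.  The empty string (or a derivation producing no atoms)
    returns ``""``, the documented empty-molecule sentinel.  The only error
    is :class:`~targen.grammar.DecodeError` for out-of-alphabet symbols.
    """
    symbols = split_symbols(selfies)
    mol = grammar.decode_to_mol(symbols)
    if mol is None:
        return ""
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token inventory with bidirectional token/index maps."""

    tokens: tuple[str, ...]  # chemical symbols, sorted
    _t2i: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        all_tokens = SPECIALS + tuple(self.tokens)
        object.__setattr__(self, "_t2i", {t: i for i, t in enumerate(all_tokens)})
        if len(self._t2i) != len(all_tokens):
            raise ValueError("duplicate tokens in vocabulary")

    @classmethod
    def from_corpus(cls, corpus: list[str]) -> "TokenVocabulary":
        if not corpus:
            raise ValueError("empty corpus")
        seen: set[str] = set()
        for s in corpus:
            seen.update(split_symbols(s))
        return cls(tokens=tuple(sorted(seen - set(SPECIALS))))

    def __len__(self) -> int:
        return len(self.tokens) + len(SPECIALS)

    def token_to_index(self, token: str) -> int:
        try:
            return self._t2i[token]
        except KeyError:
            raise TokenizationError(f"token {token!r} not in vocabulary") from None

    def index_to_token(self, index: int) -> str:
        all_tokens = SPECIALS + self.tokens
        if not 0 <= index < len(all_tokens):
            raise TokenizationError(f"index {index} out of range")
        return all_tokens[index]

    @property
    def hash(self) -> str:
        return hashlib.sha256("\x00".join(self.tokens).encode()).hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"specials": list(SPECIALS), "tokens": list(self.tokens)}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TokenVocabulary":
        payload = json.loads(Path(path).read_text())
        if tuple(payload["specials"]) != SPECIALS:
            raise ValueError("vocabulary file has unexpected special tokens")
        return cls(tokens=tuple(payload["tokens"]))


@dataclass(frozen=True)
class TokenSequence:
    """Integer token indices; ``length`` counts non-PAD positions."""

    indices: tuple[int, ...]

    @property
    def length(self) -> int:
        return sum(1 for i in self.indices if i != PAD_INDEX)

    def __len__(self) -> int:
        return len(self.indices)


def build_vocabulary(corpus: list[str]) -> TokenVocabulary:
    """Vocabulary = sorted symbols of the corpus plus the three specials."""
    return TokenVocabulary.from_corpus(corpus)


def tokenize(selfies: str, vocab: TokenVocabulary,
             add_specials: bool = True) -> TokenSequence:
    """Map a grammar string to vocabulary indices (SOS … EOS if requested)."""
    idx = [vocab.token_to_index(s) for s in split_symbols(selfies)]
    if add_specials:
        idx = [SOS_INDEX] + idx + [EOS_INDEX]
    return TokenSequence(indices=tuple(idx))


def detokenize(seq: TokenSequence | list[int], vocab: TokenVocabulary) -> str:
    """Inverse of :func:`tokenize`; PAD/SOS/EOS are stripped."""
    indices = seq.indices if isinstance(seq, TokenSequence) else seq
    out = []
    for i in indices:
        tok = vocab.index_to_token(int(i))
        if tok not in SPECIALS:
            out.append(tok)
    return "".join(out)


def read_molecules(path: str | Path) -> pd.DataFrame:
    """Read molecules from one-SMILES-per-line text or CSV.

    The CSV dialect has a ``smiles`` column and optional ``target`` (integer,
    0 = unconditional) and ``pxc50`` columns.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise ValueError(f"{path} has no 'smiles' column")
        return df
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return pd.DataFrame({"smiles": lines})


def write_molecules(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
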