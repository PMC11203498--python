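"""Robust derivation-rule grammar for molecular strings.

This module implements a SELFIES-style string grammar: molecules are written
as a sequence of bracketed symbols (``[C]``, ``[=O]``, ``[Branch1]``,
``[Ring1]`` ...), and *every* sequence of symbols from the alphabet decodes to
a syntactically and semantically valid molecule.  Robustness comes from the
derivation rules, not from the string: bond orders are capped by the remaining
valence of both partners, branch and ring instructions that cannot be realised
are consumed and skipped, and derivation of a fragment simply stops when its
current atom is saturated.

The grammar covers neutral organic molecules over the elements
B, C, N, O, S, P, F, Cl, Br, I with single, double and triple bonds.
Charges, radicals, isotopes and stereochemistry are outside the alphabet;
encoding a molecule that needs them raises :class:`EncodeError`.

Symbol inventory
----------------
* Atom symbols ``[<bond><element>]`` where ``<bond>`` is empty (single), ``=``
  (double) or ``#`` (triple) and gives the order of the bond attaching the new
  atom to the current one.  The bond prefix of the first atom of a fragment
  (molecule root or branch root) attaches a branch to its parent; at the very
  start of a string it is ignored.
* ``[Branch1] <i>`` / ``[Branch2] <i> <i>``: the next 1 (2) symbols are index
  operands encoding Q; the following Q+1 symbols derive a branch attached to
  the current atom.
* ``[Ring1] <i>`` / ``[Ring2] <i> <i>`` (and ``=``/``#`` variants): close a
  ring between the current atom and the atom created Q+1 positions earlier.

Index operands use a fixed 16-symbol digit alphabet (:data:`INDEX_ORDER`);
any other symbol used as an operand has value 0.  ``[Branch2]``/``[Ring2]``
read two base-16 digits, so branch lengths up to 256 symbols and ring
distances up to 256 atoms are expressible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ALPHABET",
    "ATOM_SYMBOLS",
    "VALENCES",
    "DecodeError",
    "EncodeError",
    "split_symbols",
    "decode_symbols",
    "decode_to_mol",
    "encode_mol",
]


class EncodeError(ValueError):
    """Molecule cannot be expressed in the grammar's symbol alphabet."""


class DecodeError(ValueError):
    """String is not a concatenation of known symbols.

    This is the *only* failure mode of decoding: any well-formed symbol
    sequence, however scrambled, yields a valid molecule.
    """


#: Default valences used to cap bond orders during derivation.  Sulfur and
#: phosphorus are capped at their lowest common valence so that every decoded
#: atom maps onto a standard neutral valence state of the toolkit.
VALENCES: dict[str, int] = {
    "B": 3, "C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

_BOND_CHAR = {1: "", 2: "=", 3: "#"}
_BOND_ORDER = {"": 1, "=": 2, "#": 3}
_RD_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}

ATOM_SYMBOLS: tuple[str, ...] = tuple(
    f"[{b}{el}]" for el in sorted(VALENCES) for b in ("", "=", "#")
    if not (VALENCES[el] < _BOND_ORDER[b])
)

STRUCTURAL_SYMBOLS: tuple[str, ...] = (
    "[Branch1]", "[Branch2]",
    "[Ring1]", "[=Ring1]", "[#Ring1]",
    "[Ring2]", "[=Ring2]", "[#Ring2]",
)

#: Full symbol alphabet of the grammar.
ALPHABET: frozenset[str] = frozenset(ATOM_SYMBOLS) | frozenset(STRUCTURAL_SYMBOLS)

#: Digit alphabet for index operands; position = value (base 16).
INDEX_ORDER: tuple[str, ...] = (
    "[C]", "[Ring1]", "[Ring2]", "[Branch1]", "[Branch2]", "[=C]", "[#C]",
    "[N]", "[=N]", "[O]", "[=O]", "[F]", "[S]", "[=S]", "[P]", "[Cl]",
)
_INDEX_VALUE = {s: i for i, s in enumerate(INDEX_ORDER)}

_ATOM_RE = re.compile(r"\[([=#]?)(Cl|Br|[BCNOSPFI])\]")
_SYMBOL_RE = re.compile(r"\[[^\[\]]*\]")


def split_symbols(selfies: str) -> list[str]:
    """Split a string into grammar symbols, validating every one.

    Raises :class:`DecodeError` if the string is not an exact concatenation
    of symbols from :data:`ALPHABET`.
    """
    symbols = _SYMBOL_RE.findall(selfies)
    if "".join(symbols) != selfies:
        raise DecodeError(f"string is not a concatenation of [..] symbols: {selfies!r}")
    for s in symbols:
        if s not in ALPHABET:
            raise DecodeError(f"unknown symbol {s!r}")
    return symbols


@dataclass
class _Graph:
    elements: list[str] = field(default_factory=list)
    used: list[int] = field(default_factory=list)
    bonds: dict[tuple[int, int], int] = field(default_factory=dict)

    def add_atom(self, element: str) -> int:
        self.elements.append(element)
        self.used.append(0)
        return len(self.elements) - 1

    def add_bond(self, a: int, b: int, order: int) -> None:
        self.bonds[(min(a, b), max(a, b))] = order
        self.used[a] += order
        self.used[b] += order

    def has_bond(self, a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in self.bonds

    def free(self, a: int) -> int:
        return VALENCES[self.elements[a]] - self.used[a]


def _read_index(symbols: list[str], i: int, n_digits: int) -> tuple[int, int]:
    """Read up to ``n_digits`` operand symbols starting at ``i``."""
    q = 0
    taken = 0
    while taken < n_digits and i < len(symbols):
        q = q * 16 + _INDEX_VALUE.get(symbols[i], 0)
        i += 1
        taken += 1
    return q, i


def _derive(symbols: list[str], prev: int | None, g: _Graph) -> None:
    """Derive one fragment (whole string or branch) into the graph."""
    cur = prev
    i = 0
    n = len(symbols)
    while i < n:
        sym = symbols[i]
        m = _ATOM_RE.fullmatch(sym)
        if m is not None:
            order = _BOND_ORDER[m.group(1)]
            element = m.group(2)
            if cur is None:
                cur = g.add_atom(element)
            else:
                free = g.free(cur)
                if free == 0:
                    break  # fragment's growth point saturated: derivation ends
                order = min(order, free, VALENCES[element])
                new = g.add_atom(element)
                g.add_bond(cur, new, order)
                cur = new
            i += 1
        elif sym in ("[Branch1]", "[Branch2]"):
            n_digits = 1 if sym == "[Branch1]" else 2
            q, i = _read_index(symbols, i + 1, n_digits)
            sub = symbols[i:i + q + 1]
            i += len(sub)
            # a branch needs one valence slot for itself and one for the
            # main chain to continue; otherwise the symbols are skipped
            if cur is not None and sub and g.free(cur) >= 2:
                _derive(sub, cur, g)
        else:  # ring symbol
            order = _BOND_ORDER[sym[1] if sym[1] in "=#" else ""]
            n_digits = 1 if sym.endswith("Ring1]") else 2
            q, i = _read_index(symbols, i + 1, n_digits)
            if cur is not None:
                tgt = cur - (q + 1)
                if tgt >= 0 and tgt != cur and not g.has_bond(cur, tgt):
                    order = min(order, g.free(cur), g.free(tgt))
                    if order >= 1:
                        g.add_bond(cur, tgt, order)


def decode_symbols(symbols: list[str]) -> _Graph:
    """Run the derivation rules over a symbol list, returning the graph."""
    g = _Graph()
    _derive(list(symbols), None, g)
    return g


def decode_to_mol(symbols: list[str]) -> Chem.Mol | None:
    """Decode symbols to a sanitized RDKit molecule.

    Returns ``None`` for an empty derivation (no atoms), the documented
    sentinel for degenerate inputs.
    """
    g = decode_symbols(symbols)
    if not g.elements:
        return None
    rw = Chem.RWMol()
    for el in g.elements:
        rw.AddAtom(Chem.Atom(el))
    for (a, b), order in g.bonds.items():
        rw.AddBond(a, b, _RD_BOND[order])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _digits(q: int, n: int) -> list[str]:
    out = []
    for _ in range(n):
        out.append(INDEX_ORDER[q % 16])
        q //= 16
    return out[::-1]


def _length_prefix(kind: str, value: int, bond: int = 1) -> list[str]:
    """Branch/ring symbol plus operands for a length/distance ``value``."""
    q = value - 1
    prefix = _BOND_CHAR[bond] if kind == "Ring" else ""
    if q < 16:
        return [f"[{prefix}{kind}1]"] + _digits(q, 1)
    if q < 256:
        return [f"[{prefix}{kind}2]"] + _digits(q, 2)
    raise EncodeError(f"{kind} operand {value} exceeds the grammar's range")


def encode_mol(mol: Chem.Mol) -> list[str]:
    """Encode an RDKit molecule as a symbol list.

    The molecule is kekulized and stereochemistry is dropped (the alphabet
    carries no stereo markers).  Charged, isotopic or radical atoms, and
    elements outside the supported set, raise :class:`EncodeError` — as do
    valence states above the grammar's caps (e.g. hexavalent sulfur).
    """
    mol = Chem.Mol(mol)
    Chem.RemoveStereochemistry(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in VALENCES:
            raise EncodeError(f"unsupported element {sym!r}")
        if atom.GetFormalCharge() != 0:
            raise EncodeError(f"charged atom {sym}{atom.GetFormalCharge():+d}")
        if atom.GetNumRadicalElectrons() != 0 or atom.GetIsotope() != 0:
            raise EncodeError(f"radical/isotopic atom {sym!r}")
        bonded = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
        if bonded > VALENCES[sym]:
            raise EncodeError(
                f"{sym} with bond order sum {bonded} exceeds the grammar cap "
                f"{VALENCES[sym]}"
            )
    if mol.GetNumAtoms() == 0:
        return []

    # spanning tree by iterative DFS from atom 0; non-tree bonds become rings
    order = {b.GetIdx(): int(b.GetBondTypeAsDouble()) for b in mol.GetBonds()}
    visited: set[int] = set()
    children: dict[int, list[int]] = {}
    ring_at: dict[int, list[int]] = {}
    stack = [0]
    visited.add(0)
    visit_seq = []
    parent: dict[int, int] = {}
    while stack:
        a = stack.pop()
        visit_seq.append(a)
        kids = []
        for nb in sorted((n.GetIdx() for n in mol.GetAtomWithIdx(a).GetNeighbors())):
            if nb not in visited:
                visited.add(nb)
                parent[nb] = a
                kids.append(nb)
        # reversed so that the DFS emission order matches sorted neighbor order
        children[a] = kids
        for k in reversed(kids):
            stack.append(k)
    if len(visited) != mol.GetNumAtoms():
        raise EncodeError("disconnected molecule (multi-fragment input)")

    def bond_order(a: int, b: int) -> int:
        return order[mol.GetBondBetweenAtoms(a, b).GetIdx()]

    ring_seen: set[tuple[int, int]] = set()
    emit_idx: dict[int, int] = {}
    counter = [0]

    def emit(a: int, incoming: int) -> list[str]:
        out = [f"[{_BOND_CHAR[incoming]}{mol.GetAtomWithIdx(a).GetSymbol()}]"]
        emit_idx[a] = counter[0]
        counter[0] += 1
        # ring closures back to already-emitted atoms, right after the atom
        for nb in sorted((n.GetIdx() for n in mol.GetAtomWithIdx(a).GetNeighbors())):
            if nb in emit_idx and nb != parent.get(a) and a not in children.get(nb, ()):
                key = (min(a, nb), max(a, nb))
                if key not in ring_seen:
                    ring_seen.add(key)
                    dist = emit_idx[a] - emit_idx[nb]
                    out += _length_prefix("Ring", dist, bond_order(a, nb))
        kids = children[a]
        for child in kids[:-1]:
            sub = emit(child, bond_order(a, child))
            out += _length_prefix("Branch", len(sub)) + sub
        if kids:
            out += emit(kids[-1], bond_order(a, kids[-1]))
        return out

    return emit(0, 1)
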