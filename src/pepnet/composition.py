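"""Amino-acid compositions (unordered multisets of subunits).

A composition such as ``A2P2`` records *how many* of each subunit a
mass decomposes into, never their sequence order.  Composition strings
always write the count, even when it is 1 (``L1R1``, not ``LR``), with
symbols in alphabet order (mass-ascending for the built-in alphabets).
"""

from __future__ import annotations

import re
from typing import Iterator, Mapping, Optional

from .alphabet import Alphabet

__all__ = ["Composition", "delta_aa", "composition_mass"]

_TOKEN = re.compile(r"([A-Za-z][a-z]*?)(\d+)")


class Composition(Mapping[str, int]):
    """An immutable multiset of subunit symbols with positive counts."""

    __slots__ = ("_counts", "_key")

    def __init__(self, counts: Mapping[str, int]):
        clean = {}
        for sym, n in counts.items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {sym!r}")
            if n > 0:
                clean[sym] = n
        if not clean:
            raise ValueError("composition must contain at least one subunit")
        self._counts = clean
        self._key = tuple(sorted(clean.items()))

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, symbol: str) -> int:
        return self._counts.get(symbol, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self._counts

    # -- identity ---------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        return isinstance(other, Composition) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        return f"Composition({self.to_string()!r})"

    # -- domain operations ------------------------------------------------
    @property
    def length(self) -> int:
        """Total residue count N (the peptide length)."""
        return sum(self._counts.values())

    def to_string(self, alphabet: Optional[Alphabet] = None) -> str:
        """Canonical string, symbols ordered by ``alphabet`` (or sorted)."""
        if alphabet is not None:
            order = sorted(
                self._counts,
                key=lambda s: alphabet.index(s) if s in alphabet else len(alphabet),
            )
        else:
            order = sorted(self._counts)
        return "".join(f"{s}{self._counts[s]}" for s in order)

    @classmethod
    def from_string(cls, text: str) -> "Composition":
        """Parse a composition string like ``A2P2`` or ``L1R1``."""
        text = text.strip()
        matches = list(_TOKEN.finditer(text))
        if not matches or "".join(m.group(0) for m in matches) != text:
            raise ValueError(f"cannot parse composition string {text!r}")
        counts: dict[str, int] = {}
        for m in matches:
            sym, n = m.group(1), int(m.group(2))
            counts[sym] = counts.get(sym, 0) + n
        return cls(counts)

    def add(self, other: "Composition") -> "Composition":
        counts = dict(self._counts)
        for sym, n in other.items():
            counts[sym] = counts.get(sym, 0) + n
        return Composition(counts)

    def mass(self, alphabet: Alphabet) -> float:
        return composition_mass(self, alphabet)


def composition_mass(comp: Composition, alphabet: Alphabet) -> float:
    """Neutral monoisotopic mass of a condensed composition.

    For residue counts ``n_i`` of subunits with free masses ``m_i`` and
    total length ``N``, the chain mass is ``sum(n_i * m_i) - (N - 1) * loss``:
    every bond formed releases one condensation-loss unit (water).
    """
    total = 0.0
    n = 0
    for sym, count in comp.items():
        total += count * alphabet.mass(sym)  # KeyError for unknown symbols
        n += count
    return total - (n - 1) * alphabet.condensation_loss


def delta_aa(a: Composition, b: Composition) -> Optional[Composition]:
    """The degraded amino acids between two compositions, or ``None``.

    Returns the component-wise difference ``a - b`` when it is entirely
    positive (every component >= 0 and at least one > 0), i.e. when ``a``
    strictly contains ``b`` as a sub-multiset.  Otherwise returns ``None``:
    equal compositions or any negative component give no degradation edge.
    """
    diff: dict[str, int] = {}
    for sym in set(a) | set(b):
        d = a[sym] - b[sym]
        if d < 0:
            return None
        if d > 0:
            diff[sym] = d
    if not diff:
        return None
    return Composition(diff)
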