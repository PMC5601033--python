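"""Subunit alphabets for mass decomposition.

A decomposition alphabet is a set of named subunits (by default free
amino acids) with neutral monoisotopic masses, plus the mass lost per
condensation bond (one water for peptide bonds).  Masses of the built-in
amino acids are derived from their elemental formulas using IUPAC
monoisotopic atomic masses, rounded to six decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Subunit",
    "Alphabet",
    "default_alphabet",
    "yeast_alphabet",
    "remove_subunits",
    "load_alphabet",
    "write_alphabet",
    "WATER",
    "PROTON",
]

# IUPAC monoisotopic atomic masses (Da)
_ATOMIC = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: monoisotopic mass of H2O, the default condensation loss
WATER = round(2 * _ATOMIC["H"] + _ATOMIC["O"], 6)

#: mass of a proton; used to neutralize protonated / deprotonated ions
PROTON = 1.0072765

# Free (non-residue) molecular formulas of the 20 proteinogenic amino
# acids, with leucine and isoleucine merged under "L" (isobaric).
_AA_FORMULAS = {
    "G": {"C": 2, "H": 5, "N": 1, "O": 2},
    "A": {"C": 3, "H": 7, "N": 1, "O": 2},
    "S": {"C": 3, "H": 7, "N": 1, "O": 3},
    "P": {"C": 5, "H": 9, "N": 1, "O": 2},
    "V": {"C": 5, "H": 11, "N": 1, "O": 2},
    "T": {"C": 4, "H": 9, "N": 1, "O": 3},
    "C": {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1},
    "L": {"C": 6, "H": 13, "N": 1, "O": 2},  # Leu/Ile, isobaric
    "N": {"C": 4, "H": 8, "N": 2, "O": 3},
    "D": {"C": 4, "H": 7, "N": 1, "O": 4},
    "Q": {"C": 5, "H": 10, "N": 2, "O": 3},
    "K": {"C": 6, "H": 14, "N": 2, "O": 2},
    "E": {"C": 5, "H": 9, "N": 1, "O": 4},
    "M": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 1},
    "H": {"C": 6, "H": 9, "N": 3, "O": 2},
    "F": {"C": 9, "H": 11, "N": 1, "O": 2},
    "R": {"C": 6, "H": 14, "N": 4, "O": 2},
    "Y": {"C": 9, "H": 11, "N": 1, "O": 3},
    "W": {"C": 11, "H": 12, "N": 2, "O": 2},
}


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Neutral monoisotopic mass of an elemental formula, in Da."""
    return sum(n * _ATOMIC[el] for el, n in formula.items())


@dataclass(frozen=True)
class Subunit:
    """A named decomposition subunit with its free-molecule neutral mass."""

    symbol: str
    mass: float

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("subunit symbol must be non-empty")
        if not self.mass > 0:
            raise ValueError(f"subunit {self.symbol!r} must have mass > 0")


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of subunits plus the condensation-loss mass.

    The order of ``subunits`` is also the canonical order in which
    composition strings are written (``A2P2`` rather than ``P2A2`` for
    the default, mass-ascending alphabet).
    """

    subunits: tuple[Subunit, ...]
    condensation_loss: float = WATER
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.condensation_loss < 0:
            raise ValueError("condensation loss must be >= 0")
        symbols = [s.symbol for s in self.subunits]
        if len(set(symbols)) != len(symbols):
            dup = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate subunit symbol(s): {', '.join(dup)}")
        for s in self.subunits:
            if s.mass <= self.condensation_loss:
                raise ValueError(
                    f"subunit {s.symbol!r} mass {s.mass} does not exceed the "
                    f"condensation loss {self.condensation_loss}"
                )
        object.__setattr__(
            self, "_index", {s.symbol: i for i, s in enumerate(self.subunits)}
        )

    def __len__(self) -> int:
        return len(self.subunits)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(s.symbol for s in self.subunits)

    def mass(self, symbol: str) -> float:
        """Free-molecule mass of one subunit."""
        try:
            return self.subunits[self._index[symbol]].mass
        except KeyError:
            raise KeyError(f"unknown subunit {symbol}") from None

    def residue_mass(self, symbol: str) -> float:
        """Mass contributed by the subunit once condensed into a chain."""
        return self.mass(symbol) - self.condensation_loss

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"unknown subunit {symbol}") from None

    def remove(self, symbols: Iterable[str]) -> "Alphabet":
        """Return a copy without the named subunits (see :func:`remove_subunits`)."""
        drop = list(symbols)
        for sym in drop:
            if sym not in self._index:
                raise KeyError(f"unknown subunit {sym}")
        dropset = set(drop)
        kept = tuple(s for s in self.subunits if s.symbol not in dropset)
        return Alphabet(kept, self.condensation_loss)

    def add(self, subunits: Iterable[Subunit]) -> "Alphabet":
        """Return a copy with extra subunits appended (order preserved)."""
        return Alphabet(self.subunits + tuple(subunits), self.condensation_loss)


def default_alphabet() -> Alphabet:
    """The 19 proteinogenic amino acids (Leu/Ile merged as ``L``).

    Subunits are ordered by ascending mass, losses per peptide bond are
    one water.  Twenty amino acids collapse to nineteen because leucine
    and isoleucine share an elemental formula and cannot be told apart
    by mass.
    """
    subunits = tuple(
        Subunit(sym, round(monoisotopic_mass(f), 6))
        for sym, f in sorted(_AA_FORMULAS.items(), key=lambda kv: monoisotopic_mass(kv[1]))
    )
    return Alphabet(subunits, WATER)


def yeast_alphabet() -> Alphabet:
    """The 17-amino-acid alphabet used for monomer-level decomposition.

    Glutamine and asparagine are dropped: at monoisotopic precision Q is
    indistinguishable from a condensed G+A and N from a condensed G+G,
    so keeping them makes every mass containing those formulas ambiguous.
    """
    return remove_subunits(default_alphabet(), ["Q", "N"])


def remove_subunits(alphabet: Alphabet, symbols: Sequence[str]) -> Alphabet:
    """Return ``alphabet`` without the named subunits.

    Raises ``KeyError`` naming the first unknown symbol.  The
    condensation loss is unchanged.
    """
    return alphabet.remove(symbols)


class AlphabetParseError(ValueError):
    """Raised when a custom alphabet file cannot be parsed."""


def load_alphabet(path: str | Path) -> Alphabet:
    """Parse a custom subunit table (tab-separated "File 3").

    The first line holds the condensation-loss mass; every following
    line is ``symbol<TAB>neutral mass``.  Blank lines are ignored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not content:
        raise AlphabetParseError(f"{path}: empty alphabet file")

    lineno, first = content[0]
    try:
        loss = float(first.split("\t")[0].strip())
    except ValueError:
        raise AlphabetParseError(
            f"{path}:{lineno}: first line must be the condensation-loss mass, "
            f"got {first!r}"
        ) from None
    if loss < 0:
        raise AlphabetParseError(f"{path}:{lineno}: condensation loss must be >= 0")

    subunits: list[Subunit] = []
    seen: set[str] = set()
    for lineno, line in content[1:]:
        parts = [p.strip() for p in line.split("\t") if p.strip()]
        if len(parts) != 2:
            raise AlphabetParseError(
                f"{path}:{lineno}: expected 'symbol<TAB>mass', got {line!r}"
            )
        symbol, mass_str = parts
        if symbol in seen:
            raise AlphabetParseError(f"{path}:{lineno}: duplicate symbol {symbol!r}")
        try:
            mass = float(mass_str)
        except ValueError:
            raise AlphabetParseError(
                f"{path}:{lineno}: non-numeric mass {mass_str!r}"
            ) from None
        if mass <= loss:
            raise AlphabetParseError(
                f"{path}:{lineno}: subunit {symbol!r} mass {mass} must exceed "
                f"the condensation loss {loss}"
            )
        seen.add(symbol)
        subunits.append(Subunit(symbol, mass))
    if not subunits:
        raise AlphabetParseError(f"{path}: no subunits defined")
    return Alphabet(tuple(subunits), loss)


def write_alphabet(alphabet: Alphabet, path: str | Path) -> None:
    """Write an alphabet in the custom-subunit ("File 3") format."""
    lines = [f"{alphabet.condensation_loss:.6f}"]
    lines += [f"{s.symbol}\t{s.mass:.6f}" for s in alphabet.subunits]
    Path(path).write_text("\n".join(lines) + "\n")
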