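import math

import numpy as np
import pytest

from pepnet import (
    Alphabet,
    Annotation,
    Composition,
    Subunit,
    composition_mass,
    default_alphabet,
    yeast_alphabet,
)


@pytest.fixture(scope="session")
def a19():
    return default_alphabet()


@pytest.fixture(scope="session")
def a17():
    return yeast_alphabet()


def brute_decompositions(mass, alphabet, tol, max_length=None):
    """Exhaustive enumeration oracle for mass decomposition.

    Recursively tries every count vector whose partial residue sum stays
    below the target window; the final acceptance check uses the same
    condensed-mass formula as the public API.  Exponential, but exact —
    only usable on small alphabets / masses.
    """
    symbols = list(alphabet.symbols)
    residues = [alphabet.residue_mass(s) for s in symbols]
    target = mass - alphabet.condensation_loss
    found = []

    def rec(i, partial, counts):
        if i == len(symbols):
            comp_counts = {s: c for s, c in zip(symbols, counts) if c}
            if not comp_counts:
                return
            if max_length is not None and sum(comp_counts.values()) > max_length:
                return
            comp = Composition(comp_counts)
            if abs(composition_mass(comp, alphabet) - mass) <= tol:
                found.append(comp)
            return
        r = residues[i]
        kmax = int(math.floor((target + tol + 1e-9 - partial) / r))
        for c in range(max(kmax, -1) + 1):
            rec(i + 1, partial + c * r, counts + [c])

    rec(0, 0.0, [])
    return set(found)


def make_uaac_annotations(comps, alphabet):
    """Wrap compositions as UAAC annotations (id = composition string)."""
    anns = []
    for i, comp in enumerate(comps):
        mass = composition_mass(comp, alphabet)
        anns.append(Annotation(f"n{i}_{comp.to_string(alphabet)}", mass, (comp,), (0.0,)))
    return anns


def random_alphabet(rng):
    """A random 1-6 subunit alphabet for oracle comparisons."""
    k = int(rng.integers(1, 7))
    loss = float(rng.choice([0.0, 18.010565]))
    masses = np.sort(rng.uniform(60.0 + loss, 250.0, size=k))
    subunits = tuple(
        Subunit(chr(ord("a") + i), round(float(m), 5)) for i, m in enumerate(masses)
    )
    return Alphabet(subunits, loss)
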