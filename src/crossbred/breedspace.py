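"""Breed sets, breed permutations/combinations, and proportion (delta) vectors.

An F2 crossbred has four purebred grandparents.  The *permutation* is the
ordered assignment of breeds to the four grandparent slots (maternal
grandfather, maternal grandmother, paternal grandfather, paternal
grandmother); the *combination* is the unordered multiset.  With ``q``
breeds there are ``q**4`` permutations and ``C(q+3, 4)`` combinations.

Every combination is summarised by a length-``q`` proportion vector
``delta`` whose entries are quarters (fractions of grandparents per breed)
and sum to one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BreedSet",
    "BreedCombination",
    "N_GRANDPARENTS",
    "enumerate_permutations",
    "enumerate_combinations",
    "delta_from_label",
    "validate_delta",
]

#: number of F0 grandparents of an F2 individual
N_GRANDPARENTS = 4


@dataclass(frozen=True)
class BreedSet:
    """An ordered set of purebred breed codes.

    Codes are single letters and are stored in ascending alphabetical
    order; every delta vector in the package is indexed against this
    canonical order.
    """

    codes: tuple[str, ...]
    names: tuple[str, ...] | None = None

    def __init__(self, codes, names=None):
        codes = tuple(codes)
        if len(codes) < 1:
            raise ValueError("a BreedSet needs at least one breed code")
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate breed codes in {codes!r}")
        for c in codes:
            if not (isinstance(c, str) and len(c) == 1 and c.isalpha() and c.isupper()):
                raise ValueError(f"breed codes must be single uppercase letters, got {c!r}")
        order = np.argsort(codes)
        object.__setattr__(self, "codes", tuple(codes[i] for i in order))
        if names is not None:
            names = tuple(names)
            if len(names) != len(codes):
                raise ValueError("names must match codes in length")
            names = tuple(names[i] for i in order)
        object.__setattr__(self, "names", names)

    @property
    def q(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"unknown breed code {code!r}; known codes are {self.codes}") from None

    def __len__(self) -> int:
        return self.q

    def __iter__(self):
        return iter(self.codes)

    def __contains__(self, code) -> bool:
        return code in self.codes


def validate_delta(delta: np.ndarray, q: int | None = None, quarters: bool = False) -> np.ndarray:
    """Validate a breed-proportion vector: entries in [0, 1], summing to 1.

    With ``quarters=True`` additionally require every entry to be a
    multiple of 1/4 (a true combination rather than a soft prediction).
    """
    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 1:
        raise ValueError("delta must be a 1-D vector")
    if q is not None and delta.shape[0] != q:
        raise ValueError(f"delta has length {delta.shape[0]}, expected {q}")
    if np.any(delta < -1e-12) or np.any(delta > 1 + 1e-12):
        raise ValueError("delta entries must lie in [0, 1]")
    if abs(delta.sum() - 1.0) > 1e-12:
        raise ValueError(f"delta must sum to 1, got {delta.sum()!r}")
    if quarters and np.any(np.abs(delta * N_GRANDPARENTS - np.round(delta * N_GRANDPARENTS)) > 1e-12):
        raise ValueError("entries of a true combination delta must be multiples of 1/4")
    return delta


@dataclass(frozen=True)
class BreedCombination:
    """A multiset of four grandparent breeds.

    ``label`` is the canonical 4-letter string (letters in ascending
    alphabetical order), ``delta`` the length-q proportion vector and
    ``multiplicity`` the number of distinct grandparent orderings
    (permutations) that collapse to this combination:
    ``4! / prod_j (4 * delta_j)!``.
    """

    label: str
    delta: np.ndarray = field(repr=False)
    multiplicity: int

    def __post_init__(self):
        validate_delta(self.delta, quarters=True)
        counts = (np.asarray(self.delta) * N_GRANDPARENTS).round().astype(int)
        expect = math.factorial(N_GRANDPARENTS) // math.prod(math.factorial(c) for c in counts)
        if expect != self.multiplicity:
            raise ValueError(f"multiplicity {self.multiplicity} inconsistent with delta for {self.label!r}")


def enumerate_permutations(breeds: BreedSet) -> list[str]:
    """All ``q**4`` ordered grandparent assignments as 4-letter labels.

    Slot order is (maternal grandfather, maternal grandmother, paternal
    grandfather, paternal grandmother).
    """
    return ["".join(p) for p in itertools.product(breeds.codes, repeat=N_GRANDPARENTS)]


def enumerate_combinations(breeds: BreedSet) -> list[BreedCombination]:
    """All ``C(q+3, 4)`` unordered breed combinations, in lexicographic
    order of their canonical labels."""
    out = []
    for combo in itertools.combinations_with_replacement(breeds.codes, N_GRANDPARENTS):
        label = "".join(combo)  # codes are sorted, so this is canonical
        delta = delta_from_label(label, breeds)
        counts = np.round(delta * N_GRANDPARENTS).astype(int)
        mult = math.factorial(N_GRANDPARENTS) // math.prod(math.factorial(int(c)) for c in counts)
        out.append(BreedCombination(label=label, delta=delta, multiplicity=mult))
    out.sort(key=lambda c: c.label)
    return out


def canonical_label(label: str, breeds: BreedSet) -> str:
    """Canonicalise a permutation label to its combination label."""
    for ch in label:
        if ch not in breeds:
            raise KeyError(f"unknown breed code {ch!r} in label {label!r}")
    return "".join(sorted(label, key=breeds.index))


def delta_from_label(label: str, breeds: BreedSet) -> np.ndarray:
    """Breed-proportion vector of a 4-letter permutation or combination label.

    ``delta[j]`` is the number of grandparents of breed ``j`` divided by 4,
    indexed in the canonical breed order; invariant under reordering of the
    label's letters.
    """
    if len(label) != N_GRANDPARENTS:
        raise ValueError(f"label must have {N_GRANDPARENTS} letters, got {label!r}")
    counts = np.zeros(breeds.q)
    for ch in label:
        if ch not in breeds:
            raise KeyError(f"unknown breed code {ch!r} in label {label!r}")
        counts[breeds.index(ch)] += 1
    return counts / N_GRANDPARENTS
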