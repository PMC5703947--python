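"""Admissible competition matrices for virtual patients.

Clinical reasoning constrains only the *rank order* of the six off-diagonal
competition coefficients: T+ cells deprived of exogenous testosterone are
the weakest competitors, and resistant T- cells press harder on TP than on
T+.  Written in the (row = affected, column = actor) convention this yields
the partial order

    a31 > a21,  a32 > a12,  a13 > a23,  a13 > a12,  a23 > a21,  a32 > a31.

Exactly 22 of the 720 rank permutations are linear extensions of this
partial order; each, combined with the fixed value grid
(0.4, 0.5, 0.6, 0.7, 0.8, 0.9), defines one admissible virtual patient.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .lv_model import PatientParams

__all__ = [
    "COEFFICIENT_LABELS",
    "PARTIAL_ORDER",
    "DEFAULT_VALUES",
    "RankOrdering",
    "CoefficientValues",
    "enumerate_orderings",
    "validate_ordering",
    "ordering_to_matrix",
    "patient_from_matrix",
    "patient_from_ordering",
    "sample_virtual_patient",
    "table3_patient",
    "PATIENT_1_MATRIX",
    "PATIENT_2_MATRIX",
]

#: Off-diagonal coefficient labels, fixed canonical order.
COEFFICIENT_LABELS = ("a12", "a13", "a21", "a23", "a31", "a32")

#: (greater, lesser) label pairs; every admissible ordering must rank the
#: first strictly above the second.
PARTIAL_ORDER = (
    ("a31", "a21"),
    ("a32", "a12"),
    ("a13", "a23"),
    ("a13", "a12"),
    ("a23", "a21"),
    ("a32", "a31"),
)

_MATRIX_SLOTS = {
    "a12": (0, 1), "a13": (0, 2),
    "a21": (1, 0), "a23": (1, 2),
    "a31": (2, 0), "a32": (2, 1),
}

#: Default value grid assigned to ranks 1..6.
DEFAULT_VALUES = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

#: The two representative responder parameterizations used throughout:
#: patient 1 carries a large "cheater" (T+) population and no resident T-,
#: patient 2 a resident low-frequency T- clone.
PATIENT_1_MATRIX = np.array([[1.0, 0.7, 0.8],
                             [0.4, 1.0, 0.5],
                             [0.6, 0.9, 1.0]])
PATIENT_2_MATRIX = np.array([[1.0, 0.6, 0.8],
                             [0.4, 1.0, 0.7],
                             [0.5, 0.9, 1.0]])


@dataclass(frozen=True)
class RankOrdering:
    """Ranks 1..6 (1 = smallest coefficient) for the six off-diagonal
    labels, stored in :data:`COEFFICIENT_LABELS` order."""

    ranks: tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if sorted(self.ranks) != [1, 2, 3, 4, 5, 6]:
            raise ValueError("ranks must be a permutation of 1..6")

    @classmethod
    def from_dict(cls, mapping: dict) -> "RankOrdering":
        return cls(tuple(int(mapping[label]) for label in COEFFICIENT_LABELS))

    def as_dict(self) -> dict:
        return dict(zip(COEFFICIENT_LABELS, self.ranks))

    def rank(self, label: str) -> int:
        return self.ranks[COEFFICIENT_LABELS.index(label)]


@dataclass(frozen=True)
class CoefficientValues:
    """Strictly increasing values in (0, 1) assigned to ranks 1..6."""

    values: tuple[float, ...] = DEFAULT_VALUES

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.values)
        if len(v) != 6:
            raise ValueError("exactly six coefficient values are required")
        if any(not 0 < x < 1 for x in v):
            raise ValueError("coefficient values must lie in (0, 1)")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("coefficient values must be strictly increasing")
        object.__setattr__(self, "values", v)


def validate_ordering(ordering: RankOrdering) -> bool:
    """True iff the ordering satisfies all six partial-order inequalities."""
    ranks = ordering.as_dict()
    return all(ranks[hi] > ranks[lo] for hi, lo in PARTIAL_ORDER)


@lru_cache(maxsize=1)
def _enumerate() -> tuple[RankOrdering, ...]:
    out = []
    for perm in itertools.permutations(range(1, 7)):
        candidate = RankOrdering(perm)
        if validate_ordering(candidate):
            out.append(candidate)
    return tuple(out)


def enumerate_orderings() -> list[RankOrdering]:
    """All admissible rank orderings, lexicographic by rank tuple in
    :data:`COEFFICIENT_LABELS` order; stable across calls.  There are 22."""
    return list(_enumerate())


def ordering_to_matrix(ordering: RankOrdering,
                       values: CoefficientValues | None = None) -> np.ndarray:
    """Competition matrix with unit diagonal and ``values[rank-1]`` in each
    off-diagonal slot."""
    values = values or CoefficientValues()
    a = np.eye(3)
    for label, rank in ordering.as_dict().items():
        a[_MATRIX_SLOTS[label]] = values.values[rank - 1]
    return a


def matrix_to_ordering(matrix: np.ndarray) -> RankOrdering:
    """Rank ordering implied by a matrix with six distinct off-diagonals."""
    coef = [matrix[_MATRIX_SLOTS[label]] for label in COEFFICIENT_LABELS]
    order = np.argsort(coef)
    ranks = np.empty(6, dtype=int)
    ranks[order] = np.arange(1, 7)
    return RankOrdering(tuple(int(k) for k in ranks))


def patient_from_matrix(competition: np.ndarray, **overrides) -> PatientParams:
    """PatientParams with the default growth rates and capacity policy."""
    return PatientParams(competition=np.array(competition, dtype=float), **overrides)


def patient_from_ordering(ordering: RankOrdering,
                          values: CoefficientValues | None = None,
                          **overrides) -> PatientParams:
    return patient_from_matrix(ordering_to_matrix(ordering, values), **overrides)


def table3_patient(which: int) -> PatientParams:
    """The two representative responder patients (1 or 2)."""
    if which == 1:
        return patient_from_matrix(PATIENT_1_MATRIX)
    if which == 2:
        return patient_from_matrix(PATIENT_2_MATRIX)
    raise ValueError("representative patients are numbered 1 and 2")


def sample_virtual_patient(seed: int,
                           values: CoefficientValues | None = None) -> PatientParams:
    """Draw one of the 22 admissible orderings uniformly (deterministic for
    a given seed) and return the corresponding patient."""
    rng = np.random.default_rng(seed)
    orderings = enumerate_orderings()
    idx = int(rng.integers(len(orderings)))
    return patient_from_ordering(orderings[idx], values)
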