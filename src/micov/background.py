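"""Amino-acid background distribution and physicochemical group definitions.

Two fixed reference objects live here:

* the BLOSUM62 amino-acid background distribution ``q``, used to factor the
  evolutionary pressure on individual residue types out of covariation scores;
* Taylor's ten *overlapping* physicochemical groups of the 20 amino acids,
  used to score covariation of properties rather than of residue identities.

The derived group background ``q_p(a) = sum_{i in a} q_i`` weighs each
property group by the total background mass of its members.  Because the
groups overlap, these weights do not sum to one across groups, and the group
fractional frequencies of an alignment column are likewise not a probability
distribution; all downstream formulas are written with that in mind.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

#: Canonical residue ordering used for every 20-vector in this package.
#: The ordering is arbitrary (all measures are permutation-invariant); it
#: only fixes the array layout.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class BackgroundDistribution:
    """A probability distribution over the 20 amino acids."""

    probabilities: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.probabilities) != set(AMINO_ACIDS):
            raise ValueError("background must cover exactly the 20 amino acids")
        vec = np.array([self.probabilities[a] for a in AMINO_ACIDS])
        if not (vec > 0).all():
            raise ValueError("background probabilities must be positive")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")

    def as_vector(self) -> np.ndarray:
        """Return the distribution as a 20-vector in ``AMINO_ACIDS`` order."""
        return np.array([self.probabilities[a] for a in AMINO_ACIDS])

    def __getitem__(self, letter: str) -> float:
        return self.probabilities[letter]


@dataclass(frozen=True)
class GroupScheme:
    """An ordered collection of named, possibly overlapping residue groups."""

    groups: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        if len(self.groups) != 10:
            raise ValueError("expected exactly ten groups")
        for name, members in self.groups:
            unknown = members - set(AMINO_ACIDS)
            if unknown:
                raise ValueError(f"group {name!r} has non-canonical members {unknown}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.groups)

    def membership_matrix(self) -> np.ndarray:
        """Return a 20 x n_groups 0/1 matrix; entry (i, g) = residue i in group g."""
        mat = np.zeros((len(AMINO_ACIDS), len(self.groups)))
        for g, (_, members) in enumerate(self.groups):
            for letter in members:
                mat[_AA_INDEX[letter], g] = 1.0
        return mat

    def membership_vector(self, letter: str) -> tuple[bool, ...]:
        """Group-membership profile of a single residue."""
        return tuple(letter in members for _, members in self.groups)


@dataclass(frozen=True)
class GroupBackground:
    """Background weight of each property group (sum of member frequencies)."""

    values: Mapping[str, float]

    def as_vector(self, scheme: "GroupScheme") -> np.ndarray:
        return np.array([self.values[name] for name in scheme.names])

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _load_q_table() -> dict[str, float]:
    text = resources.files("micov.data").joinpath("blosum62_background.json").read_text()
    return json.loads(text)["frequencies"]


_RAW_Q = _load_q_table()
_Q_TOTAL = sum(_RAW_Q.values())
_Q = BackgroundDistribution({a: v / _Q_TOTAL for a, v in _RAW_Q.items()})

# Taylor's ten overlapping groups, in the conventional order.  M belongs only
# to the hydrophobic group and Q only to the polar group; that asymmetry is
# part of the classification, not an omission.
_TAYLOR = GroupScheme((
    ("hydrophobic", frozenset("AGCTIVLKHFYWM")),
    ("aromatic", frozenset("FYWH")),
    ("aliphatic", frozenset("IVL")),
    ("tiny", frozenset("ASGC")),
    ("small", frozenset("PNDTCAGSV")),
    ("proline", frozenset("P")),
    ("charged", frozenset("KHRDE")),
    ("negative", frozenset("DE")),
    ("polar", frozenset("NQSDECTKRHYW")),
    ("positive", frozenset("KHR")),
))


def blosum62_background() -> BackgroundDistribution:
    """The BLOSUM62 amino-acid background distribution.

    Loaded from the package's JSON resource (raw 3-decimal published values,
    renormalized to sum exactly to 1).  The same object is returned on every
    call.
    """
    return _Q


def uniform_background() -> BackgroundDistribution:
    """A uniform distribution over the 20 amino acids (for null analyses)."""
    return BackgroundDistribution({a: 1.0 / 20 for a in AMINO_ACIDS})


def taylor_groups() -> GroupScheme:
    """Taylor's ten overlapping physicochemical amino-acid groups."""
    return _TAYLOR


def group_background(
    scheme: GroupScheme | None = None,
    q: BackgroundDistribution | None = None,
) -> GroupBackground:
    """Background weight of each group: ``q_p(a) = sum of q_i over i in a``.

    Because groups overlap, the weights intentionally do not sum to 1 across
    groups.  Every covariation measure that consumes them is invariant to a
    global rescaling, so no renormalization is applied.
    """
    scheme = scheme if scheme is not None else taylor_groups()
    q = q if q is not None else blosum62_background()
    return GroupBackground({
        name: float(sum(q[a] for a in members)) for name, members in scheme.groups
    })
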