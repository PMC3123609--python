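"""Built-in reference alignment and synthetic alignments with known structure.

``toy_msa`` returns the six-sequence, six-column reference alignment used
throughout the tests and documentation: columns 1 and 2 are fully conserved
(D and A), columns 3-5 covary bijectively in two sequence blocks (W/Y, A/C,
E/M), and column 6 is irregular.  Small as it is, it separates all four
measures: MI' sees only the bijective covariation, MIB' additionally ranks
conserved-vs-variable pairs, MIP' is silenced by property-conserved columns
(W and Y share every Taylor group), and MIBP' scores even the doubly
conserved pair.

``simulate_msa`` draws alignments from an explicit generative model so that
measure behaviour can be tested at scale: independent columns are i.i.d.
from a background distribution; a coevolving pair with coupling ``c`` copies
column b from a fixed random residue permutation of column a with
probability ``c`` per row (coupling 1 gives bijective covariation with
MI' = 1 exactly; coupling 0, independence); conserved columns are constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment_io import Alignment
from .background import AMINO_ACIDS, BackgroundDistribution, blosum62_background

_TOY_ROWS = ("DAWAEE", "DAWAEF", "DAWAED", "DAYCMD", "DAYCMT", "DAYCMT")


def toy_msa() -> Alignment:
    """The 6 x 6 gap-free reference alignment."""
    return Alignment(
        sequence_ids=tuple(f"seq{i}" for i in range(1, 7)),
        rows=_TOY_ROWS,
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic alignment.

    Column indices are 0-based.  Columns listed in ``coevolving_pairs`` and
    ``conserved_columns`` must be mutually disjoint across roles and within
    range; coupling strengths lie in [0, 1].
    """

    n_sequences: int
    n_columns: int
    background: BackgroundDistribution | None = None
    coevolving_pairs: tuple[tuple[int, int, float], ...] = field(default=())
    conserved_columns: tuple[tuple[int, str], ...] = field(default=())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.n_columns < 1:
            raise ValueError("alignment dimensions must be positive")
        claimed: set[int] = set()
        for a, b, coupling in self.coevolving_pairs:
            if a == b:
                raise ValueError("a column cannot coevolve with itself")
            for col in (a, b):
                if not 0 <= col < self.n_columns:
                    raise ValueError(f"column {col} out of range")
                if col in claimed:
                    raise ValueError(f"column {col} assigned to several roles")
                claimed.add(col)
            if not 0.0 <= coupling <= 1.0:
                raise ValueError(f"coupling must be in [0, 1], got {coupling}")
        for col, residue in self.conserved_columns:
            if not 0 <= col < self.n_columns:
                raise ValueError(f"column {col} out of range")
            if col in claimed:
                raise ValueError(f"column {col} assigned to several roles")
            claimed.add(col)
            if residue not in AMINO_ACIDS:
                raise ValueError(f"invalid conserved residue {residue!r}")


def simulate_msa(spec: SimulationSpec) -> Alignment:
    """Draw an alignment from the generative model; deterministic per seed."""
    background = (
        spec.background if spec.background is not None else blosum62_background()
    )
    probs = background.as_vector()
    rng = np.random.default_rng(spec.seed)
    # residue indices, all columns i.i.d. from the background to begin with
    matrix = rng.choice(20, size=(spec.n_sequences, spec.n_columns), p=probs)
    for col, residue in spec.conserved_columns:
        matrix[:, col] = AMINO_ACIDS.index(residue)
    for a, b, coupling in spec.coevolving_pairs:
        permutation = rng.permutation(20)
        coupled = rng.random(spec.n_sequences) < coupling
        matrix[coupled, b] = permutation[matrix[coupled, a]]
    rows = tuple("".join(AMINO_ACIDS[i] for i in row) for row in matrix)
    ids = tuple(f"sim{i + 1:04d}" for i in range(spec.n_sequences))
    return Alignment(sequence_ids=ids, rows=rows)
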