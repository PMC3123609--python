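"""Reading, validation and preprocessing of protein multiple sequence alignments.

The preprocessing pipeline mirrors common practice for covariation analysis:
redundant sequences are removed by greedy identity clustering (default 90%
identity), columns with more than 25% gaps are dropped, and alignments with
125 or fewer sequences are flagged as shallow (covariation estimates from
small alignments are noisy, but shallow inputs are still scored).

Column bookkeeping matters: ``Alignment.column_index_map`` records, for every
retained column, its 1-based position in the original alignment, so that
per-site reports remain in the coordinates of the input family even after
gap-column removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .background import AMINO_ACIDS

GAP = "-"
#: Symbols normalized to the canonical gap: gap variants plus ambiguity /
#: non-standard codes (B, Z, X, J, U, O), which the 20-letter frequency model
#: cannot represent.
_GAP_LIKE = set(".~-*BZXJUO")
_VALID = set(AMINO_ACIDS) | {GAP}

SUPPORTED_FORMATS = ("fasta", "stockholm")


class AlignmentFormatError(ValueError):
    """Raised when an input file is not a well-formed alignment."""


@dataclass(frozen=True)
class Alignment:
    """A rectangular protein alignment over the 20 amino acids plus gap.

    Attributes
    ----------
    sequence_ids:
        One identifier per row, input order preserved.
    rows:
        Equal-length strings of uppercase residue letters and ``-`` gaps.
    column_index_map:
        For each retained column, its 1-based position in the original
        alignment.  The identity mapping for freshly read alignments.
    """

    sequence_ids: tuple[str, ...]
    rows: tuple[str, ...]
    column_index_map: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.sequence_ids) != len(self.rows):
            raise ValueError("one identifier required per sequence")
        if not self.rows:
            raise AlignmentFormatError("empty alignment")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise AlignmentFormatError("ragged alignment rows")
        for r in self.rows:
            bad = set(r) - _VALID
            if bad:
                raise AlignmentFormatError(f"invalid symbols {sorted(bad)} in alignment")
        if not self.column_index_map:
            object.__setattr__(self, "column_index_map", tuple(range(1, width + 1)))
        if len(self.column_index_map) != width:
            raise ValueError("column_index_map length must equal alignment width")
        if any(b <= a for a, b in zip(self.column_index_map, self.column_index_map[1:])):
            raise ValueError("column_index_map must be strictly increasing")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, index: int) -> str:
        """Residues of retained column ``index`` (0-based), top to bottom."""
        return "".join(row[index] for row in self.rows)

    def original_column_number(self, index: int) -> int:
        """1-based position of retained column ``index`` in the input alignment."""
        return self.column_index_map[index]


def _normalize_symbol(symbol: str) -> str:
    symbol = symbol.upper()
    if symbol in _GAP_LIKE:
        return GAP
    return symbol


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file into a normalized Alignment.

    Symbols are uppercased; ``.``, ``~`` and ``-`` gaps as well as ambiguity
    codes are mapped to the canonical gap.  Any other unexpected letter raises
    :class:`AlignmentFormatError`.
    """
    if format not in SUPPORTED_FORMATS:
        raise ValueError(f"format must be one of {SUPPORTED_FORMATS}, got {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    ids = tuple(rec.id for rec in msa)
    rows = tuple("".join(_normalize_symbol(c) for c in str(rec.seq)) for rec in msa)
    return Alignment(sequence_ids=ids, rows=rows)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment to FASTA or Stockholm."""
    if format not in SUPPORTED_FORMATS:
        raise ValueError(f"format must be one of {SUPPORTED_FORMATS}, got {format!r}")
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.sequence_ids, aln.rows)
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), format)


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical residues over columns where both rows are non-gap.

    Defined as 0 when the two rows share no non-gap column.
    """
    shared = matches = 0
    for a, b in zip(row_a, row_b):
        if a != GAP and b != GAP:
            shared += 1
            if a == b:
                matches += 1
    return matches / shared if shared else 0.0


def cluster_by_identity(aln: Alignment, threshold: float = 0.9) -> Alignment:
    """Remove redundant sequences by greedy representative selection.

    Sequences are scanned in input order; a sequence is dropped iff its
    identity to an already-retained representative is >= ``threshold``.
    Deterministic, CD-HIT-like, order preserved.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"identity threshold must be in (0, 1], got {threshold}")
    kept: list[int] = []
    for i, row in enumerate(aln.rows):
        redundant = any(
            pairwise_identity(row, aln.rows[j]) >= threshold for j in kept
        )
        if not redundant:
            kept.append(i)
    return Alignment(
        sequence_ids=tuple(aln.sequence_ids[i] for i in kept),
        rows=tuple(aln.rows[i] for i in kept),
        column_index_map=aln.column_index_map,
    )


def gap_fraction(aln: Alignment, index: int) -> float:
    col = aln.column(index)
    return col.count(GAP) / len(col)


def filter_gap_columns(aln: Alignment, max_gap_fraction: float = 0.25) -> Alignment:
    """Drop columns whose gap fraction strictly exceeds ``max_gap_fraction``.

    A column with exactly the threshold fraction of gaps is retained.  The
    returned alignment's ``column_index_map`` points at the surviving original
    positions.  If every column is removed a warning is emitted and a
    0-column alignment is returned.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError(f"max_gap_fraction must be in [0, 1], got {max_gap_fraction}")
    kept = [
        j for j in range(aln.n_columns) if gap_fraction(aln, j) <= max_gap_fraction
    ]
    if not kept:
        warnings.warn("all columns exceeded the gap threshold; empty alignment")
        return Alignment(
            sequence_ids=aln.sequence_ids,
            rows=tuple("" for _ in aln.rows),
            column_index_map=(),
        )
    return Alignment(
        sequence_ids=aln.sequence_ids,
        rows=tuple("".join(row[j] for j in kept) for row in aln.rows),
        column_index_map=tuple(aln.column_index_map[j] for j in kept),
    )


def validate_depth(aln: Alignment, min_sequences: int = 125) -> bool:
    """True iff the alignment holds strictly more than ``min_sequences`` rows.

    Covariation estimates from alignments at or below this depth are
    unreliable; callers are expected to warn rather than abort, so that small
    demonstration alignments remain scoreable.
    """
    return aln.n_sequences > min_sequences
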