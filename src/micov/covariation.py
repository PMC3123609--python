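"""The four covariation measures: MI', MIB', MIP' and MIBP'.

All four start from position-specific frequencies of an alignment column
pair (K, L) and a mutual-information-style sum; they differ in the alphabet
(20 residues vs 10 overlapping physicochemical groups) and in whether the
marginal distributions are corrected for the amino-acid background:

``MI(K,L) = sum_ij p(i,j) ln[ p(i,j) / (p(K_i) p(L_j)) ]``, normalized by the
joint column entropy ``H(K,L)`` to give MI' in [0, 1].

MIB replaces each observed marginal by a background-modified marginal

``m(K_i) = (p(K_i) / q_i) / sum_j (p(K_j) / q_j)``,

i.e. the observed frequencies are divided by the BLOSUM62 background (the
residue's evolutionary pressure) and renormalized.  A residue that is common
simply because its type is common everywhere is thereby down-weighted, so a
fully conserved column paired with a variable one can score non-zero.

MIP applies the MI sum to the 10 x 10 table of Taylor-group joint fractional
frequencies.  Because the groups overlap, these tables are *not* probability
distributions (their entries can sum to well above 1); the normalizing
entropy ``H_p(K,L)`` is computed over the same table.  MIBP applies the
background correction at the group level with ``q_p(a) = sum_{i in a} q_i``.

Conventions, all pinned by the scores of the six-column reference alignment
(see :func:`micov.synthetic.toy_msa`):

* natural logarithm internally; every primed (normalized) measure is
  invariant to the log base;
* ``0 * ln 0 = 0``: empty cells contribute nothing;
* when the entropy denominator is 0 the raw score is reported as the primed
  score.  For MI and MIB a zero denominator forces a raw score of 0 on
  ungapped data, reproducing the convention that conserved pairs score 0;
  for MIBP the raw score of a doubly conserved pair is legitimately non-zero;
* per-pair statistics are computed from the rows that are non-gap at *both*
  columns, which keeps MI non-negative and the entropy identity
  ``MI = H(K) + H(L) - H(K,L)`` exact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .alignment_io import GAP, Alignment
from .background import (
    AMINO_ACIDS,
    BackgroundDistribution,
    GroupBackground,
    GroupScheme,
    blosum62_background,
    group_background,
    taylor_groups,
)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class Measure(str, enum.Enum):
    """The four covariation measures."""

    MI = "MI"
    MIB = "MIB"
    MIP = "MIP"
    MIBP = "MIBP"


@dataclass(frozen=True)
class ColumnDistribution:
    """Residue frequencies of one column, gaps excluded."""

    frequencies: np.ndarray  # 20-vector
    effective_count: int

    @property
    def degenerate(self) -> bool:
        return self.effective_count == 0

    def frequency(self, letter: str) -> float:
        return float(self.frequencies[_AA_INDEX[letter]])


@dataclass(frozen=True)
class JointDistribution:
    """Joint residue frequencies of a column pair over jointly non-gap rows."""

    frequencies: np.ndarray  # 20 x 20
    effective_count: int

    @property
    def degenerate(self) -> bool:
        return self.effective_count == 0


@dataclass(frozen=True)
class GroupDistribution:
    """Fractional frequency of each overlapping group in one column.

    Entries are each in [0, 1] but need not sum to 1: one residue can belong
    to several groups.
    """

    frequencies: np.ndarray  # 10-vector
    effective_count: int

    @property
    def degenerate(self) -> bool:
        return self.effective_count == 0


@dataclass(frozen=True)
class GroupJointDistribution:
    """Joint group fractional frequencies of a column pair (10 x 10)."""

    frequencies: np.ndarray
    effective_count: int

    @property
    def degenerate(self) -> bool:
        return self.effective_count == 0


@dataclass(frozen=True)
class PairScore:
    """Raw and normalized covariation score of one column pair.

    ``column_k``/``column_l`` are 1-based positions in the *original*
    alignment coordinates.
    """

    column_k: int
    column_l: int
    raw: float
    normalized: float
    measure: Measure
    degenerate: bool = False


def _column_counts(aln: Alignment, k: int) -> np.ndarray:
    counts = np.zeros(20)
    for symbol in aln.column(k):
        if symbol != GAP:
            counts[_AA_INDEX[symbol]] += 1
    return counts


def _joint_counts(aln: Alignment, k: int, l: int) -> np.ndarray:
    counts = np.zeros((20, 20))
    for row in aln.rows:
        a, b = row[k], row[l]
        if a != GAP and b != GAP:
            counts[_AA_INDEX[a], _AA_INDEX[b]] += 1
    return counts


def column_distribution(aln: Alignment, k: int) -> ColumnDistribution:
    """Residue frequencies of column ``k`` (0-based retained index)."""
    counts = _column_counts(aln, k)
    n = int(counts.sum())
    freqs = counts / n if n else counts
    return ColumnDistribution(frequencies=freqs, effective_count=n)


def joint_distribution(aln: Alignment, k: int, l: int) -> JointDistribution:
    """Joint residue frequencies of columns ``k`` and ``l`` (0-based)."""
    if k == l:
        raise ValueError("joint distribution requires two distinct columns")
    counts = _joint_counts(aln, k, l)
    n = int(counts.sum())
    freqs = counts / n if n else counts
    return JointDistribution(frequencies=freqs, effective_count=n)


def group_distribution(
    aln: Alignment, k: int, scheme: GroupScheme | None = None
) -> GroupDistribution:
    """Fractional frequency of each property group in column ``k``."""
    scheme = scheme if scheme is not None else taylor_groups()
    counts = _column_counts(aln, k)
    n = int(counts.sum())
    member = scheme.membership_matrix()  # 20 x 10
    group_counts = member.T @ counts
    freqs = group_counts / n if n else group_counts
    return GroupDistribution(frequencies=freqs, effective_count=n)


def group_joint_distribution(
    aln: Alignment, k: int, l: int, scheme: GroupScheme | None = None
) -> GroupJointDistribution:
    """Joint property-group frequencies of a column pair (10 x 10 table)."""
    if k == l:
        raise ValueError("joint distribution requires two distinct columns")
    scheme = scheme if scheme is not None else taylor_groups()
    counts = _joint_counts(aln, k, l)
    n = int(counts.sum())
    member = scheme.membership_matrix()
    group_counts = member.T @ counts @ member
    freqs = group_counts / n if n else group_counts
    return GroupJointDistribution(frequencies=freqs, effective_count=n)


def modified_marginal(
    col: ColumnDistribution, q: BackgroundDistribution | None = None
) -> ColumnDistribution:
    """Background-modified marginal: observed / background, renormalized.

    ``m_i = (p_i / q_i) / sum_j (p_j / q_j)`` over the observed residues.
    A fully conserved column maps to a point mass of 1 on its residue
    whatever that residue's background frequency — which is exactly why the
    background-corrected measures treat all conserved columns alike.
    """
    if col.degenerate:
        raise ValueError("cannot modify a degenerate (all-gap) column")
    q = q if q is not None else blosum62_background()
    ratio = np.where(col.frequencies > 0, col.frequencies / q.as_vector(), 0.0)
    return ColumnDistribution(
        frequencies=ratio / ratio.sum(), effective_count=col.effective_count
    )


def _modified_group_marginal(freqs: np.ndarray, qp_vec: np.ndarray) -> np.ndarray:
    ratio = np.where(freqs > 0, freqs / qp_vec, 0.0)
    return ratio / ratio.sum()


def entropy(frequencies: np.ndarray) -> float:
    """Shannon entropy (nats) of a frequency table, with 0 ln 0 = 0.

    Also applied to the improper group tables, whose entries need not sum
    to 1; the same plug-in formula defines their normalizing "entropy".
    Terms are sorted before summation so that tables holding the same
    multiset of frequencies get bitwise-identical entropies — this keeps
    the exact identities (MI' of a conserved pair is 0, of a bijectively
    covarying pair 1) exact in floating point too.
    """
    p = np.asarray(frequencies, dtype=float).ravel()
    p = np.sort(p[p > 0])
    return float(-(p * np.log(p)).sum())


def joint_entropy(joint: JointDistribution | GroupJointDistribution) -> float:
    """H(K, L): entropy of the joint table of a column pair."""
    return entropy(joint.frequencies)


def _mi_sum(joint: np.ndarray, marg_k: np.ndarray, marg_l: np.ndarray) -> float:
    nz = joint > 0
    expected = np.outer(marg_k, marg_l)
    return float((joint[nz] * np.log(joint[nz] / expected[nz])).sum())


def _normalize(raw: float, denom: float) -> float:
    return raw / denom if denom > 0 else raw


def _degenerate_score(aln: Alignment, k: int, l: int, measure: Measure) -> PairScore:
    return PairScore(
        column_k=aln.original_column_number(k),
        column_l=aln.original_column_number(l),
        raw=float("nan"),
        normalized=float("nan"),
        measure=measure,
        degenerate=True,
    )


def mi_scores(aln: Alignment, k: int, l: int) -> PairScore:
    """Classical mutual information of columns ``k`` and ``l``, and MI'.

    MI' = MI / H(K,L), in [0, 1]; 0 whenever one column is fully conserved.

    Computed through the entropy identity ``MI = H(K) + H(L) - H(K,L)``
    (exact because the marginals are taken from the pair's jointly non-gap
    rows), with the marginal entropies built from integer counts.  Together
    with the sorted entropy summation this makes the two boundary cases
    exact: a conserved column gives MI' = 0.0 and a bijective covariation
    MI' = 1.0, with no floating-point residue.
    """
    counts = _joint_counts(aln, k, l)
    n = int(counts.sum())
    if n == 0:
        return _degenerate_score(aln, k, l, Measure.MI)
    h_k = entropy(counts.sum(axis=1) / n)
    h_l = entropy(counts.sum(axis=0) / n)
    h_kl = entropy(counts / n)
    raw = max(h_k + h_l - h_kl, 0.0)
    normalized = max((h_k + h_l) / h_kl - 1.0, 0.0) if h_kl > 0 else raw
    return PairScore(
        column_k=aln.original_column_number(k),
        column_l=aln.original_column_number(l),
        raw=raw,
        normalized=normalized,
        measure=Measure.MI,
    )


def mib_scores(
    aln: Alignment, k: int, l: int, q: BackgroundDistribution | None = None
) -> PairScore:
    """MI with background-modified marginals (MIB), and MIB' = MIB / H(K,L).

    MIB' may exceed 1; no clamping is applied.
    """
    q = q if q is not None else blosum62_background()
    counts = _joint_counts(aln, k, l)
    n = int(counts.sum())
    if n == 0:
        return _degenerate_score(aln, k, l, Measure.MIB)
    freqs = counts / n
    marg_k = ColumnDistribution(counts.sum(axis=1) / n, n)
    marg_l = ColumnDistribution(counts.sum(axis=0) / n, n)
    mod_k = modified_marginal(marg_k, q).frequencies
    mod_l = modified_marginal(marg_l, q).frequencies
    raw = _mi_sum(freqs, mod_k, mod_l)
    h = entropy(freqs)
    return PairScore(
        column_k=aln.original_column_number(k),
        column_l=aln.original_column_number(l),
        raw=raw,
        normalized=_normalize(raw, h),
        measure=Measure.MIB,
    )


def mip_scores(
    aln: Alignment, k: int, l: int, scheme: GroupScheme | None = None
) -> PairScore:
    """MI of physicochemical properties (MIP), and MIP' = MIP / H_p(K,L).

    Computed over the 10 x 10 joint Taylor-group table.  A column whose
    residues all share the same group-membership profile (e.g. all W/Y) has
    group frequencies of exactly 0 or 1, which forces MIP to 0 — property
    conservation, even without residue conservation, silences the measure.
    """
    scheme = scheme if scheme is not None else taylor_groups()
    counts = _joint_counts(aln, k, l)
    n = int(counts.sum())
    if n == 0:
        return _degenerate_score(aln, k, l, Measure.MIP)
    member = scheme.membership_matrix()
    group_joint = (member.T @ counts @ member) / n  # integer counts: exact 0/1 cells
    marg_k = (member.T @ counts.sum(axis=1)) / n
    marg_l = (member.T @ counts.sum(axis=0)) / n
    raw = _mi_sum(group_joint, marg_k, marg_l)
    h = entropy(group_joint)
    return PairScore(
        column_k=aln.original_column_number(k),
        column_l=aln.original_column_number(l),
        raw=raw,
        normalized=_normalize(raw, h),
        measure=Measure.MIP,
    )


def mibp_scores(
    aln: Alignment,
    k: int,
    l: int,
    scheme: GroupScheme | None = None,
    qp: GroupBackground | None = None,
) -> PairScore:
    """MIP with the property background distribution (MIBP), and MIBP'.

    The group marginals are divided by ``q_p`` and renormalized before
    entering the MI sum; the primed score divides by the group joint entropy
    ``H_p(K,L)`` when it is positive and reports the raw score otherwise.
    Doubly conserved column pairs therefore get large, finite scores instead
    of the flat 0 that MI', MIB' and MIP' assign them.
    """
    scheme = scheme if scheme is not None else taylor_groups()
    qp = qp if qp is not None else group_background(scheme)
    counts = _joint_counts(aln, k, l)
    n = int(counts.sum())
    if n == 0:
        return _degenerate_score(aln, k, l, Measure.MIBP)
    member = scheme.membership_matrix()
    group_joint = (member.T @ counts @ member) / n
    qp_vec = qp.as_vector(scheme)
    mod_k = _modified_group_marginal((member.T @ counts.sum(axis=1)) / n, qp_vec)
    mod_l = _modified_group_marginal((member.T @ counts.sum(axis=0)) / n, qp_vec)
    raw = _mi_sum(group_joint, mod_k, mod_l)
    h = entropy(group_joint)
    return PairScore(
        column_k=aln.original_column_number(k),
        column_l=aln.original_column_number(l),
        raw=raw,
        normalized=_normalize(raw, h),
        measure=Measure.MIBP,
    )


_SCORERS = {
    Measure.MI: mi_scores,
    Measure.MIB: mib_scores,
    Measure.MIP: mip_scores,
    Measure.MIBP: mibp_scores,
}


@dataclass(frozen=True)
class PairScoreMatrix:
    """Symmetric matrix of covariation scores over the retained columns.

    ``columns`` holds the original 1-based column numbers labelling both
    axes; the diagonal is defined as 0.  Degenerate pairs (no jointly
    non-gap rows) carry NaN and are flagged in ``degenerate``.
    """

    measure: Measure
    columns: tuple[int, ...]
    raw: np.ndarray
    normalized: np.ndarray
    degenerate: np.ndarray  # boolean mask

    def pairs(self) -> Iterator[PairScore]:
        """Iterate the unordered pairs (k < l) as :class:`PairScore`."""
        for i, j in combinations(range(len(self.columns)), 2):
            yield PairScore(
                column_k=self.columns[i],
                column_l=self.columns[j],
                raw=float(self.raw[i, j]),
                normalized=float(self.normalized[i, j]),
                measure=self.measure,
                degenerate=bool(self.degenerate[i, j]),
            )

    def value(self, col_k: int, col_l: int) -> float:
        """Normalized score for a pair of original 1-based column numbers."""
        i, j = self.columns.index(col_k), self.columns.index(col_l)
        return float(self.normalized[i, j])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: one row per unordered pair."""
        records = [
            {
                "col_k": p.column_k,
                "col_l": p.column_l,
                "raw": p.raw,
                "normalized": p.normalized,
                "measure": p.measure.value,
            }
            for p in self.pairs()
        ]
        return pd.DataFrame.from_records(
            records, columns=["col_k", "col_l", "raw", "normalized", "measure"]
        )

    def to_square_frame(self) -> pd.DataFrame:
        """Square matrix of normalized scores labelled by original columns."""
        labels = [f"C{c}" for c in self.columns]
        return pd.DataFrame(self.normalized, index=labels, columns=labels)

    def write_tsv(self, path: str | Path, layout: str = "long") -> None:
        if layout == "long":
            self.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
        elif layout == "square":
            self.to_square_frame().round(3).to_csv(path, sep="\t")
        else:
            raise ValueError("layout must be 'long' or 'square'")


def score_all_pairs(
    aln: Alignment,
    measure: Measure | str,
    q: BackgroundDistribution | None = None,
    scheme: GroupScheme | None = None,
    qp: GroupBackground | None = None,
) -> PairScoreMatrix:
    """Score every unordered column pair of ``aln`` with one measure."""
    measure = Measure(measure)
    if aln.n_columns < 2:
        raise ValueError("need at least two retained columns to score pairs")
    n = aln.n_columns
    raw = np.zeros((n, n))
    normalized = np.zeros((n, n))
    degenerate = np.zeros((n, n), dtype=bool)
    for i, j in combinations(range(n), 2):
        if measure is Measure.MI:
            score = mi_scores(aln, i, j)
        elif measure is Measure.MIB:
            score = mib_scores(aln, i, j, q)
        elif measure is Measure.MIP:
            score = mip_scores(aln, i, j, scheme)
        else:
            score = mibp_scores(aln, i, j, scheme, qp)
        raw[i, j] = raw[j, i] = score.raw
        normalized[i, j] = normalized[j, i] = score.normalized
        degenerate[i, j] = degenerate[j, i] = score.degenerate
    return PairScoreMatrix(
        measure=measure,
        columns=tuple(aln.column_index_map),
        raw=raw,
        normalized=normalized,
        degenerate=degenerate,
    )
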