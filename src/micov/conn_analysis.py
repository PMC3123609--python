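"""Per-site covariation connectivity: conn(k).

Individual pair scores are noisy; a more robust per-site signal is how often
a site participates in the top-n scoring pairs.  ``conn(k)`` counts the
occurrences of column k among those pairs, and sites with conn(k) at or above
a cut-off are reported as covariation hubs.  Conventional settings: the top
75 pairs with cut-off 5 for the residue-level measures (MI', MIB'), and the
top 25 pairs with cut-off 3 for the coarser property-level measures (MIP',
MIBP'), whose 10-letter alphabet produces fewer distinguishable pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .covariation import Measure, PairScore, PairScoreMatrix

#: (n_top, cutoff) defaults per measure.
DEFAULT_CONN_PARAMS: dict[Measure, tuple[int, int]] = {
    Measure.MI: (75, 5),
    Measure.MIB: (75, 5),
    Measure.MIP: (25, 3),
    Measure.MIBP: (25, 3),
}


@dataclass(frozen=True)
class ConnTable:
    """conn(k) for every retained site, with the provenance of the counts.

    ``entries`` is sorted by descending conn, ties by ascending site number,
    and includes sub-threshold sites (so a different cut-off can be applied
    without recomputation); ``report_sites`` applies the cut-off.
    """

    entries: tuple[tuple[int, int], ...]  # (site, conn)
    n_top: int
    cutoff: int
    measure: Measure

    def conn(self, site: int) -> int:
        for s, c in self.entries:
            if s == site:
                return c
        raise KeyError(f"site {site} not in table")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site": s,
                    "conn": c,
                    "n_top": self.n_top,
                    "cutoff": self.cutoff,
                    "measure": self.measure.value,
                }
                for s, c in self.entries
            ],
            columns=["site", "conn", "n_top", "cutoff", "measure"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def top_pairs(
    matrix: PairScoreMatrix, n: int, include_ties: bool = False
) -> list[PairScore]:
    """The ``n`` highest-scoring non-degenerate pairs of a score matrix.

    Ordering is deterministic: score descending, then column numbers
    ascending.  With ``include_ties`` the full cohort tied with the n-th
    score is admitted.  If fewer than ``n`` valid pairs exist, all are
    returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    candidates = [p for p in matrix.pairs() if not p.degenerate]
    if not candidates:
        warnings.warn("score matrix has no valid pairs")
        return []
    candidates.sort(key=lambda p: (-p.normalized, p.column_k, p.column_l))
    if len(candidates) <= n:
        return candidates
    if include_ties:
        boundary = candidates[n - 1].normalized
        return [p for p in candidates if p.normalized >= boundary]
    return candidates[:n]


def conn_scores(
    pairs: list[PairScore],
    n_top: int,
    cutoff: int,
    measure: Measure,
    sites: tuple[int, ...] | None = None,
) -> ConnTable:
    """Count, per site, its occurrences among the given top pairs.

    ``sites`` optionally fixes the universe of reported sites (e.g. all
    retained columns); sites absent from every pair then appear with conn 0.
    """
    counts: dict[int, int] = {s: 0 for s in (sites or ())}
    for p in pairs:
        counts[p.column_k] = counts.get(p.column_k, 0) + 1
        counts[p.column_l] = counts.get(p.column_l, 0) + 1
    ordered = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return ConnTable(
        entries=tuple(ordered), n_top=n_top, cutoff=cutoff, measure=measure
    )


def conn_from_matrix(
    matrix: PairScoreMatrix,
    n_top: int | None = None,
    cutoff: int | None = None,
    include_ties: bool = False,
) -> ConnTable:
    """Convenience pipeline: top pairs then conn(k), with per-measure defaults."""
    default_n, default_cut = DEFAULT_CONN_PARAMS[matrix.measure]
    n_top = n_top if n_top is not None else default_n
    cutoff = cutoff if cutoff is not None else default_cut
    pairs = top_pairs(matrix, n_top, include_ties=include_ties)
    return conn_scores(pairs, n_top, cutoff, matrix.measure, sites=matrix.columns)


def report_sites(table: ConnTable) -> list[tuple[int, int]]:
    """Sites whose conn(k) reaches the table's cut-off, hub-first."""
    return [(s, c) for s, c in table.entries if c >= table.cutoff]


def format_report(table: ConnTable) -> str:
    """Human-readable hub report with 'k' and 'conn(k)' columns."""
    lines = [
        f"# measure={table.measure.value}'  n_top={table.n_top}  cutoff={table.cutoff}",
        f"{'k':>6s}  {'conn(k)':>8s}",
    ]
    for site, conn in report_sites(table):
        lines.append(f"{site:>6d}  {conn:>8d}")
    if len(lines) == 2:
        lines.append("(no site reaches the cut-off)")
    return "\n".join(lines)
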