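# Methods

## Problem setting

Compensatory substitutions leave a statistical trace: two alignment columns
whose residues change together across a protein family. `micov` quantifies
that covariation for every column pair (K, L) of a protein multiple sequence
alignment and summarizes it per site. Four related measures are provided;
all are mutual-information (MI) functionals of position-specific
frequencies, and they differ along two axes — whether the alphabet is the
20 residues or ten overlapping physicochemical groups, and whether the
marginals are corrected for the amino-acid background distribution.

Notation: N sequences; `p(K^i)` the frequency of residue i in column K
(gaps excluded); `p(K^i, L^j)` the joint frequency over rows that are
non-gap at both columns; `H(K,L)` the Shannon entropy of the joint table.
Logarithms are natural throughout; every normalized ("primed") measure is a
ratio of entropies and therefore base-free.

## The measures

**MI and MI'.**

    MI(K,L)  = Σ_ij p(i,j) ln[ p(i,j) / (p(K^i) p(L^j)) ]
    MI'(K,L) = MI(K,L) / H(K,L)

with the convention 0·ln 0 = 0. MI' lies in [0, 1]; it is 0 whenever one
column is fully conserved and exactly 1 for bijective covariation.

**MIB and MIB'.** Common residue types are common everywhere; their high
frequencies reflect weak evolutionary pressure rather than interaction. MIB
removes this effect by replacing each observed marginal with a
background-modified marginal

    m(K^i) = (p(K^i) / q_i) / Σ_j (p(K^j) / q_j)

where q is the BLOSUM62 amino-acid background distribution, and

    MIB(K,L)  = Σ_ij p(i,j) ln[ p(i,j) / (m(K^i) m(L^j)) ]
    MIB'(K,L) = MIB(K,L) / H(K,L).

Dividing by q and renormalizing shifts marginal mass toward rare residues:
a half-W/half-Y column gets marginal (0.708, 0.292) instead of (0.5, 0.5),
because W is the rarest residue. A fully conserved column maps to a point
mass of 1 regardless of which residue it conserves, so all conserved columns
are treated alike — which is why MIB'(1,k) = MIB'(2,k) on the reference
alignment although columns 1 and 2 conserve different residues. MIB' is not
bounded by 1 (the reference alignment reaches 1.378); no clamping is
applied.

**MIP and MIP'.** To score covariation of physicochemical character rather
than residue identity, residues are mapped into Taylor's ten *overlapping*
groups (hydrophobic, aromatic, aliphatic, tiny, small, proline, charged,
negative, polar, positive). The fractional frequency of group a in column K
is `p_p(K^a) = count(K^a)/N`, and the joint table `p_p(K^a, L^b)` counts
rows whose residue pair lies in (a, b). Because groups overlap, these
tables are *not* probability distributions — their entries can sum well
above 1 — but the same MI functional and the same plug-in entropy formula
apply:

    MIP(K,L)  = Σ_ab p_p(a,b) ln[ p_p(a,b) / (p_p(K^a) p_p(L^b)) ]
    MIP'(K,L) = MIP(K,L) / H_p(K,L),   H_p = −Σ_ab p_p(a,b) ln p_p(a,b).

A column whose residues all share one membership profile (all W/Y, all G/A,
all I/L — pairs the ten groups cannot distinguish) has group frequencies of
exactly 0 or 1, which forces MIP to 0: property conservation silences the
measure even without residue conservation.

**MIBP and MIBP'.** The background correction applied at the group level.
The group background is `q_p(a) = Σ_{i∈a} q_i`, the modified group marginal
is `(p_p(K^a)/q_p(a)) / Σ_b (p_p(K^b)/q_p(b))`, and MIBP is the MI
functional of the group joint table against these marginals, normalized by
`H_p(K,L)`. Because the group marginals do not sum to 1 before
renormalization, MIBP is not forced to 0 by conservation: a doubly
conserved column pair has `H_p = 0` and a large positive raw MIBP (33.425
for the reference pair of conserved D and A columns), which is reported
as-is (see conventions).

## Conventions and degenerate cases

- **Zero denominators.** When the normalizing entropy is 0 the raw score is
  reported as the primed score. For MI and MIB on gap-free data a zero
  denominator implies a raw score of 0, so this coincides with the "report
  0" convention; for MIBP it is what makes conserved pairs scoreable.
- **Gaps.** Single-column frequencies use that column's non-gap rows. All
  pair statistics — joint *and* marginals — use the rows non-gap at both
  columns. This guarantees MI ≥ 0 and makes the entropy identity
  `MI = H(K) + H(L) − H(K,L)` exact; on gap-free input it reduces to the
  per-column definition. A pair with no jointly non-gap row is flagged
  degenerate (NaN), excluded from rankings rather than scored 0.
- **Float exactness.** MI is evaluated through the entropy identity from
  integer counts, and entropy terms are sorted before summation so that
  identical frequency multisets give bitwise-identical entropies. The
  boundary conventions (conserved → MI' = 0.0, bijective → MI' = 1.0) then
  hold exactly in floating point.
- **Background table.** The packaged q is the 3-decimal BLOSUM62 background
  table familiar from the conservation-scoring literature (A 0.078, R 0.051,
  …, V 0.072; `src/micov/data/blosum62_background.json`). Its raw values
  sum to 1.002 from rounding and are renormalized on load; every measure is
  invariant to a global rescaling of q, so this is purely cosmetic. This
  specific table was selected because it is the unique common BLOSUM62
  background variant that reproduces the reference alignment's published
  MIB'/MIBP' scores to all three printed decimals; the more finely grained
  BLOSUM62 marginals and the Robinson-Robinson frequencies do not (e.g.
  they give 0.203 instead of 0.237 for one conserved-column pair).
- **Rounding.** Public reports round to 3 decimals; internal values keep
  full precision.

## A non-reduction worth knowing about

With a uniform residue background, MIB' collapses to MI' exactly: residue
marginals are proper distributions, so dividing by a constant and
renormalizing is a no-op. The analogous statement is *false* at the group
level. Overlapping-group frequencies sum to S ≥ 1, so even a constant
q_p yields modified marginals `p_p(a)/S ≠ p_p(a)`, and

    MIBP = MIP + T (ln S_K + ln S_L),   T = Σ_ab p_p(a,b) ≥ 1.

MIBP' under a flat group background therefore exceeds MIP' whenever the
group tables are improper — on the reference alignment, pair (4,5) gives
MIP' = 0.077 but flat-background MIBP' = 2.884. The uniform-background
sanity check is valid for the residue measures only; the property-level
analogue is a structural offset, not a bug.

## Preprocessing

1. **Reading.** Aligned FASTA or Stockholm via Biopython. Symbols are
   uppercased; `.`, `~`, `-` and the ambiguity codes B, Z, X, J, U, O are
   normalized to the canonical gap (the frequency model is strictly
   20-letter).
2. **Redundancy removal.** Greedy representative selection in file order:
   a sequence is dropped iff its identity to an earlier-retained sequence
   is ≥ the threshold (default 0.90). Identity is matches over columns
   where both sequences are non-gap, 0 if there is no such column. Greedy
   scanning is deterministic and CD-HIT-like; on deep families it may keep
   a different representative set than other tools, but the toy and test
   surfaces are unaffected.
3. **Gap columns.** Columns with strictly more than 25% gaps (default) are
   removed. `column_index_map` keeps the surviving columns' original
   1-based positions so every downstream report stays in input coordinates.
4. **Depth.** Alignments need more than 125 sequences for stable estimates;
   shallower inputs produce a warning, not an error (the CLI's `--strict`
   upgrades warnings to failures). The built-in reference alignment itself
   is 6 sequences deep and must remain runnable.

Note an interaction: the reference alignment contains an exact duplicate
row, and its published scores include it. Redundancy removal at any
threshold would drop that row and change the scores, so the reference
surface is computed on the raw alignment; the CLI exposes `--no-cluster`
for this situation.

## conn(k)

From one measure's score matrix, the n_top highest-scoring non-degenerate
pairs are selected (ties broken deterministically: score descending, then
column numbers ascending; `include_ties` admits the whole tied cohort) and
`conn(k)` counts the pairs containing site k. Σ_k conn(k) = 2·n_top
whenever n_top pairs exist. Defaults: n_top 75 / cut-off 5 for MI' and
MIB'; n_top 25 / cut-off 3 for MIP' and MIBP' — the property alphabet is
coarser, so fewer pairs are distinguishable and a smaller pool with a lower
cut-off is conventional. Sub-threshold sites are kept in the machine-readable
table and only hidden from the human report, so cut-offs can be re-applied
cheaply.

## Synthetic alignments

`simulate_msa` draws columns i.i.d. from a background distribution
(BLOSUM62 by default), overrides conserved columns with a constant residue,
and couples column pairs by copying, per row with probability c (the
coupling), column b from a fixed random permutation image of column a.
Coupling 1 yields bijective covariation (MI' = 1 exactly); coupling 0,
independence. A single seeded `numpy` generator drives everything, so equal
specs give bitwise-equal alignments.

What the generator emulates: finite-sample composition noise, conserved
sites, tunable pairwise coupling. What it does not: phylogenetic
correlation between rows (sequences are exchangeable draws, while real
families share a tree), gaps, indel structure, and site-specific
composition biases. Tests passing on these alignments validate the
estimators' algebra and conventions, not robustness to tree-induced
covariation — the main known confounder of MI methods on real families.

## Test and verification sizes

The suite checks the full 6×6 reference surface exactly (±0.001, the
printed precision); the entropy identity on 100 random 20×4 alignments at
1e-9; agreement of all four measures with an independently written base-2
oracle at 1e-9; the uniform-background reduction on the reference plus 20
seeded 15×4 alignments; the finite-sample null (median MI' over 50
replicates of two independent columns at N = 5000, required < 0.02, typical
value ≈ 0.006); and the conn(k) handshake and monotonicity identities on
100 random 8-site matrices. These sizes keep the whole suite within a few
seconds while leaving each property statistically unambiguous.

## Known limitations

- No correction for phylogenetic structure (no shuffling null, no APC);
  scores on real families mix interaction signal with shared ancestry.
- The greedy clustering is order-dependent by design (deterministic), and
  its representative set can differ from the original tooling on deep
  families.
- The ten-group scheme cannot distinguish W/Y, G/A, I/L; property-level
  measures are blind to covariation within those pairs.
- MIBP' values are not on a comparable scale across pairs with and without
  `H_p = 0`; rank them within, not across, those two regimes.
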