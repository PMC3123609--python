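# micov

Mutual-information measures of residue coevolution in protein multiple
sequence alignments.

When a functionally important residue mutates, compensatory mutations at
interacting positions often follow; across a protein family this leaves
correlated substitution patterns at pairs of alignment columns. `micov`
computes four related covariation measures for every column pair of an MSA
and turns them into per-site reports, for people who want interaction or
functional-site candidates from sequence data alone:

- **MI′** — classical mutual information of the two columns' residue
  frequencies, normalized by the pair's joint entropy H(K,L):
  `MI′ = MI/H(K,L) ∈ [0,1]`.
- **MIB′** — MI with each marginal replaced by a background-modified
  marginal `m(K^i) ∝ p(K^i)/q_i` (renormalized), where q is the BLOSUM62
  amino-acid background. Dividing by q removes the evolutionary pressure on
  residue types, so pairs involving conserved columns — invisible to MI′ —
  become distinguishable.
- **MIP′** — mutual information over the 10×10 joint table of Taylor's ten
  *overlapping* physicochemical groups (hydrophobic, aromatic, aliphatic,
  tiny, small, proline, charged, negative, polar, positive): covariation of
  chemical character rather than residue identity.
- **MIBP′** — the property-level measure with group marginals corrected by
  the group background `q_p(a) = Σ_{i∈a} q_i`; it can even score a pair of
  two fully conserved columns.

Per site, `conn(k)` counts how often column k appears among the top-n
scoring pairs of a measure (defaults: top 75 / cut-off 5 for MI′ and MIB′,
top 25 / cut-off 3 for MIP′ and MIBP′); sites above the cut-off are
reported as covariation hubs.

The mathematical details, conventions for gaps and degenerate columns, and
known limitations are in [docs/methods.md](docs/methods.md).

## Worked example

The package ships a six-sequence reference alignment whose columns are
constructed to separate the four measures:

```python
>>> from micov import toy_msa, score_all_pairs, Measure
>>> aln = toy_msa()
>>> print("\n".join(aln.rows))
DAWAEE
DAWAEF
DAWAED
DAYCMD
DAYCMT
DAYCMT
>>> score_all_pairs(aln, Measure.MIB).to_square_frame().round(3)
       C1     C2     C3     C4     C5     C6
C1  0.000  0.000  0.138  0.237  0.141  0.003
C2  0.000  0.000  0.138  0.237  0.141  0.003
C3  0.138  0.138  0.000  1.375  1.279  0.360
C4  0.237  0.237  1.375  0.000  1.378  0.404
C5  0.141  0.141  1.279  1.378  0.000  0.362
C6  0.003  0.003  0.360  0.404  0.362  0.000
```

Reading the MIB′ block: columns 1 and 2 are fully conserved, so MI′ scores
every pair containing them 0 — but MIB′ separates (1,3) = 0.138 from
(1,4) = 0.237, because after background correction the W/Y and A/C columns
carry different information. The perfectly covarying pairs (3,4), (3,5),
(4,5) all have MI′ = 1 yet different MIB′ (1.375, 1.279, 1.378): the
background makes rare-residue covariation count for more. Running
`Measure.MIP` instead returns 0 for every pair containing column 3 — W and
Y share all ten property groups, so the column is property-conserved — and
`Measure.MIBP` gives the doubly conserved pair (1,2) a score of 33.425,
chemistry covariation that none of the other measures can see.

The `examples/` directory holds short runnable scripts: scoring the
reference alignment (`toy_alignment_scores.py`), hub detection with conn(k)
on a simulated family (`coevolution_hubs.py`), and the preprocessing
pipeline (`preprocess_and_score.py`).

## Command line

```bash
micov --input family.fasta --format fasta --out results/
```

runs identity clustering (90%), gap-column filtering (> 25% gaps removed),
a depth check (warns at ≤ 125 sequences), all four measures, and conn(k)
reports, writing per-measure pair TSVs, conn tables, the filtered
alignment, and a JSON manifest of the effective configuration. All column
numbers are original-alignment coordinates. See `micov --help` for flags
(`--measures`, `--identity`, `--no-cluster`, `--n-top`, `--cutoff`,
`--strict`, `--config`, …).

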