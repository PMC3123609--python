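"""Score the built-in 6x6 reference alignment with all four measures.

The alignment is tiny but built to separate the measures: columns 1-2 are
fully conserved (D, A), columns 3-5 covary perfectly in two blocks (W/Y,
A/C, E/M), and column 6 is irregular.
"""

from micov import Measure, score_all_pairs, toy_msa

aln = toy_msa()
print("Reference alignment:")
for sid, row in zip(aln.sequence_ids, aln.rows):
    print(f"  {sid}  {row}")

for measure in Measure:
    matrix = score_all_pairs(aln, measure)
    print(f"\n{measure.value}' scores (normalized):")
    print(matrix.to_square_frame().round(3).to_string())

print(
    "\nHow to read this:\n"
    "  MI'   : 1.0 for the perfectly covarying pairs (3,4),(3,5),(4,5); 0 for\n"
    "          every pair with a conserved column.\n"
    "  MIB'  : the background-corrected marginals separate pairs MI' cannot:\n"
    "          (1,3)=0.138 vs (1,4)=0.237 although both involve conserved C1.\n"
    "  MIP'  : W and Y share every Taylor property group, so column 3 is\n"
    "          property-conserved and all its pairs score 0.\n"
    "  MIBP' : the property background even scores the doubly conserved pair\n"
    "          (1,2)=33.425 - property covariation of D with A is informative."
)
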