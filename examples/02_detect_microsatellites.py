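"""Detect microsatellites by wraparound dynamic programming.

Scans a read carrying a compound repeat -- a (CT) array next to a (CA)
array, as seen at some immune-gene loci -- plus a diverged (AAT) array.
Scoring is +2 per match, -3 per mismatch, -5 per indel; arrays need score
>=50, length >=12 bp and purity >55% to be reported.
"""

from fessurvey.tandem import arrays_to_gff3, call_tandem_arrays, wraparound_align

read = (
    "GATTACCAGT" * 3
    + "CT" * 38
    + "ATTGCATCGCAT"
    + "CA" * 14
    + "TTGCAGGACCA" * 3
    + "AATAATGATAATAATAATACTAATAATAAT"  # (AAT)x10 with 3 substitutions
    + "CCGATTGGCA" * 3
)

print("wraparound alignment of (AG)x3 against AG:",
      wraparound_align("AGAGAG", "AG")[:2], "(score, purity)")
print()
arrays = call_tandem_arrays(read, read_id="demo")
for a in arrays:
    print(
        f"{a.start:4d}-{a.end:<4d} period {a.period}  motif {a.motif}"
        f"  class {a.canonical_motif}  copies {a.copy_number:5.1f}"
        f"  score {a.score:4d}  purity {a.purity:.2f}"
    )
print()
print(arrays_to_gff3(arrays))
# The compound (CT)/(CA) repeat is reported as two separate arrays of the
# AG and AC classes; the diverged AAT array keeps its full span with
# purity < 1 reflecting the substitutions.
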