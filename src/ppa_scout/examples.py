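"""Bundled worked example: an exon-intron junction whose unspliced
read-through frame terminates shortly into the intron.

The junction is the canonical configuration at a cryptic-PAS intron: the
exon ends on a codon boundary, the donor site carries an intact U1 snRNA
binding hexamer (GGTAAG spanning the last exonic base and the first five
intronic bases), and the read-through frame meets its first stop codon
six nucleotides after the junction.
"""

from __future__ import annotations

__all__ = [
    "JUNCTION_EXON_TAIL",
    "JUNCTION_INTRON_SEQ",
    "JUNCTION_FRAME_OFFSET",
]

#: Exonic sequence ending at the junction (junction on a codon boundary).
JUNCTION_EXON_TAIL = "TCCAAGGAGCTGCAG"

#: Intronic sequence starting at the first intronic base.  In the
#: read-through frame the codons are GTA AGT TGA ... so the first stop
#: (TGA) begins after six intronic nucleotides.
JUNCTION_INTRON_SEQ = (
    "GTAAGTTGATTTGCCTTTCAAGGCATTTCCTTTTCCTCAGGTTTCTCTTTGCTTCCCAG"
)

#: Number of exonic nucleotides completing the codon spanning the junction.
JUNCTION_FRAME_OFFSET = 0
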