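"""Published primer and clamp oligos for 18S rDNA eukaryote metabarcoding.

TAReuk454FWD1/TAReukREV3 amplify the V4 hypervariable region of the 18S
rRNA gene across eukaryotes.  EUK581F/EUK1134R and E572F/E1009R form the
nested UNonMet scheme biased against metazoan templates; the second-round
oligos are printed with their sequencing-adapter tails (see the ``tail``
handling in :mod:`clampkit.insilico`).  TICKB is the 16-mer clamp that
suppresses amplification of tick (Ixodidae) 18S rDNA; its W absorbs an A/T
polymorphism segregating between the two ixodid haplotypes at that column.
"""

from .seqcore import DegenerateSequence

__all__ = [
    "TAREUK454FWD1",
    "TAREUKREV3",
    "EUK581F",
    "EUK1134R",
    "E572F",
    "E1009R",
    "TICKB",
    "TICKB_N_LNA",
]

TAREUK454FWD1 = DegenerateSequence("CCAGCASCYGCGGTAATTCC", id="TAReuk454FWD1")
TAREUKREV3 = DegenerateSequence("ACTTTCGTTCTTGATYRA", id="TAReukREV3")

EUK581F = DegenerateSequence("GTGCCAGCAGCCGCG", id="EUK581F")
EUK1134R = DegenerateSequence("TTTAAGTTTCAGCCTTGCG", id="EUK1134R")

# second-round UNonMet oligos as printed, adapter tails included
E572F = DegenerateSequence("CCATCTCATCCCTGCGTGTCTCCGACTCAG", id="E572F")
E1009R = DegenerateSequence("CCTATCCCCTGTGTGCCTTGGCAGTCTCAG", id="E1009R")

TICKB = DegenerateSequence("GATCAAWGAAAACATT", id="TickB")

#: Number of LNA-substituted residues in the synthesized LNA variant of the
#: clamp (the exact substitution pattern is a vendor design choice).
TICKB_N_LNA = 11
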