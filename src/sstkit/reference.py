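"""Reference sequences and constants for the DUF2775 family.

``MTST3_NONREPEAT_QUERY`` is the mature (signal-peptide-removed) non-repeat
domain of the Medicago truncatula MtST3 protein (Medtr3g116430), the
classic query used to mine SST/ST family members from plant genome
databases.  It carries the shared N-terminal conserved block with the
family-typical five-residue spacer between the leading R and the YW pair.
"""

MTST3_NONREPEAT_QUERY = "RNNLGEYWKLFMKDQNMPEEIQGLLSANTKSNLKTLEKKKVFGE"

#: Arabidopsis thaliana SST1 locus (At1g49310): CDS length in bp without
#: the stop codon, i.e. 82 codons for an 82-residue precursor.
SST1_CDS_LEN_NO_STOP = 246
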