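"""Extract putative cyclopeptide-alkaloid core pentapeptides.

Under the burpitide hypothesis the xxxxY motif — once per ST tandem repeat,
once in the SST C-terminal conserved block — is a RiPP core peptide.  Cores
with Ser/Thr two positions before the anchoring Tyr match the Ser/Thr
cyclopeptide-alkaloid class (xxS/TxY).
"""

from sstkit import SimConfig, classify, generate_dataset
from sstkit.cpa import extract_cores

bundle = generate_dataset(SimConfig(n_sst=4, n_st=2, n_decoy=0), seed=9)

print(f"{'parent':<16} {'source':<12} {'span':<10} {'core':<6} Ser/Thr-CPA")
for record in bundle.records:
    seq = record.residues[record.sp_length:]
    label, ev = classify(record)
    for c in extract_cores(record.id, seq, label, ev):
        span = f"{c.span[0]}-{c.span[1]}"
        print(f"{c.parent_id:<16} {c.source:<12} {span:<10} {c.core:<6} {c.ser_thr_cpa}")
# Each ST yields one pentapeptide per repeat; each SST yields at most one,
# anchored at the Y of its conserved terminal YH.  Every core is exactly
# 5 residues ending in Y.
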