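"""Molecular weight and isoelectric point of mature proteins.

Average-mass Mw and Henderson-Hasselbalch pI (bisection) for the mature
forms of a small synthetic SST set.  Family SSTs typically run 4.6-13.5 kDa
with pI anywhere from acidic to strongly basic.
"""

from sstkit import SimConfig, generate_dataset
from sstkit.physchem import profile

bundle = generate_dataset(SimConfig(n_sst=8, n_st=0, n_decoy=0), seed=5)

print(f"{'id':<18} {'aa':>4} {'Mw (kDa)':>9} {'pI':>6}")
for record in bundle.records:
    mature = record.residues[record.sp_length:]
    p = profile(record.id, mature)
    print(f"{p.id:<18} {p.length_aa:>4} {p.mw_da / 1000:>9.2f} {p.pi:>6.2f}")
# Mw sums fixed average residue masses plus one water; pI is the unique pH
# where the peptide's net charge crosses zero.
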