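"""Family-binned percentage distributions of gene and protein features.

Reproduces the comparative reporting style for the three family groups:
first-exon/intron/CDS lengths from the gene models, signal-peptide and
mature-protein sizes, Mw and pI from the sequences.
"""

from sstkit import SimConfig, generate_dataset, summarize

bundle = generate_dataset(SimConfig(n_sst=60, n_st=0, n_decoy=0), seed=8)
summaries = summarize(bundle.records, bundle.gene_models)

for s in summaries:
    if s.feature not in ("exon1_len", "cds_len", "mature_len"):
        continue
    parts = ", ".join(
        f"{b.label}: {p:.0f}%" for b, p in zip(s.bins, s.percentages) if p > 0
    )
    print(f"{s.group.value:<14} {s.feature:<12} (n={s.n:>3})  {parts}")
# Brassicaceae genes peak at a 57 bp first exon and 51-60 aa matures;
# Fabaceae/Other peak at 45 bp first exons with larger matures — percentages
# within each row sum to 100.
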