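"""Write a complete labelled synthetic dataset to disk.

Produces sequences.faa, gene_models.tsv, annotations.tsv, truth.tsv and the
pre-gapped aligned_sst.fasta under ./sim_out — the same files the CLI's
`sstkit simulate` command writes.  Generation is byte-identical per seed.
"""

from collections import Counter

from sstkit import SimConfig, generate_dataset, write_dataset

config = SimConfig(n_sst=30, n_st=10, n_burp=3, n_decoy=15, n_misannotated_per_flag=2)
bundle = generate_dataset(config, seed=42)
write_dataset(bundle, "sim_out")

print(f"wrote {len(bundle.records)} records to sim_out/")
print("class composition:", dict(Counter(t.true_class for t in bundle.truths)))
print(
    "planted flags:",
    dict(Counter(f.value for t in bundle.truths for f in t.planted_flags)),
)
# truth.tsv carries the planted class, flags and repeat counts, so any
# downstream analysis can be scored against known ground truth.
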