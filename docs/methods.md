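# Methods

This note records the models, parameter choices and numerical conventions
behind sstkit, and what the synthetic-data tests do and do not establish.

## Sequence model and coordinates

All analyses run on **mature proteins**: the precursor minus its annotated
signal peptide (SP). SP lengths are consumed as annotation — the package
does not predict them; an entry without one is flagged (*2) rather than
guessed. Residues are the 20 standard one-letter codes plus `X`, which is
tolerated on input but never satisfies a motif element. All reported
coordinates are 1-based closed intervals; internal indexing is 0-based.

Gene models describe the family's canonical single-intron architecture:
`exon1_len + exon2_len = cds_len`, with `exon2_len` always derived. CDS
lengths are stop-codon-inclusive by default because annotation sources mix
conventions; `cds_includes_stop=False` selects the other dialect, and
`protein_len` accounts for it (an 82-residue precursor ↔ 249 bp inclusive ↔
246 bp exclusive).

## Motif engine

Patterns use a PROSITE-like mini-language: fixed residues, classes `[IL]`,
negated classes `{P}`, wildcards `x` and bounded runs `x{a,b}`. Matching
counts mismatches on non-wildcard elements only. Two deliberate
conventions:

- **`X` in the subject** never matches a fixed, class or (non-trivially)
  negated element; it costs a mismatch.
- **Negated classes match vacuously past the sequence end** — an absent
  residue cannot be the forbidden one. This makes C-terminal exclusion
  patterns behave as PROSITE users expect (e.g. the N-glycosylation site
  `N-{P}-[ST]-{P}` matches the C-terminal tripeptide `NAS`).

Per start position the engine reports the best match (fewest mismatches,
then shortest span, then lexicographically smallest run-length assignment),
so results are deterministic; overlapping occurrences at distinct starts
are all reported. A brute-force enumeration oracle in the test suite
verifies exact agreement on random sequences up to 200 aa.

**Mismatch budgets.** The family literature matched motifs by eye; budgets
are this package's operationalisation: 3 for the N-terminal region
(`Rx{5,7}YWx{3}Mx{3}PxPx{2}Ix{2}LL`, 9 scored positions), 2 for the SST
C-terminal region (`Fx{3}Fx{5}I[IL]YH`, 6 scored), 2 on the 7 fixed
positions of the ST repeat `EFEPRPx{4}Y`. They admit the canonical anchors
(the MtST3 non-repeat query matches region 1 with one mismatch) while a
random 70-mer passes the joint SST test with probability well below 10⁻³
(checked by simulation: 30 random decoys per suite run, and larger
Monte-Carlo sweeps during development, produce no false positives). All
budgets are `MotifConfig` fields.

**Tandem repeats.** Repeat hits (canonical with budget, plus the degenerate
first-repeat form `DFDx{2}Px{4}Y` matched exactly) are chained by
inter-start spacing within [20, 30] residues using longest-chain dynamic
programming; the period is the median inter-start spacing, defined only for
≥ 2 chained hits.

**Classification order.** ST (≥ 2 chained repeats) ≻ BURP-like (exact
`Ax{6}YWx{7}PMP` starting within the first 60 residues **and** length > 90
aa) ≻ SST (both regions in order) ≻ unclassified. STs contain the SST-like
N-terminal block, so repeat evidence must dominate; the size condition on
the BURP call keeps genuine SSTs from being shadowed by their
motif-resembling N-terminus. BURP detection is a motif proxy only — no
PF03181 domain model is evaluated — hence the class name BURP_LIKE.

## Curation flags

- *1 — mature sequence does not start with R (operational reading of
  "cleavage site does not correspond to the canonical start").
- *2 — no SP annotated; the full precursor is carried forward, flagged.
- *3 — length < 50 aa, or region 1 present but region 2 absent.
- *4 — start ≠ R but an R within the first 10 residues (configurable
  window) yields a sequence whose region-1 match starts at position 1;
  filtering keeps that R-trimmed form and records the original as removed.
- OVERSIZE — mature length > 90 aa with no other domain claimed.
- OUTLIER — a manual, config-driven id list; never inferred.

Flags are advisory, recomputable and idempotent. `filter_canonical`
removes *1/*2/*3/OVERSIZE/OUTLIER entries and replaces valid *4 entries by
their trimmed forms. Because the trimmed form enters the kept set while the
original is recorded as removed, `len(kept) + len(removed)` exceeds the
input size by one per trimmed entry; the invariant tested is that the
original ids partition exactly between `removed` and the untrimmed kept
set, with trimmed forms traceable by `parent_id`. Thresholds 50/90 and the
10-residue window default to the family's size envelope and are config.

## Physicochemistry

Average residue masses plus one water (18.0153 Da) give Mw; monoisotopic
masses are out of scope. pI solves net charge = 0 by bisection on [0, 14]
to 1e-4 pH; the Henderson–Hasselbalch net charge is strictly decreasing in
pH, so the root is unique. The pKa set (N-term 7.50, C-term 3.55, D 4.05,
E 4.45, H 5.98, C 9.00, Y 10.00, K 10.00, R 12.00) and the mass table are
module constants chosen for bit-for-bit reproducibility rather than
mimicry of any particular web tool; published pKa sets differ enough to
shift extreme pI values by a few tenths of a pH unit.

## Conservation, consensus and trees

Per-column information content is log2(20) − H over **non-gap** symbols
(max 4.32 bits); the gap-scaled stack width is 1 − gap_fraction; an
all-gap column has 0 bits and width 0. No small-sample correction by
default (`small_sample_correction=True` subtracts 19/(2 ln 2 · n)).

Consensus emission: a column contributes its modal residue when bits ≥ 2.0
and gap fraction ≤ 0.5 (both config); other columns are wildcards, and
consecutive wildcard columns collapse to `x{a,b}` with a/b the min/max
number of residues the aligned sequences actually place there. The
thresholds were fixed so that a planted synthetic SST alignment reproduces
the family consensus tokens (`Rx{5,7}YW…`); the consensus string re-parses
in the motif mini-language.

Distances are uncorrected p-distances over shared non-gap columns (error on
disjoint coverage). Neighbour joining is the standard Saitou–Nei
agglomeration with Q-matrix minimisation; ties break on the
lexicographically smallest label pair, so output is deterministic. True
branch lengths (possibly negative at internal edges, as NJ allows) are kept
in the Newick output; render as a cladogram if preferred. The final three
nodes join at an unrooted trifurcation. On additive matrices the
reconstruction is exact: tests regenerate random additive trees (n ≤ 12)
and verify path lengths to 1e-9, and cross-check leaf path-lengths against
scikit-bio's independent NJ.

## Core pentapeptides

For STs, each chained repeat contributes the `xxxxY` occupying positions
7–11 of its repeat hit — the in-repeat reading; the alternative
"immediately after the repeat" reading exists in the literature and is not
used here. For SSTs the anchor is the Y of the conserved terminal YH of
region 2 (which aligns with the repeat consensus), giving at most one
candidate. Cores are always 5 residues ending in Y; `ser_thr_cpa` is true
when position 3 (two before the Tyr) is S or T. No cyclisation chemistry is
modelled.

## Family summaries

Features (first-exon/intron/CDS length; SP length, mature length, Mw in
kDa, pI) are binned per family group on config edges defaulting to the
ranges conventionally quoted for the family (CDS ≤ 200, 201–250, …, > 400
bp; mature ≤ 50, 51–60, …, > 90 aa; intron bands around 70–200 bp).
Integer features use closed integer bins; continuous features use [lo, hi)
with the last bin closed. Percentages are per group × feature and sum
to 100; empty groups are omitted with a log note. The exact figure-panel
edges of the source analyses are not published, so these defaults are an
interpretation, not constants.

## Synthetic data: what it emulates and what it does not

The generator instantiates the family templates with family profiles:
SP-length distributions peaking at 26 aa (Brassicaceae, 72%) or 22 aa
(Fabaceae/Other), R-to-YW spacers of 5–7 (7 mainly in Brassicaceae),
interzones of 10/19/34 aa, first exons of 57/45/45 bp (77%/62%/57% modal),
introns uniform on 70–200 bp, and family embellishments (Brassicaceae
P-L-P-E-P; Fabaceae P-M-P, I-L-Y-H and the YH-x-H tail; a conserved C in
the ST non-repeat zone; a degenerate DFD… first repeat in STs).

Variable positions draw from a reduced 12-letter alphabet that excludes
the anchor residues (F, I, L, M, P, R, W, Y), so zero-noise outputs cannot
contain spurious anchor matches — classification and flag recovery on the
truth set are exact *by construction*. Within a family, variable positions
follow a family consensus (drawn deterministically per group from disjoint
sub-alphabets) with conservation 0.85/0.70/0.55 for
Brassicaceae/Fabaceae/Other, reflecting the observed ordering of
within-family conservation; this gives family clading in p-distance NJ
trees while keeping pooled multi-family logo columns below the consensus
threshold at variable positions. The bundled SST alignment places gaps
only in spacer/interzone/tail, so conserved-block columns are gap-free.

Consequently, passing tests show the pipeline is correct on data that obey
the family architecture — they do not show robustness to real-world
artefacts the generator omits: codon-level errors, indels inside conserved
blocks, compositional biases, chimeric annotations, or anchor residues
appearing at variable positions. Misannotated variants are planted
mutations of canonical SSTs (start substitution, SP-annotation removal,
C-terminal truncation to 40–48 aa, 3–8 extra N-terminal residues, tail
inflation past 90 aa), with all implied flags recorded in the truth table.
Dataset composition defaults to 50 SST (split ~52:34:65 across
Brassicaceae:Fabaceae:Other, the proportions of curated collections), 20
ST (2–8 repeats, absent from Brassicaceae), 30 decoys; generation is
byte-identical per seed.

## Problem sizes

The default test suite and the acceptance script use 100-record truth sets,
300–1000 random sequences (≤ 200 aa) for scanner-vs-oracle checks, 1000
random peptides for the physicochemical invariants and 15–20 random
additive trees (n ≤ 12) for NJ; the whole suite runs in a few seconds.

## Known limitations

- BURP-likeness is a motif proxy; a PF03181 HMM search would be stronger.
- SP lengths are trusted annotation; a hydrophobicity heuristic is
  deliberately not part of the default path.
- pI/Mw values depend on the fixed tables; comparisons against other tools
  need a tolerance of a few tenths of a pH unit / fractions of a percent.
- Multiple alignments are consumed, never computed; logo and consensus
  quality inherit the input alignment's quality.
- The mismatch budgets are calibrated for ~40–300 aa family proteins;
  scanning much longer sequences raises the false-positive odds and the
  budgets should be tightened accordingly.
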