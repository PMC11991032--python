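"""Synthetic DUF2775 dataset generator with planted ground truth.

Emulates the statistical structure of a curated family collection: SST
proteins built from the two-conserved-region template
(R + spacer + YW...LL, family-length interzone, FxxxF...I[IL]YH, variable
tail) with family-typical signal-peptide lengths, spacers, interzones and
gene models; ST proteins sharing the N-terminal block plus k tandem
25/26-aa repeats (a degenerate DFDxxPxxxxY first repeat, then canonical
EFEPRPxxxxY units); BURP-like decoys carrying the Ax{6}YWx{7}PMP
N-terminal motif on an oversize body; random decoys; and misannotated SST
variants that plant each curation flag.  Every record's class, flags and
repeat count are recorded in a truth table, and generation is fully
deterministic given a seed.

Wildcard positions are drawn from a reduced alphabet excluding the anchor
residues of the family motifs (F, I, L, M, P, R, W, Y), so zero-noise
outputs can never contain spurious anchor matches and classification on
the truth set is exact by construction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .curation import CurationFlag
from .io_model import (
    Alignment,
    FamilyGroup,
    GeneModel,
    SequenceRecord,
    write_alignment,
    write_annotations,
    write_fasta,
    write_gene_models,
)

#: wildcard alphabet: 20 standard residues minus the family-motif anchors
WILDCARD_ALPHABET = "ACDEGHKNQSTV"
#: signal peptides: initiator Met plus a hydrophobic-rich body (no R/Y/W,
#: and none within reach of the extra-N-terminal trimming window)
SP_BODY_ALPHABET = "ALVIFSTG"
FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilyProfile:
    """Family-typical architecture parameters for SST generation.

    Lengths in residues (gene features in bp).  Defaults follow the modal
    values observed per taxonomic group: signal peptides peaking at 26
    (Brassicaceae) or 22 (Fabaceae/Other) residues; R-to-YW spacers of 5-7
    (7 mainly in Brassicaceae); interzones of 10/19/34 residues; first
    exons of 57/45/45 bp; introns of 70-200 bp."""

    group: FamilyGroup
    sp_len_values: tuple = (26, 24, 25, 27, 28)
    sp_len_probs: tuple = (0.72, 0.07, 0.07, 0.07, 0.07)
    spacer_values: tuple = (5, 7)
    spacer_probs: tuple = (0.75, 0.25)
    interzone_len: int = 10
    tail_range: tuple = (2, 8)
    exon1_values: tuple = (57, 54, 60)
    exon1_probs: tuple = (0.77, 0.115, 0.115)
    intron_range: tuple = (70, 200)
    #: probability that a variable position carries the family's own
    #: consensus residue rather than a random one; highest in the
    #: extremely conserved Brassicaceae, lowest in the heterogeneous
    #: Other group.  Gives within-family similarity so family groups
    #: clade in distance trees, as real collections do.
    wildcard_conservation: float = 0.85


def default_profiles() -> dict:
    """The three family profiles used throughout the package."""
    return {
        FamilyGroup.BRASSICACEAE: FamilyProfile(group=FamilyGroup.BRASSICACEAE),
        FamilyGroup.FABACEAE: FamilyProfile(
            group=FamilyGroup.FABACEAE,
            sp_len_values=(22, 20, 21, 23, 24),
            sp_len_probs=(0.47, 0.1325, 0.1325, 0.1325, 0.1325),
            spacer_values=(5, 6, 7),
            spacer_probs=(0.8, 0.1, 0.1),
            interzone_len=19,
            tail_range=(4, 14),
            exon1_values=(45, 48, 51),
            exon1_probs=(0.62, 0.19, 0.19),
            wildcard_conservation=0.70,
        ),
        FamilyGroup.OTHER: FamilyProfile(
            group=FamilyGroup.OTHER,
            sp_len_values=(22, 20, 21, 23, 24),
            sp_len_probs=(0.40, 0.15, 0.15, 0.15, 0.15),
            spacer_values=(5, 6, 7),
            spacer_probs=(0.8, 0.1, 0.1),
            interzone_len=34,
            tail_range=(2, 12),
            exon1_values=(45, 48, 51),
            exon1_probs=(0.57, 0.215, 0.215),
            wildcard_conservation=0.55,
        ),
    }


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one generated record."""

    id: str
    true_class: str  # SST | ST | BURP_LIKE | DECOY
    planted_flags: frozenset = frozenset()
    n_repeats: int = 0
    family_group: FamilyGroup = FamilyGroup.OTHER


@dataclass(frozen=True)
class _SSTParts:
    """Segment decomposition of a generated SST mature sequence, kept so the
    bundled alignment can be built with gaps only in the variable segments."""

    spacer: str
    block1a: str  # YW x3 M x3 P x P x2 I x2 L L
    interzone: str
    region2: str  # F x3 F x5 I [IL] Y H
    tail: str

    @property
    def mature(self) -> str:
        return "R" + self.spacer + self.block1a + self.interzone + self.region2 + self.tail


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _choice(rng: np.random.Generator, values, probs):
    return values[rng.choice(len(values), p=np.asarray(probs) / np.sum(probs))]


def _signal_peptide(rng: np.random.Generator, length: int) -> str:
    return "M" + _draw(rng, SP_BODY_ALPHABET, length - 1)


#: disjoint consensus sub-alphabets so no variable position is shared
#: between family consensuses: pooled multi-family alignments stay
#: heterogeneous at variable columns while each family is internally
#: conserved
_CONSENSUS_ALPHABETS = {
    FamilyGroup.BRASSICACEAE: "ACDE",
    FamilyGroup.FABACEAE: "GHKN",
    FamilyGroup.OTHER: "QSTV",
}


def _family_consensus(profile: FamilyProfile) -> str:
    """Deterministic per-family consensus residues for variable positions.

    Seeded from the group name only, so the same family always carries the
    same consensus irrespective of dataset composition or seed."""
    seed = zlib.crc32(profile.group.value.encode())
    rng = np.random.default_rng(seed)
    return _draw(rng, _CONSENSUS_ALPHABETS[profile.group], 80)


def _draw_conserved(rng: np.random.Generator, consensus: str, p: float) -> str:
    """Each position: the family consensus residue with probability ``p``,
    otherwise a random non-anchor residue."""
    out = []
    for c in consensus:
        out.append(c if rng.random() < p else _draw(rng, WILDCARD_ALPHABET, 1))
    return "".join(out)


def _sst_parts(profile: FamilyProfile, rng: np.random.Generator) -> _SSTParts:
    cons = _family_consensus(profile)
    p = profile.wildcard_conservation

    def wild(offset: int, n: int) -> str:
        return _draw_conserved(rng, cons[offset : offset + n], p)

    # the R-to-YW spacer is variable in every family: no consensus pull
    spacer_len = _choice(rng, profile.spacer_values, profile.spacer_probs)
    spacer = _draw(rng, WILDCARD_ALPHABET, spacer_len)
    if profile.group == FamilyGroup.BRASSICACEAE:
        # the highly conserved P-L-P-E-P stretch
        pxp = "PLPEP"
    else:
        mid = "M" if rng.random() < 0.7 else wild(7, 1)
        pxp = "P" + mid + "P" + wild(8, 2)
    block1a = "YW" + wild(10, 3) + "M" + wild(13, 3) + pxp + "I" + wild(16, 2) + "LL"
    interzone = wild(18, profile.interzone_len)
    second_i = "L" if profile.group == FamilyGroup.FABACEAE and rng.random() < 0.7 else "I"
    region2 = "F" + wild(52, 3) + "F" + wild(55, 5) + "I" + second_i + "YH"
    tail_len = int(rng.integers(profile.tail_range[0], profile.tail_range[1] + 1))
    if profile.group == FamilyGroup.FABACEAE:
        # YH-X-H pattern: the tail starts with (usually) T then H
        x = "T" if rng.random() < 0.7 else _draw(rng, "ACDEGKNQS", 1)
        tail = x + "H" + wild(62, max(tail_len - 2, 0))
    else:
        tail = wild(60, tail_len)
    return _SSTParts(spacer=spacer, block1a=block1a, interzone=interzone, region2=region2, tail=tail)


def _taxon(group: FamilyGroup, index: int) -> str:
    stem = {"Brassicaceae": "Synbrassica", "Fabaceae": "Synfaba", "Other": "Synplanta"}[group.value]
    return f"{stem} simulata {index}"


def generate_sst(
    profile: FamilyProfile,
    rng: np.random.Generator,
    record_id: str = "SST_1",
    taxon: str = "",
):
    """One canonical SST: (SequenceRecord, GeneModel, TruthRecord, parts).

    The CDS is stop-codon-inclusive (3 x protein length + 3); the first
    exon and intron lengths follow the family profile."""
    sp_len = _choice(rng, profile.sp_len_values, profile.sp_len_probs)
    parts = _sst_parts(profile, rng)
    residues = _signal_peptide(rng, sp_len) + parts.mature
    record = SequenceRecord(
        id=record_id,
        residues=residues,
        taxon=taxon or _taxon(profile.group, 1),
        family_group=profile.group,
        sp_length=sp_len,
    )
    model = GeneModel(
        gene_id=record_id,
        exon1_len=_choice(rng, profile.exon1_values, profile.exon1_probs),
        intron_len=int(rng.integers(profile.intron_range[0], profile.intron_range[1] + 1)),
        cds_len=3 * len(residues) + 3,
    )
    truth = TruthRecord(id=record_id, true_class="SST", family_group=profile.group)
    return record, model, truth, parts


def generate_st(
    profile: FamilyProfile,
    k_repeats: int,
    rng: np.random.Generator,
    record_id: str = "ST_1",
    taxon: str = "",
):
    """One ST protein: shared N-terminal block, a non-repeat zone with its
    well-conserved C, then a degenerate first repeat (DFDxxPxxxxY) and
    k-1 canonical EFEPRPxxxxY repeats, all of one unit length (25 or 26)."""
    if k_repeats < 2:
        raise ValueError("ST proteins have at least 2 tandem repeats")
    w = WILDCARD_ALPHABET
    sp_len = _choice(rng, profile.sp_len_values, profile.sp_len_probs)
    spacer = _draw(rng, w, _choice(rng, profile.spacer_values, profile.spacer_probs))
    block1 = (
        "R" + spacer + "YW" + _draw(rng, w, 3) + "M" + _draw(rng, w, 3)
        + "P" + _draw(rng, w, 1) + "P" + _draw(rng, w, 2) + "I" + _draw(rng, w, 2) + "LL"
    )
    filler_len = int(rng.integers(45, 66))
    c_pos = int(rng.integers(5, filler_len - 5))
    filler = _draw(rng, w.replace("C", ""), filler_len)
    filler = filler[:c_pos] + "C" + filler[c_pos + 1 :]
    unit_len = int(rng.integers(25, 27))
    pad = unit_len - 11
    units = ["DFD" + _draw(rng, w, 2) + "P" + _draw(rng, w, 4) + "Y" + _draw(rng, w, pad)]
    for _ in range(k_repeats - 1):
        units.append("EFEPRP" + _draw(rng, w, 4) + "Y" + _draw(rng, w, pad))
    residues = _signal_peptide(rng, sp_len) + block1 + filler + "".join(units)
    record = SequenceRecord(
        id=record_id,
        residues=residues,
        taxon=taxon or _taxon(profile.group, 1),
        family_group=profile.group,
        sp_length=sp_len,
    )
    truth = TruthRecord(
        id=record_id, true_class="ST", n_repeats=k_repeats, family_group=profile.group
    )
    return record, truth


def generate_burp_like(
    rng: np.random.Generator, record_id: str = "BURP_1", taxon: str = "Synplanta simulata 1"
):
    """A BURP-like decoy: the Ax{6}YWx{7}PMP N-terminal motif on a body well
    beyond the SST size envelope."""
    w = WILDCARD_ALPHABET
    sp_len = int(rng.integers(22, 27))
    mature = (
        "A" + _draw(rng, w, 6) + "YW" + _draw(rng, w, 7) + "PMP"
        + _draw(rng, w, int(rng.integers(120, 181)))
    )
    residues = _signal_peptide(rng, sp_len) + mature
    record = SequenceRecord(
        id=record_id, residues=residues, taxon=taxon,
        family_group=FamilyGroup.OTHER, sp_length=sp_len,
    )
    return record, TruthRecord(id=record_id, true_class="BURP_LIKE")


def generate_decoy(
    rng: np.random.Generator, record_id: str = "DECOY_1", taxon: str = "Synplanta simulata 1"
):
    """A random protein drawn uniformly from the full 20-letter alphabet."""
    sp_len = int(rng.integers(18, 25))
    mature_len = int(rng.integers(55, 81))
    residues = _signal_peptide(rng, sp_len) + _draw(rng, FULL_ALPHABET, mature_len)
    record = SequenceRecord(
        id=record_id, residues=residues, taxon=taxon,
        family_group=FamilyGroup.OTHER, sp_length=sp_len,
    )
    return record, TruthRecord(id=record_id, true_class="DECOY")


_MISANNOTATION_FLAGS = (
    CurationFlag.NONCANONICAL_START,
    CurationFlag.NO_SP,
    CurationFlag.TRUNCATED_CTERM,
    CurationFlag.EXTRA_NTERM,
    CurationFlag.OVERSIZE,
)


def generate_misannotated(
    record: SequenceRecord,
    truth: TruthRecord,
    flag: CurationFlag,
    rng: np.random.Generator,
):
    """Mutate a canonical SST so curation must assign the given flag.

    The returned truth lists every flag the mutation implies by
    construction (e.g. dropping the signal-peptide annotation also makes
    the first mature residue non-R)."""
    sp = record.sp_length
    mature = record.residues[sp:]
    planted = {flag}
    if flag == CurationFlag.NONCANONICAL_START:
        new_mature = _draw(rng, "ANQSTG", 1) + mature[1:]
        residues, sp_len = record.residues[:sp] + new_mature, sp
    elif flag == CurationFlag.NO_SP:
        residues, sp_len = record.residues, None
        planted.add(CurationFlag.NONCANONICAL_START)
        if len(record.residues) > 90:
            planted.add(CurationFlag.OVERSIZE)
    elif flag == CurationFlag.TRUNCATED_CTERM:
        keep = int(rng.integers(40, 49))
        residues, sp_len = record.residues[:sp] + mature[:keep], sp
    elif flag == CurationFlag.EXTRA_NTERM:
        max_ext = min(8, 90 - len(mature))
        if max_ext < 3:
            raise ValueError("mature too long to plant an extra N-terminus within the size envelope")
        ext = _draw(rng, WILDCARD_ALPHABET, int(rng.integers(3, max_ext + 1)))
        residues, sp_len = record.residues[:sp] + ext + mature, sp
        planted.add(CurationFlag.NONCANONICAL_START)
    elif flag == CurationFlag.OVERSIZE:
        extra = _draw(rng, WILDCARD_ALPHABET, 91 - len(mature) + int(rng.integers(0, 25)))
        residues, sp_len = record.residues + extra, sp
    else:
        raise ValueError(f"cannot plant flag {flag}")
    new_id = f"{record.id}_{flag.name}"
    mutated = SequenceRecord(
        id=new_id, residues=residues, taxon=record.taxon,
        family_group=record.family_group, sp_length=sp_len,
    )
    new_truth = TruthRecord(
        id=new_id, true_class="SST", planted_flags=frozenset(planted),
        family_group=truth.family_group,
    )
    return mutated, new_truth


@dataclass
class SimConfig:
    """Dataset composition.  SST counts are split over the family groups in
    roughly the proportions seen in curated collections (about one third
    Brassicaceae, a quarter Fabaceae, the rest Other)."""

    n_sst: int = 50
    n_st: int = 20
    n_burp: int = 0
    n_decoy: int = 30
    n_misannotated_per_flag: int = 0
    st_repeat_range: tuple = (2, 8)
    family_weights: tuple = (52, 34, 65)
    make_alignment: bool = True


@dataclass
class DatasetBundle:
    records: list
    gene_models: list
    truths: list
    aligned_sst: Optional[Alignment] = None

    @property
    def truth_by_id(self) -> dict:
        return {t.id: t for t in self.truths}


def _split_counts(total: int, weights) -> list:
    weights = np.asarray(weights, dtype=float)
    raw = weights / weights.sum() * total
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for i in range(total - counts.sum()):
        counts[order[i % len(counts)]] += 1
    return list(counts)


def _build_alignment(entries: list) -> Alignment:
    """Gapped rows for the SST set: gaps only in spacer, interzone and tail,
    so every conserved-block column is gap-free."""
    max_sp = max(len(p.spacer) for _, p in entries)
    max_iz = max(len(p.interzone) for _, p in entries)
    max_tail = max(len(p.tail) for _, p in entries)
    rows = []
    for rid, p in entries:
        gapped = (
            "R"
            + p.spacer.ljust(max_sp, "-")
            + p.block1a
            + p.interzone.ljust(max_iz, "-")
            + p.region2
            + p.tail.ljust(max_tail, "-")
        )
        rows.append((rid, gapped))
    return Alignment(rows=tuple(rows))


def generate_dataset(config: SimConfig = SimConfig(), seed: int = 0) -> DatasetBundle:
    """Generate the full labelled dataset; byte-identical given a seed."""
    rng = np.random.default_rng(seed)
    profiles = default_profiles()
    records, models, truths, sst_parts = [], [], [], []
    groups = [FamilyGroup.BRASSICACEAE, FamilyGroup.FABACEAE, FamilyGroup.OTHER]
    counts = _split_counts(config.n_sst, config.family_weights)
    idx = 1
    sst_pool = []  # canonical SSTs usable as misannotation bases
    for group, n in zip(groups, counts):
        for i in range(n):
            rid = f"SST_{group.value[:3]}_{idx:04d}"
            rec, model, truth, parts = generate_sst(
                profiles[group], rng, record_id=rid, taxon=_taxon(group, i + 1)
            )
            records.append(rec)
            models.append(model)
            truths.append(truth)
            sst_parts.append((rid, parts))
            sst_pool.append((rec, truth))
            idx += 1
    for i in range(config.n_st):
        group = groups[int(rng.integers(1, 3))]  # STs are absent from Brassicaceae
        k = int(rng.integers(config.st_repeat_range[0], config.st_repeat_range[1] + 1))
        rec, truth = generate_st(
            profiles[group], k, rng, record_id=f"ST_{i + 1:04d}", taxon=_taxon(group, i + 1)
        )
        records.append(rec)
        truths.append(truth)
    for i in range(config.n_burp):
        rec, truth = generate_burp_like(rng, record_id=f"BURP_{i + 1:04d}")
        records.append(rec)
        truths.append(truth)
    for i in range(config.n_decoy):
        rec, truth = generate_decoy(rng, record_id=f"DECOY_{i + 1:04d}")
        records.append(rec)
        truths.append(truth)
    if config.n_misannotated_per_flag > 0:
        for flag in _MISANNOTATION_FLAGS:
            for i in range(config.n_misannotated_per_flag):
                base_idx = int(rng.integers(0, len(sst_pool)))
                base_rec, base_truth = sst_pool[base_idx]
                if flag == CurationFlag.EXTRA_NTERM:
                    # need headroom below the oversize bound
                    tries = 0
                    while len(base_rec.residues) - base_rec.sp_length > 87 and tries < 50:
                        base_idx = int(rng.integers(0, len(sst_pool)))
                        base_rec, base_truth = sst_pool[base_idx]
                        tries += 1
                mut, truth = generate_misannotated(base_rec, base_truth, flag, rng)
                mut = replace(mut, id=f"{mut.id}_{i + 1}")
                truth = replace(truth, id=mut.id)
                records.append(mut)
                truths.append(truth)
    aligned = _build_alignment(sst_parts) if (config.make_alignment and sst_parts) else None
    return DatasetBundle(records=records, gene_models=models, truths=truths, aligned_sst=aligned)


def write_dataset(bundle: DatasetBundle, outdir) -> None:
    """Write sequences.faa, gene_models.tsv, annotations.tsv, truth.tsv and
    (when present) aligned_sst.fasta under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.records, outdir / "sequences.faa")
    write_gene_models(bundle.gene_models, outdir / "gene_models.tsv")
    write_annotations(bundle.records, outdir / "annotations.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("id\ttrue_class\tplanted_flags\tn_repeats\tfamily_group\n")
        for t in bundle.truths:
            flags = ",".join(sorted(f.value for f in t.planted_flags))
            fh.write(f"{t.id}\t{t.true_class}\t{flags}\t{t.n_repeats}\t{t.family_group.value}\n")
    if bundle.aligned_sst is not None:
        write_alignment(bundle.aligned_sst, outdir / "aligned_sst.fasta")
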