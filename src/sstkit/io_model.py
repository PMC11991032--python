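"""Shared record types and readers/writers for the formats the pipeline touches.

Sequences travel as FASTA, alignments as aligned FASTA or Clustal, gene
models and per-sequence annotations as TSV with a header row.  All
coordinates reported anywhere in the package are 1-based closed intervals;
internal indexing is 0-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: 'X' is tolerated in input sequences but never matches a motif element.
VALID_INPUT_RESIDUES = VALID_RESIDUES | {"X"}

GAP_GLYPHS = ".-~"


class FamilyGroup(str, enum.Enum):
    """Taxonomic grouping used throughout the comparative analyses."""

    BRASSICACEAE = "Brassicaceae"
    FABACEAE = "Fabaceae"
    OTHER = "Other"

    @classmethod
    def coerce(cls, value: "str | FamilyGroup") -> "FamilyGroup":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).capitalize())
        except ValueError:
            return cls.OTHER


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A raw protein entry: precursor sequence plus annotation.

    ``sp_length`` is the annotated signal-peptide length in residues (the
    pipeline consumes signal-peptide calls, it does not predict them).
    """

    id: str
    residues: str
    taxon: str = ""
    family_group: FamilyGroup = FamilyGroup.OTHER
    sp_length: Optional[int] = None

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_INPUT_RESIDUES
        if bad:
            offset = min(i for i, c in enumerate(self.residues) if c in bad) + 1
            raise FormatError(
                f"record {self.id!r}: illegal residue {sorted(bad)[0]!r} at position {offset}"
            )
        if self.sp_length is not None:
            if self.sp_length < 0:
                raise FormatError(f"record {self.id!r}: negative sp_length")
            if self.sp_length >= len(self.residues):
                raise FormatError(
                    f"record {self.id!r}: sp_length {self.sp_length} >= sequence length "
                    f"{len(self.residues)}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron architecture of a single-intron gene.

    ``cds_len`` is stop-codon-inclusive by default; pass
    ``cds_includes_stop=False`` at read time for the other dialect.
    ``exon2_len`` is always derived as ``cds_len - exon1_len``.
    """

    gene_id: str
    exon1_len: int
    intron_len: int
    cds_len: int
    cds_includes_stop: bool = True

    def __post_init__(self) -> None:
        for name in ("exon1_len", "intron_len", "cds_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"gene {self.gene_id!r}: {name} must be positive")
        if self.exon1_len >= self.cds_len:
            raise ValueError(
                f"gene {self.gene_id!r}: exon1_len {self.exon1_len} >= cds_len {self.cds_len}"
            )
        if self.cds_len % 3 != 0:
            raise ValueError(f"gene {self.gene_id!r}: cds_len {self.cds_len} not divisible by 3")

    @property
    def exon2_len(self) -> int:
        return self.cds_len - self.exon1_len

    @property
    def protein_len(self) -> int:
        """Encoded protein length in residues (stop codon excluded)."""
        n_codons = self.cds_len // 3
        return n_codons - 1 if self.cds_includes_stop else n_codons


@dataclass(frozen=True)
class Alignment:
    """A multiple alignment: rows of equal gapped length, gap char '-'."""

    rows: tuple
    ncols: int = field(default=0)

    def __post_init__(self) -> None:
        rows = tuple((str(i), str(s)) for i, s in self.rows)
        object.__setattr__(self, "rows", rows)
        if rows:
            lengths = {len(s) for _, s in rows}
            if len(lengths) != 1:
                ragged = [i for i, s in rows if len(s) != len(rows[0][1])]
                raise FormatError(f"ragged alignment rows: {ragged}")
            object.__setattr__(self, "ncols", len(rows[0][1]))

    @property
    def ids(self) -> list:
        return [i for i, _ in self.rows]

    def column(self, index: int) -> str:
        """1-based column as a string of symbols."""
        return "".join(s[index - 1] for _, s in self.rows)


def _normalise_residues(raw: str, record_id: str) -> str:
    seq = raw.upper().rstrip("*")
    bad = set(seq) - VALID_INPUT_RESIDUES
    if bad:
        offset = min(i for i, c in enumerate(seq) if c in bad) + 1
        raise FormatError(
            f"record {record_id!r}: illegal residue {sorted(bad)[0]!r} at position {offset}"
        )
    return seq


def read_fasta(path, annotations: Optional[pd.DataFrame] = None) -> list:
    """Read protein FASTA into ``SequenceRecord`` objects, input order kept.

    Residues are uppercased and trailing '*' stop symbols stripped.  If an
    annotation table (from :func:`read_annotations`) is given, taxon, family
    group and signal-peptide length are joined in by id.
    """
    path = Path(path)
    ann = {}
    if annotations is not None:
        ann = {str(r["id"]): r for _, r in annotations.iterrows()}
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _normalise_residues(str(entry.seq), entry.id)
        meta = ann.get(entry.id)
        sp = None
        taxon = ""
        group = FamilyGroup.OTHER
        if meta is not None:
            sp_val = meta.get("sp_length")
            if sp_val is not None and not pd.isna(sp_val):
                sp = int(sp_val)
            taxon = str(meta.get("taxon", "") or "")
            group = FamilyGroup.coerce(meta.get("family_group", "Other"))
        records.append(
            SequenceRecord(id=entry.id, residues=seq, taxon=taxon, family_group=group, sp_length=sp)
        )
    return records


def write_fasta(records: Iterable, path) -> None:
    """Write records (anything with ``.id`` and ``.residues``) as FASTA."""
    bio = [_BioRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


GENE_MODEL_COLUMNS = ("gene_id", "exon1_len", "intron_len", "cds_len")


def read_gene_models(path, cds_includes_stop: bool = True) -> list:
    """Read a gene-model TSV (header: gene_id, exon1_len, intron_len, cds_len).

    Rows violating the invariants (non-positive lengths, exon1 >= CDS,
    CDS not a codon multiple) raise a validation error naming the row.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"gene-model table missing columns: {sorted(missing)}")
    models = []
    for i, row in df.iterrows():
        try:
            models.append(
                GeneModel(
                    gene_id=str(row["gene_id"]),
                    exon1_len=int(row["exon1_len"]),
                    intron_len=int(row["intron_len"]),
                    cds_len=int(row["cds_len"]),
                    cds_includes_stop=cds_includes_stop,
                )
            )
        except ValueError as exc:
            raise ValueError(f"gene-model row {i + 2}: {exc}") from exc
    return models


def write_gene_models(models: Iterable, path) -> None:
    df = pd.DataFrame(
        [(m.gene_id, m.exon1_len, m.intron_len, m.cds_len) for m in models],
        columns=list(GENE_MODEL_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read the per-sequence annotation TSV (id, taxon, family_group, sp_length)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise FormatError("annotation table must have an 'id' column")
    return df


def write_annotations(records: Iterable, path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "taxon": r.taxon,
                "family_group": r.family_group.value,
                "sp_length": "" if r.sp_length is None else r.sp_length,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alignment(path, format: str = "aligned-fasta") -> Alignment:
    """Read an alignment; '.' and '~' gap glyphs are normalised to '-'.

    ``format`` is ``aligned-fasta`` or ``clustal``.  Both encodings of the
    same alignment yield identical ``Alignment`` values.
    """
    fmt = {"aligned-fasta": "fasta", "fasta": "fasta", "clustal": "clustal"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    aln = AlignIO.read(str(path), fmt)
    rows = []
    for rec in aln:
        gapped = str(rec.seq).upper()
        for glyph in GAP_GLYPHS:
            gapped = gapped.replace(glyph, "-")
        rows.append((rec.id, gapped))
    return Alignment(rows=tuple(rows))


def write_alignment(aln: Alignment, path, format: str = "aligned-fasta") -> None:
    from Bio.Align import MultipleSeqAlignment

    msa = MultipleSeqAlignment([_BioRecord(Seq(s), id=i, description="") for i, s in aln.rows])
    fmt = {"aligned-fasta": "fasta", "fasta": "fasta", "clustal": "clustal"}[format]
    AlignIO.write(msa, str(path), fmt)
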