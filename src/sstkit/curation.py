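"""Mature-protein derivation, misannotation flagging and canonical filtering.

Database-mined DUF2775 entries are frequently misannotated: wrong start
codon choice, missing signal peptide, C-terminally truncated models, or
extra N-terminal sequence ahead of the true mature start.  The flags here
reproduce that curation scheme: *1 non-canonical start, *2 no signal
peptide, *3 truncated C-terminus, *4 extra N-terminal sequence — plus an
oversize class for unusually long members and a config-driven manual
outlier list.  Flags are advisory; :func:`filter_canonical` turns them into
the kept/removed partition used for all comparative analyses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_model import FamilyGroup, SequenceRecord
from .motifs import (
    DEFAULT_MOTIF_CONFIG,
    MotifConfig,
    find_sst_regions,
    match_region1,
)


class CurationFlag(str, enum.Enum):
    NONCANONICAL_START = "*1"
    NO_SP = "*2"
    TRUNCATED_CTERM = "*3"
    EXTRA_NTERM = "*4"
    OVERSIZE = "OVERSIZE"
    OUTLIER = "OUTLIER"


@dataclass
class CurationConfig:
    """Thresholds for the misannotation flags.

    ``truncation_min``/``oversize_max`` default to the family's size
    envelope (mature proteins of 51-90 aa are typical; shorter ones look
    C-terminally truncated, longer ones carry extra sequence).
    ``extra_nterm_window`` bounds how far downstream the true mature-start
    R may sit.  ``outlier_ids`` is a manual exclusion list."""

    truncation_min: int = 50
    oversize_max: int = 90
    extra_nterm_window: int = 10
    outlier_ids: frozenset = frozenset()
    motif: MotifConfig = field(default_factory=MotifConfig)


DEFAULT_CURATION_CONFIG = CurationConfig()


@dataclass(frozen=True)
class MatureProtein:
    """A signal-peptide-stripped protein plus its curation flags."""

    id: str
    residues: str
    flags: frozenset = frozenset()
    family_group: FamilyGroup = FamilyGroup.OTHER
    taxon: str = ""
    parent_id: Optional[str] = None

    @property
    def length_aa(self) -> int:
        return len(self.residues)

    def with_flags(self, flags) -> "MatureProtein":
        return MatureProtein(
            id=self.id,
            residues=self.residues,
            flags=frozenset(flags),
            family_group=self.family_group,
            taxon=self.taxon,
            parent_id=self.parent_id,
        )


def derive_mature(record: SequenceRecord) -> MatureProtein:
    """Strip the annotated signal peptide; without one, the full sequence is
    kept and the NO_SP flag is raised."""
    if record.sp_length is not None:
        if record.sp_length >= len(record.residues):
            raise ValueError(
                f"record {record.id!r}: sp_length {record.sp_length} covers the whole sequence"
            )
        return MatureProtein(
            id=record.id,
            residues=record.residues[record.sp_length:],
            family_group=record.family_group,
            taxon=record.taxon,
            parent_id=record.id,
        )
    return MatureProtein(
        id=record.id,
        residues=record.residues,
        flags=frozenset({CurationFlag.NO_SP}),
        family_group=record.family_group,
        taxon=record.taxon,
        parent_id=record.id,
    )


def _trimmed_form(mature: MatureProtein, config: CurationConfig) -> Optional[MatureProtein]:
    """The R-trimmed candidate for an extra-N-terminal entry, if valid."""
    window = mature.residues[: config.extra_nterm_window]
    for offset, residue in enumerate(window):
        if residue != "R" or offset == 0:
            continue
        candidate = mature.residues[offset:]
        r1 = match_region1(candidate, config.motif)
        if r1 is not None and r1.start == 1:
            return MatureProtein(
                id=mature.id + "|trimmed",
                residues=candidate,
                family_group=mature.family_group,
                taxon=mature.taxon,
                parent_id=mature.parent_id or mature.id,
            )
    return None


def assign_flags(mature: MatureProtein, config: CurationConfig = DEFAULT_CURATION_CONFIG) -> frozenset:
    """Recompute the advisory flag set for a mature protein (idempotent)."""
    flags = set(mature.flags & {CurationFlag.NO_SP})  # NO_SP comes from derivation
    seq = mature.residues
    if mature.id in config.outlier_ids or (mature.parent_id or "") in config.outlier_ids:
        flags.add(CurationFlag.OUTLIER)
    if not seq.startswith("R"):
        flags.add(CurationFlag.NONCANONICAL_START)
        if _trimmed_form(mature, config) is not None:
            flags.add(CurationFlag.EXTRA_NTERM)
    r1 = match_region1(seq, config.motif)
    sst = find_sst_regions(seq, config.motif)
    if mature.length_aa < config.truncation_min or (r1 is not None and sst is None):
        flags.add(CurationFlag.TRUNCATED_CTERM)
    if mature.length_aa > config.oversize_max:
        flags.add(CurationFlag.OVERSIZE)
    return frozenset(flags)


def flag_matures(
    records: Iterable[SequenceRecord], config: CurationConfig = DEFAULT_CURATION_CONFIG
) -> list:
    """Derive matures from raw records and attach their flags."""
    out = []
    for record in records:
        mature = derive_mature(record)
        out.append(mature.with_flags(assign_flags(mature, config)))
    return out


#: flags whose presence removes an entry outright
_REMOVAL_FLAGS = (
    CurationFlag.NO_SP,
    CurationFlag.TRUNCATED_CTERM,
    CurationFlag.OVERSIZE,
    CurationFlag.OUTLIER,
)


def filter_canonical(
    matures: Iterable[MatureProtein], config: CurationConfig = DEFAULT_CURATION_CONFIG
):
    """Partition flagged matures into the canonical analysis set and the
    removed set (with per-entry reasons).

    Entries flagged *2/*3/OVERSIZE/OUTLIER are removed; *4 entries are
    replaced by their R-trimmed canonical form (the original is recorded as
    removed); remaining *1 entries are removed; unflagged entries are kept.
    ``len(kept) + len(removed) == len(input)`` always (trimmed forms replace
    their originals in the kept set)."""
    kept = []
    removed = []
    for mature in matures:
        flags = mature.flags
        hard = [f for f in _REMOVAL_FLAGS if f in flags]
        if hard:
            removed.append((mature, ", ".join(f.value for f in hard)))
            continue
        if CurationFlag.EXTRA_NTERM in flags:
            trimmed = _trimmed_form(mature, config)
            if trimmed is not None:
                kept.append(trimmed.with_flags(assign_flags(trimmed, config)))
                removed.append((mature, "*4 (trimmed form retained)"))
                continue
            removed.append((mature, CurationFlag.EXTRA_NTERM.value))
            continue
        if CurationFlag.NONCANONICAL_START in flags:
            removed.append((mature, CurationFlag.NONCANONICAL_START.value))
            continue
        kept.append(mature)
    return kept, removed


def curation_report(kept, removed):
    """Tidy per-entry report rows: id, length_aa, flags, action, reason."""
    rows = []
    for m in kept:
        rows.append(
            {
                "id": m.id,
                "length_aa": m.length_aa,
                "flags": ",".join(sorted(f.value for f in m.flags)),
                "action": "kept",
                "reason": "",
            }
        )
    for m, reason in removed:
        rows.append(
            {
                "id": m.id,
                "length_aa": m.length_aa,
                "flags": ",".join(sorted(f.value for f in m.flags)),
                "action": "removed",
                "reason": reason,
            }
        )
    return rows
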