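"""Putative cyclopeptide-alkaloid (burpitide) core pentapeptide extraction.

Under the burpitide hypothesis, the xxxxY motif — once per tandem repeat in
ST proteins, once in the C-terminal conserved block of SST proteins — is
the core peptide of a ribosomally synthesised and post-translationally
modified peptide (RiPP).  The mature cyclopeptide would be closed by a
Tyr-phenol-O-to-C ether bond; when Ser or Thr sits two positions before the
Tyr the core matches the Ser/Thr cyclopeptide-alkaloid (xxS/TxY) class.
Only the pentapeptide slicing and that annotation are done here — no
cyclisation chemistry is modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .motifs import Evidence, ProteinClass

logger = logging.getLogger(__name__)

CORE_LENGTH = 5


@dataclass(frozen=True)
class CoreCandidate:
    """A 5-residue putative core ending in the anchoring Tyr.

    ``ser_thr_cpa`` marks the xxS/TxY sub-class (S or T at core position 3,
    two residues before the Tyr)."""

    parent_id: str
    source: str  # "ST_REPEAT" or "SST_REGION2"
    span: tuple  # 1-based closed interval on the mature sequence
    core: str

    def __post_init__(self) -> None:
        if len(self.core) != CORE_LENGTH or not self.core.endswith("Y"):
            raise ValueError(f"core {self.core!r} is not a 5-mer ending in Y")

    @property
    def ser_thr_cpa(self) -> bool:
        return self.core[2] in ("S", "T")


def extract_cores(parent_id: str, seq: str, protein_class: ProteinClass, evidence: Evidence) -> list:
    """Core pentapeptides for one classified sequence.

    ST: the xxxxY tail of every chained repeat hit (one candidate per
    repeat).  SST: the xxxxY ending at the Y of the region-2 terminal YH
    (at most one candidate).  A repeat or region whose anchor position is
    not actually a Y (possible under the mismatch budget) is skipped with a
    logged reason."""
    candidates = []
    if protein_class == ProteinClass.ST:
        for hit in evidence.repeat_track.hits:
            end = hit.end  # pattern ends on the anchor Y
            start = end - CORE_LENGTH + 1
            core = seq[start - 1 : end]
            if len(core) != CORE_LENGTH or not core.endswith("Y"):
                logger.warning(
                    "%s: repeat at %d-%d lacks a qualifying terminal Y; candidate omitted",
                    parent_id, hit.start, hit.end,
                )
                continue
            candidates.append(
                CoreCandidate(parent_id=parent_id, source="ST_REPEAT", span=(start, end), core=core)
            )
    elif protein_class == ProteinClass.SST and evidence.sst_match is not None:
        # region 2 ends ...I[IL]YH: the anchor Y is the penultimate position
        y_pos = evidence.sst_match.region2_span[1] - 1
        start = y_pos - CORE_LENGTH + 1
        core = seq[start - 1 : y_pos] if start >= 1 else ""
        if len(core) == CORE_LENGTH and core.endswith("Y"):
            candidates.append(
                CoreCandidate(
                    parent_id=parent_id, source="SST_REGION2", span=(start, y_pos), core=core
                )
            )
        else:
            logger.warning(
                "%s: conserved block lacks a qualifying Y with 4 preceding residues; "
                "candidate omitted", parent_id,
            )
    return candidates
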