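"""Family-binned percentage distributions of gene and protein features.

Comparative analyses in this family are reported per taxonomic group
(Brassicaceae, Fabaceae, Other) as percentage histograms of gene-structure
features (first-exon, intron and CDS lengths) and protein features
(signal-peptide length, mature size, Mw, pI).  Bin edges follow the ranges
conventionally quoted for the family (e.g. CDS 201-250 / 251-300 bp,
mature 51-60 / 61-90 aa) and are configuration, not constants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .curation import derive_mature
from .io_model import FamilyGroup, GeneModel, SequenceRecord
from .physchem import isoelectric_point, molecular_weight

logger = logging.getLogger(__name__)

INF = math.inf


@dataclass(frozen=True)
class Bin:
    """A half-open interval [lo, hi); the last bin of a spec is closed above."""

    label: str
    lo: float
    hi: float


def make_bins(edges: list, fmt=lambda v: f"{v:g}") -> list:
    """Contiguous bins from an ascending edge list (first lo may be -inf,
    last hi may be +inf)."""
    bins = []
    for lo, hi in zip(edges, edges[1:]):
        if math.isinf(lo):
            label = f"<={fmt(hi)}" if not math.isinf(hi) else "all"
        elif math.isinf(hi):
            label = f">{fmt(lo)}"
        else:
            label = f"{fmt(lo)}-{fmt(hi)}"
        bins.append(Bin(label=label, lo=lo, hi=hi))
    return bins


def _int_bins(*closed_ranges) -> list:
    """Bins from closed integer ranges, e.g. (201, 250) -> [201, 251)."""
    bins = []
    for lo, hi in closed_ranges:
        if math.isinf(lo):
            label, blo = f"<={hi:g}", -INF
        else:
            label, blo = (f"{lo:g}-{hi:g}" if not math.isinf(hi) else f">={lo:g}"), lo
        bhi = hi + 1 if not math.isinf(hi) else INF
        bins.append(Bin(label=label, lo=blo, hi=bhi))
    return bins


@dataclass
class BinConfig:
    """Default bin edges per feature (all overridable)."""

    cds_len: list = field(
        default_factory=lambda: _int_bins((-INF, 200), (201, 250), (251, 300), (301, 350), (351, 400), (401, INF))
    )
    exon1_len: list = field(
        default_factory=lambda: _int_bins((-INF, 44), (45, 48), (49, 52), (53, 56), (57, 60), (61, INF))
    )
    intron_len: list = field(
        default_factory=lambda: _int_bins((-INF, 69), (70, 200), (201, INF))
    )
    sp_len: list = field(
        default_factory=lambda: _int_bins((-INF, 20), (21, 25), (26, 30), (31, INF))
    )
    mature_len: list = field(
        default_factory=lambda: _int_bins((-INF, 50), (51, 60), (61, 70), (71, 80), (81, 90), (91, INF))
    )
    mw: list = field(  # kDa
        default_factory=lambda: make_bins([0.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, INF])
    )
    pi: list = field(
        default_factory=lambda: make_bins([0.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 14.0])
    )


DEFAULT_BIN_CONFIG = BinConfig()

FEATURES = ("exon1_len", "intron_len", "cds_len", "sp_len", "mature_len", "mw", "pi")


@dataclass(frozen=True)
class FamilySummary:
    """Binned percentage distribution of one feature in one family group."""

    group: FamilyGroup
    feature: str
    bins: tuple
    counts: tuple
    n: int

    @property
    def percentages(self) -> tuple:
        return tuple(100.0 * c / self.n for c in self.counts)

    @property
    def modal_bin(self) -> Bin:
        best = max(range(len(self.bins)), key=lambda i: self.counts[i])
        return self.bins[best]


def _bin_index(bins: list, value: float) -> Optional[int]:
    for i, b in enumerate(bins):
        last = i == len(bins) - 1
        if b.lo <= value < b.hi or (last and value == b.hi):
            return i
    return None


def feature_values(
    records: Iterable[SequenceRecord],
    gene_models: Optional[Iterable[GeneModel]] = None,
) -> list:
    """Per-record feature rows: (group, feature, value) tuples.

    Gene models are joined to records by id; protein features come from the
    signal-peptide annotation and the derived mature sequence (Mw in kDa)."""
    gm = {m.gene_id: m for m in (gene_models or [])}
    rows = []
    for record in records:
        group = record.family_group
        if not isinstance(group, FamilyGroup):
            logger.warning("record %s: unknown family group %r, assigned to Other", record.id, group)
            group = FamilyGroup.OTHER
        model = gm.get(record.id)
        if model is not None:
            rows.append((group, "exon1_len", model.exon1_len))
            rows.append((group, "intron_len", model.intron_len))
            rows.append((group, "cds_len", model.cds_len))
        if record.sp_length is not None:
            rows.append((group, "sp_len", record.sp_length))
        mature = derive_mature(record).residues
        rows.append((group, "mature_len", len(mature)))
        rows.append((group, "mw", molecular_weight(mature) / 1000.0))
        rows.append((group, "pi", isoelectric_point(mature)))
    return rows


def summarize(
    records: Iterable[SequenceRecord],
    gene_models: Optional[Iterable[GeneModel]] = None,
    config: BinConfig = DEFAULT_BIN_CONFIG,
) -> list:
    """Binned percentage summaries per (family group, feature).

    Groups or features with no observations are omitted (with a log note);
    each summary's percentages sum to 100."""
    rows = feature_values(records, gene_models)
    out = []
    for group in FamilyGroup:
        for feature in FEATURES:
            values = [v for g, f, v in rows if g == group and f == feature]
            if not values:
                logger.info("no %s observations for group %s; omitted", feature, group.value)
                continue
            bins = getattr(config, feature)
            counts = [0] * len(bins)
            for v in values:
                idx = _bin_index(bins, v)
                if idx is None:
                    raise ValueError(f"value {v} outside the {feature} bin range")
                counts[idx] += 1
            out.append(
                FamilySummary(
                    group=group, feature=feature, bins=tuple(bins), counts=tuple(counts), n=len(values)
                )
            )
    return out


def summary_table(summaries: Iterable[FamilySummary]):
    """Tidy rows (group, feature, bin, count, percentage) for TSV export."""
    rows = []
    for s in summaries:
        for b, c, p in zip(s.bins, s.counts, s.percentages):
            rows.append(
                {
                    "group": s.group.value,
                    "feature": s.feature,
                    "bin": b.label,
                    "count": c,
                    "percentage": round(p, 4),
                }
            )
    return rows
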