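"""PROSITE-style motif compilation and scanning, tandem-repeat detection and
sequence classification for the DUF2775 (PF10950) protein family.

The family splits into two architectures sharing one N-terminal conserved
block: ST proteins carry tandem 25-26 aa repeats containing EFEPRPxxxxY,
while SST proteins instead carry a second short conserved block
(FxxxF...I[IL]YH) after a family-length interzone.  BURP-domain proteins
recovered by family searches share a resembling N-terminal motif
(Ax{6}YWx{7}PMP) and are called out as BURP_LIKE here because detection is
by motif proxy, not by a PF03181 domain model.

Pattern mini-language
---------------------
``R``        fixed residue (uppercase one-letter code)
``x``        wildcard (any residue)
``x{a}``     exactly ``a`` wildcards
``x{a,b}``   between ``a`` and ``b`` wildcards
``[ILV]``    residue class
``{P}``      negated class (any residue except those listed)

Mismatches are counted on non-wildcard elements only.  An 'X' in the
subject never satisfies a fixed or class element.  A negated class placed
beyond the end of the subject matches vacuously (an absent residue cannot
be the forbidden one), which makes C-terminal exclusion patterns such as
the N-glycosylation site N-{P}-[ST]-{P} behave as PROSITE users expect.
"""

from __future__ import annotations

import enum
import re
import statistics
from dataclasses import dataclass, field
from typing import Optional

from .io_model import VALID_RESIDUES


class PatternError(ValueError):
    """Malformed motif pattern specification."""


@dataclass(frozen=True)
class Fixed:
    residue: str


@dataclass(frozen=True)
class ResidueClass:
    residues: frozenset


@dataclass(frozen=True)
class NegatedClass:
    residues: frozenset


@dataclass(frozen=True)
class WildcardRun:
    lo: int
    hi: int


_TOKEN = re.compile(
    r"""
    (?P<fixed>[A-WYZ])            # uppercase fixed residue (x is reserved)
  | (?P<run>x(?:\{(?P<a>\d+)(?:,(?P<b>\d+))?\})?)
  | \[(?P<cls>[A-Z]+)\]
  | \{(?P<neg>[A-Z]+)\}
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class MotifPattern:
    """A compiled motif: an ordered tuple of match elements."""

    elements: tuple
    source: str = ""

    @property
    def n_scored(self) -> int:
        """Number of elements that can incur mismatches (non-wildcards)."""
        return sum(1 for e in self.elements if not isinstance(e, WildcardRun))

    def canonical(self) -> str:
        out = []
        for e in self.elements:
            if isinstance(e, Fixed):
                out.append(e.residue)
            elif isinstance(e, ResidueClass):
                out.append("[" + "".join(sorted(e.residues)) + "]")
            elif isinstance(e, NegatedClass):
                out.append("{" + "".join(sorted(e.residues)) + "}")
            else:
                if e.lo == e.hi:
                    out.append("x" if e.lo == 1 else f"x{{{e.lo}}}")
                else:
                    out.append(f"x{{{e.lo},{e.hi}}}")
        return "".join(out)


def compile_pattern(spec: str) -> MotifPattern:
    """Compile a pattern string; raises :class:`PatternError` with the offset
    of the first malformed token."""
    elements = []
    pos = 0
    while pos < len(spec):
        m = _TOKEN.match(spec, pos)
        if m is None:
            raise PatternError(f"malformed token at offset {pos} in {spec!r}")
        if m.group("fixed"):
            res = m.group("fixed")
            if res not in VALID_RESIDUES:
                raise PatternError(f"unknown residue {res!r} at offset {pos}")
            elements.append(Fixed(res))
        elif m.group("run"):
            a = m.group("a")
            b = m.group("b")
            lo = int(a) if a else 1
            hi = int(b) if b else lo
            if lo > hi:
                raise PatternError(f"bounded run x{{{lo},{hi}}} has lo > hi at offset {pos}")
            elements.append(WildcardRun(lo, hi))
        elif m.group("cls"):
            bad = set(m.group("cls")) - VALID_RESIDUES
            if bad:
                raise PatternError(f"unknown residue in class at offset {pos}")
            elements.append(ResidueClass(frozenset(m.group("cls"))))
        else:
            bad = set(m.group("neg")) - VALID_RESIDUES
            if bad:
                raise PatternError(f"unknown residue in negated class at offset {pos}")
            elements.append(NegatedClass(frozenset(m.group("neg"))))
        pos = m.end()
    if not elements or all(isinstance(e, WildcardRun) for e in elements):
        raise PatternError("pattern needs at least one non-wildcard element")
    return MotifPattern(elements=tuple(elements), source=spec)


@dataclass(frozen=True)
class Match:
    """One pattern occurrence. Spans are 1-based closed intervals."""

    start: int
    end: int
    mismatches: int
    #: length chosen for each bounded wildcard run, in pattern order
    run_lengths: tuple = ()


def _element_cost(element, residue: Optional[str]) -> Optional[int]:
    """Mismatch cost of placing ``element`` on ``residue`` (None = past end).

    Returns None when the placement is structurally impossible (a residue
    is required but the sequence has ended)."""
    if residue is None:
        # only a negated class matches vacuously past the end
        return 0 if isinstance(element, NegatedClass) else None
    if isinstance(element, Fixed):
        return 0 if residue == element.residue else 1
    if isinstance(element, ResidueClass):
        return 0 if (residue != "X" and residue in element.residues) else 1
    if isinstance(element, NegatedClass):
        return 0 if (residue != "X" and residue not in element.residues) else 1
    raise TypeError(element)


def _match_at(elements, seq: str, start: int, budget: int):
    """Best match of ``elements`` anchored at 0-based ``start``.

    Returns (end_exclusive, mismatches, run_lengths) or None.  Preference
    order: fewest mismatches, then shortest span, then lexicographically
    smallest run-length tuple (deterministic)."""
    best = None

    def recurse(ei: int, pos: int, mism: int, runs: tuple):
        nonlocal best
        if mism > budget:
            return
        if ei == len(elements):
            cand = (mism, pos, runs)
            if best is None or cand < best:
                best = cand
            return
        e = elements[ei]
        if isinstance(e, WildcardRun):
            for take in range(e.lo, e.hi + 1):
                if pos + take > len(seq):
                    break
                recurse(ei + 1, pos + take, mism, runs + (take,))
        else:
            residue = seq[pos] if pos < len(seq) else None
            cost = _element_cost(e, residue)
            if cost is None:
                return
            advance = 1 if residue is not None else 0
            recurse(ei + 1, pos + advance, mism + cost, runs)

    recurse(0, start, 0, ())
    if best is None:
        return None
    mism, end, runs = best
    return end, mism, runs


def scan(pattern: MotifPattern, seq: str, max_mismatch: int = 0) -> list:
    """All occurrences of ``pattern`` in ``seq``, leftmost-first.

    Overlapping occurrences are reported; at most one (the best) per start
    position.  Spans are 1-based closed."""
    hits = []
    for start in range(len(seq)):
        got = _match_at(pattern.elements, seq, start, max_mismatch)
        if got is None:
            continue
        end, mism, runs = got
        if end == start:  # fully vacuous, not a real occurrence
            continue
        hits.append(Match(start=start + 1, end=min(end, len(seq)), mismatches=mism, run_lengths=runs))
    return hits


# ---------------------------------------------------------------------------
# Family-specific motifs

#: N-terminal conserved block shared by SST and ST proteins.
REGION1 = "Rx{5,7}YWx{3}Mx{3}PxPx{2}Ix{2}LL"
#: Second conserved block characteristic of SST proteins.
REGION2 = "Fx{3}Fx{5}I[IL]YH"
#: Canonical ST tandem-repeat signature.
ST_REPEAT = "EFEPRPx{4}Y"
#: Degenerate form of the first ST repeat (also the SST C-terminal block
#: when read against the repeat consensus).
ST_REPEAT_DEGENERATE = "DFDx{2}Px{4}Y"
#: N-terminal motif shared by BURP-domain proteins.
BURP_NTERM = "Ax{6}YWx{7}PMP"

PTM_PATTERNS = {
    "N_GLYC": "N{P}[ST]{P}",
    "PKC": "[ST]x[RK]",
    "CK2": "[ST]x{2}[DE]",
    "MYRISTOYL": "G{EDRKHPFYW}x{2}[STAGCN]{P}",
    "AMIDATION": "xG[RK][RK]",
}


@dataclass
class MotifConfig:
    """Mismatch budgets and windows for family-motif scanning.

    Budgets are an operationalisation of by-eye matching: chosen so the
    canonical family anchors match while random ~70-mers essentially never
    do (validated by simulation in the test-suite)."""

    region1_mismatch_budget: int = 3
    region2_mismatch_budget: int = 2
    repeat_mismatch_budget: int = 2
    period_min: int = 20
    period_max: int = 30
    burp_window: int = 60
    oversize_max: int = 90


DEFAULT_MOTIF_CONFIG = MotifConfig()


@dataclass(frozen=True)
class SSTMatch:
    """Joint occurrence of the two SST conserved regions.

    ``spacer_len`` counts residues strictly between the leading R and the Y
    of YW; ``interzone_len`` is the variable segment between the regions and
    ``tail_len`` the unconstrained C-terminal stretch after region 2."""

    region1_span: tuple
    region2_span: tuple
    spacer_len: int
    interzone_len: int
    tail_len: int
    mismatches: int


@dataclass(frozen=True)
class RepeatTrack:
    """Chained tandem-repeat hits with their estimated period."""

    hits: tuple
    n_repeats: int
    period: Optional[int]


@dataclass(frozen=True)
class PTMSite:
    kind: str
    span: tuple


class ProteinClass(str, enum.Enum):
    ST = "ST"
    SST = "SST"
    BURP_LIKE = "BURP_LIKE"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class Evidence:
    """All sub-results backing a classification decision."""

    repeat_track: RepeatTrack
    burp_match: Optional[Match]
    sst_match: Optional[SSTMatch]


_REGION1_COMPILED = compile_pattern(REGION1)
_REGION2_COMPILED = compile_pattern(REGION2)
_ST_REPEAT_COMPILED = compile_pattern(ST_REPEAT)
_ST_DEGENERATE_COMPILED = compile_pattern(ST_REPEAT_DEGENERATE)
_BURP_COMPILED = compile_pattern(BURP_NTERM)
_PTM_COMPILED = {kind: compile_pattern(p) for kind, p in PTM_PATTERNS.items()}


def match_region1(seq: str, config: MotifConfig = DEFAULT_MOTIF_CONFIG) -> Optional[Match]:
    """Leftmost best occurrence of the shared N-terminal block.

    ``run_lengths[0]`` of the returned match is the R-to-YW spacer length."""
    hits = scan(_REGION1_COMPILED, seq, config.region1_mismatch_budget)
    return hits[0] if hits else None


def find_sst_regions(seq: str, config: MotifConfig = DEFAULT_MOTIF_CONFIG) -> Optional[SSTMatch]:
    """Locate both SST conserved regions, in order, or return None."""
    r1 = match_region1(seq, config)
    if r1 is None:
        return None
    r2_hits = [
        h
        for h in scan(_REGION2_COMPILED, seq, config.region2_mismatch_budget)
        if h.start > r1.end
    ]
    if not r2_hits:
        return None
    r2 = r2_hits[0]
    return SSTMatch(
        region1_span=(r1.start, r1.end),
        region2_span=(r2.start, r2.end),
        spacer_len=r1.run_lengths[0],
        interzone_len=r2.start - r1.end - 1,
        tail_len=len(seq) - r2.end,
        mismatches=r1.mismatches + r2.mismatches,
    )


def detect_st_repeats(seq: str, config: MotifConfig = DEFAULT_MOTIF_CONFIG) -> RepeatTrack:
    """Find the tandem-repeat track: EFEPRPxxxxY hits (with mismatch budget)
    plus the exactly-matching degenerate first-repeat form, chained by
    inter-start spacing within [period_min, period_max].

    The period is the median inter-start spacing, defined only for two or
    more chained repeats."""
    canonical = scan(_ST_REPEAT_COMPILED, seq, config.repeat_mismatch_budget)
    degenerate = scan(_ST_DEGENERATE_COMPILED, seq, 0)
    by_start = {}
    for h in canonical + degenerate:
        if h.start not in by_start or h.mismatches < by_start[h.start].mismatches:
            by_start[h.start] = h
    hits = [by_start[s] for s in sorted(by_start)]
    if not hits:
        return RepeatTrack(hits=(), n_repeats=0, period=None)
    # longest chain under the spacing constraint (DP over sorted starts)
    n = len(hits)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            gap = hits[i].start - hits[j].start
            if config.period_min <= gap <= config.period_max and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -hits[i].start))
    chain = []
    while end != -1:
        chain.append(hits[end])
        end = prev[end]
    chain.reverse()
    period = None
    if len(chain) >= 2:
        spacings = [b.start - a.start for a, b in zip(chain, chain[1:])]
        period = int(round(statistics.median(spacings)))
    return RepeatTrack(hits=tuple(chain), n_repeats=len(chain), period=period)


def detect_burp_nterm(seq: str, config: MotifConfig = DEFAULT_MOTIF_CONFIG) -> Optional[Match]:
    """Exact occurrence of the BURP N-terminal motif starting within the
    first ``burp_window`` residues, or None."""
    for h in scan(_BURP_COMPILED, seq, 0):
        if h.start <= config.burp_window:
            return h
    return None


def scan_ptm_sites(seq: str) -> list:
    """Standard post-translational-modification site patterns, all hits."""
    sites = []
    for kind, pat in _PTM_COMPILED.items():
        for h in scan(pat, seq, 0):
            sites.append(PTMSite(kind=kind, span=(h.start, h.end)))
    sites.sort(key=lambda s: (s.span, s.kind))
    return sites


def classify(seq_or_record, config: MotifConfig = DEFAULT_MOTIF_CONFIG):
    """Classify a (mature) sequence as ST / SST / BURP_LIKE / UNCLASSIFIED.

    Accepts a plain residue string, a SequenceRecord (classified on its
    mature part when a signal peptide is annotated) or a MatureProtein.
    Decision order: tandem repeats trump everything (ST proteins contain the
    SST-like N-terminal block too); the BURP motif only counts on proteins
    larger than the SST size envelope; otherwise the joint two-region SST
    match decides.  Returns (ProteinClass, Evidence)."""
    if isinstance(seq_or_record, str):
        seq = seq_or_record
    elif getattr(seq_or_record, "sp_length", None) is not None:
        seq = seq_or_record.residues[seq_or_record.sp_length:]
    else:
        seq = seq_or_record.residues
    track = detect_st_repeats(seq, config)
    burp = detect_burp_nterm(seq, config)
    sst = find_sst_regions(seq, config)
    evidence = Evidence(repeat_track=track, burp_match=burp, sst_match=sst)
    if track.n_repeats >= 2:
        return ProteinClass.ST, evidence
    if burp is not None and len(seq) > config.oversize_max:
        return ProteinClass.BURP_LIKE, evidence
    if sst is not None:
        return ProteinClass.SST, evidence
    return ProteinClass.UNCLASSIFIED, evidence
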