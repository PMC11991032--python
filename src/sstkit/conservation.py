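"""Alignment conservation statistics, consensus derivation, p-distances and
neighbour-joining trees.

The logo statistics follow the WebLogo conventions: per-column information
content in bits over the 20-letter amino-acid alphabet (maximum
log2(20) = 4.32 bits for a fully conserved, gap-free column), with stack
widths scaled by the fraction of non-gap symbols in the column.  Distances
are uncorrected p-distances and trees are standard Saitou-Nei
neighbour-joining with deterministic lexicographic tie-breaking, emitted as
Newick with true branch lengths (render as a cladogram if preferred).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_model import Alignment

MAX_BITS = math.log2(20.0)


@dataclass(frozen=True)
class LogoColumn:
    """Conservation statistics for one alignment column (1-based index).

    ``freqs`` are relative frequencies over non-gap symbols; ``bits`` is
    log2(20) minus the Shannon entropy of those frequencies; ``width`` is
    the gap-scaled stack width, 1 - gap_fraction."""

    index: int
    freqs: dict
    gap_fraction: float
    bits: float

    @property
    def width(self) -> float:
        return 1.0 - self.gap_fraction

    @property
    def modal_residue(self) -> Optional[str]:
        if not self.freqs:
            return None
        return max(sorted(self.freqs), key=lambda r: self.freqs[r])


def logo_columns(aln: Alignment, small_sample_correction: bool = False) -> list:
    """Per-column residue frequencies, gap fraction and information content.

    An all-gap column has 0 bits and width 0.  The optional small-sample
    correction subtracts (19 / (2 ln 2 n)) from the information content,
    clipped at zero; it is off by default."""
    if not aln.rows:
        raise ValueError("empty alignment")
    cols = []
    nrows = len(aln.rows)
    for index in range(1, aln.ncols + 1):
        symbols = aln.column(index)
        residues = [s for s in symbols if s != "-"]
        gap_fraction = 1.0 - len(residues) / nrows
        if not residues:
            cols.append(LogoColumn(index=index, freqs={}, gap_fraction=1.0, bits=0.0))
            continue
        freqs = {}
        for r in residues:
            freqs[r] = freqs.get(r, 0) + 1
        total = len(residues)
        freqs = {r: c / total for r, c in sorted(freqs.items())}
        entropy = -sum(p * math.log2(p) for p in freqs.values())
        bits = MAX_BITS - entropy
        if small_sample_correction:
            bits -= 19.0 / (2.0 * math.log(2.0) * total)
        cols.append(
            LogoColumn(index=index, freqs=freqs, gap_fraction=gap_fraction, bits=max(bits, 0.0))
        )
    return cols


def consensus_from_logo(
    cols: list,
    aln: Optional[Alignment] = None,
    bits_min: float = 2.0,
    gap_max: float = 0.5,
) -> str:
    """Consensus string in the motif mini-language.

    A column emits its modal residue when its information content reaches
    ``bits_min`` and its gap fraction stays below ``gap_max``; all other
    columns are wildcards.  Consecutive wildcard columns collapse to a
    bounded run ``x{a,b}`` where a/b are the min/max number of residues the
    aligned sequences actually place in that stretch (requires the
    alignment; without it the column count is used)."""
    emitted = [
        c.bits >= bits_min and c.gap_fraction <= gap_max and c.modal_residue is not None
        for c in cols
    ]
    tokens = []
    i = 0
    while i < len(cols):
        if emitted[i]:
            tokens.append(cols[i].modal_residue)
            i += 1
            continue
        j = i
        while j < len(cols) and not emitted[j]:
            j += 1
        if aln is not None:
            counts = [
                sum(1 for c in range(i, j) if s[c] != "-") for _, s in aln.rows
            ]
            lo, hi = min(counts), max(counts)
        else:
            lo = hi = j - i
        if hi > 0:
            if lo == hi:
                tokens.append("x" if lo == 1 else f"x{{{lo}}}")
            else:
                tokens.append(f"x{{{lo},{hi}}}")
        i = j
    return "".join(tokens)


def p_distance(a: str, b: str) -> float:
    """Uncorrected proportion of mismatches over shared non-gap columns."""
    if len(a) != len(b):
        raise ValueError("gapped lengths differ")
    shared = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        shared += 1
        if x != y:
            mismatches += 1
    if shared == 0:
        raise ValueError("no shared non-gap columns")
    return mismatches / shared


def distance_matrix(aln: Alignment):
    """(labels, symmetric p-distance matrix) for all row pairs."""
    labels = aln.ids
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(aln.rows[i][1], aln.rows[j][1])
    return labels, d


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def nj_tree(d: np.ndarray, labels: list) -> str:
    """Neighbour-joining (Saitou-Nei) tree as a Newick string.

    Validates symmetry/non-negativity, minimises the Q criterion at each
    agglomeration with ties broken by the lexicographically smallest label
    pair, and keeps true (possibly negative) branch lengths.  Exact on
    additive matrices."""
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("matrix/label size mismatch")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if (d < -1e-12).any():
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")

    # each active node: (sort_label, newick_fragment)
    nodes = {i: (str(labels[i]), str(labels[i])) for i in range(n)}
    if len({lab for lab, _ in nodes.values()}) != n:
        raise ValueError("duplicate labels")
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}
    next_id = n

    def get(i, j):
        return dist[(i, j) if i < j else (j, i)]

    while len(nodes) > 3:
        active = sorted(nodes)
        m = len(nodes)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * get(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((nodes[i][0], nodes[j][0])))
                cand = (q, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        dij = get(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        frag = f"({nodes[i][1]}:{_fmt(li)},{nodes[j][1]}:{_fmt(lj)})"
        sort_label = min(nodes[i][0], nodes[j][0])
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_id), max(k, next_id))] = (get(i, k) + get(j, k) - dij) / 2.0
        del nodes[i], nodes[j]
        nodes[next_id] = (sort_label, frag)
        next_id += 1

    if len(nodes) == 2:
        (i, j) = sorted(nodes)
        half = get(i, j) / 2.0
        return f"({nodes[i][1]}:{_fmt(half)},{nodes[j][1]}:{_fmt(half)});"
    # three remaining nodes join at one internal vertex (unrooted star)
    a, b, c = sorted(nodes)
    la = (get(a, b) + get(a, c) - get(b, c)) / 2.0
    lb = (get(a, b) + get(b, c) - get(a, c)) / 2.0
    lc = (get(a, c) + get(b, c) - get(a, b)) / 2.0
    return (
        f"({nodes[a][1]}:{_fmt(la)},{nodes[b][1]}:{_fmt(lb)},{nodes[c][1]}:{_fmt(lc)});"
    )
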