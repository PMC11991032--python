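"""Molecular weight and isoelectric point of peptides.

Average (not monoisotopic) residue masses; pI by bisection of the
Henderson-Hasselbalch net charge, which is strictly decreasing in pH, so
the zero crossing is unique.  Both tables are module-level constants and
can be swapped wholesale for reproducibility studies; different published
pKa sets shift pI extremes by a few tenths of a pH unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

WATER_MASS = 18.0153

#: average residue (i.e. amino acid minus water) masses, Daltons
RESIDUE_MASSES: Mapping[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: pKa values of ionisable groups
PKA = {
    "nterm": 7.50,
    "cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "H": 5.98,
    "C": 9.00,
    "Y": 10.00,
    "K": 10.00,
    "R": 12.00,
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Daltons: residue masses plus one water."""
    if not seq:
        raise ValueError("empty sequence")
    try:
        return sum(RESIDUE_MASSES[r] for r in seq) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} (X not allowed here)") from None


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at the given pH (termini included)."""
    if not seq:
        raise ValueError("empty sequence")
    positive = 1.0 / (1.0 + 10.0 ** (ph - PKA["nterm"]))
    negative = 1.0 / (1.0 + 10.0 ** (PKA["cterm"] - ph))
    for r in _POSITIVE:
        n = seq.count(r)
        if n:
            positive += n / (1.0 + 10.0 ** (ph - PKA[r]))
    for r in _NEGATIVE:
        n = seq.count(r)
        if n:
            negative += n / (1.0 + 10.0 ** (PKA[r] - ph))
    return positive - negative


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class PhyschemProfile:
    id: str
    length_aa: int
    mw_da: float
    pi: float


def profile(id: str, seq: str) -> PhyschemProfile:
    """Length, Mw and pI of one sequence."""
    return PhyschemProfile(
        id=id, length_aa=len(seq), mw_da=molecular_weight(seq), pi=isoelectric_point(seq)
    )
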