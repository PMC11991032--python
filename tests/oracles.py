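"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration and share no
code with the implementation they check.
"""

import itertools

from sstkit.motifs import Fixed, NegatedClass, WildcardRun


def oracle_scan(pattern, seq, max_mismatch):
    """Every (1-based start, best mismatch count) by enumerating all starts
    and all bounded-run length combinations."""
    runs = [e for e in pattern.elements if isinstance(e, WildcardRun)]
    choices = [range(r.lo, r.hi + 1) for r in runs]
    starts = set()
    for start in range(len(seq)):
        best = None
        for combo in itertools.product(*choices):
            it = iter(combo)
            pos = start
            mism = 0
            feasible = True
            for e in pattern.elements:
                if isinstance(e, WildcardRun):
                    take = next(it)
                    if pos + take > len(seq):
                        feasible = False
                        break
                    pos += take
                elif isinstance(e, NegatedClass):
                    if pos < len(seq):
                        if seq[pos] == "X" or seq[pos] in e.residues:
                            mism += 1
                        pos += 1
                elif pos >= len(seq):
                    feasible = False
                    break
                else:
                    if isinstance(e, Fixed):
                        ok = seq[pos] == e.residue
                    else:
                        ok = seq[pos] != "X" and seq[pos] in e.residues
                    if not ok:
                        mism += 1
                    pos += 1
            if feasible and mism <= max_mismatch:
                if best is None or mism < best:
                    best = mism
        if best is not None:
            starts.add((start + 1, best))
    return starts
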