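"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (enumeration,
direct table summation) without touching the implementation paths they check.
"""

from __future__ import annotations

from cisrate.folding.params import (
    HAIRPIN_A,
    HAIRPIN_B,
    INTERIOR_A,
    INTERIOR_B,
    MIN_HAIRPIN,
    MULTI_A,
    MULTI_B,
    MULTI_C,
    NT_INDEX,
    PAIRABLE,
    stack_energy,
)

# independent copy of the published Watson-Crick duplex parameters for the
# hand-summed duplex oracle (top-strand dinucleotide -> stack DeltaG)
XIA_STACKS = {
    "AA": -0.93, "AU": -1.10, "UA": -1.33, "CU": -2.08, "CA": -2.11,
    "GU": -2.24, "GA": -2.35, "CG": -2.36, "GG": -3.26, "GC": -3.42,
    "UU": -0.93, "AG": -2.08, "UG": -2.11, "AC": -2.24, "UC": -2.35, "CC": -3.26,
}
XIA_INIT = 4.09
XIA_TERM_AU = 0.45
XIA_SYM = 0.43

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def duplex_oracle(top: str) -> float:
    """Hand-summed duplex energy for a top strand (bottom = WC complement)."""
    dg = XIA_INIT
    for i in range(len(top) - 1):
        dg += XIA_STACKS[top[i : i + 2]]
    for end in (top[0], top[-1]):
        if end in "AU":
            dg += XIA_TERM_AU
    bottom_5to3 = "".join(COMPLEMENT[c] for c in reversed(top))
    if top == bottom_5to3:
        dg += XIA_SYM
    return dg


def _legal(a: str, b: str) -> bool:
    return bool(PAIRABLE[NT_INDEX[a], NT_INDEX[b]])


def enumerate_structures(seq: str):
    """All legal nested pairings (hairpin >= MIN_HAIRPIN, legal pairs)."""

    def rec(positions):
        if not positions:
            yield []
            return
        i = positions[0]
        for rest in rec(positions[1:]):
            yield rest
        for j in positions[1:]:
            if j - i - 1 >= MIN_HAIRPIN and _legal(seq[i], seq[j]):
                inside = [p for p in positions if i < p < j]
                outside = [p for p in positions if p > j]
                for s1 in rec(inside):
                    for s2 in rec(outside):
                        yield [(i, j)] + s1 + s2

    yield from rec(list(range(len(seq))))


def structure_energy(seq: str, pairs) -> float:
    """Loop-decomposition energy of a structure under the builtin model."""
    if not pairs:
        return 0.0
    pairs = sorted(pairs)
    children = {p: [] for p in pairs}
    for p in pairs:
        i, j = p
        parent = None
        for q in pairs:
            a, b = q
            if a < i and j < b and (parent is None or a > parent[0]):
                parent = q
        if parent is not None:
            children[parent].append(p)
    total = 0.0
    for i, j in pairs:
        kids = sorted(children[(i, j)])
        if not kids:
            total += HAIRPIN_A + HAIRPIN_B * (j - i - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            if k == i + 1 and l == j - 1:
                total += stack_energy(seq[i], seq[j], seq[k], seq[l])
            else:
                total += INTERIOR_A + INTERIOR_B * ((k - i - 1) + (j - l - 1))
        else:
            unpaired = (j - i - 1) - sum(b - a + 1 for a, b in kids)
            total += MULTI_A + MULTI_B * unpaired + MULTI_C * len(kids)
    return total


def brute_force_mfe(seq: str) -> float:
    best = 0.0
    for pairs in enumerate_structures(seq):
        e = structure_energy(seq, pairs)
        if e < best:
            best = e
    return best
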