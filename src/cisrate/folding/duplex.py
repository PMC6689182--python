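"""Nearest-neighbor Gibbs energies for fully complementary RNA duplexes."""

from __future__ import annotations

from .params import DUPLEX_INIT, SYMMETRY, TERMINAL_AU, WC_COMPLEMENT, WC_STACK


def duplex_energy(strand5to3: str, strand3to5: str) -> float:
    """DeltaG(37C) in kcal/mol of a Watson-Crick RNA duplex.

    ``strand5to3`` is the top strand read 5'->3'; ``strand3to5`` is the bottom
    strand read 3'->5', i.e. aligned position-by-position with the top strand.
    The duplex energy is the initiation term plus the sum of nearest-neighbor
    stacking terms, a per-end penalty for terminal A:U pairs, and a symmetry
    correction for self-complementary duplexes.
    """
    top, bottom = strand5to3.upper().replace("T", "U"), strand3to5.upper().replace("T", "U")
    if len(top) != len(bottom):
        raise ValueError("strands must have equal length")
    if len(top) < 2:
        raise ValueError("duplex must be at least 2 bp")
    for i, (x, y) in enumerate(zip(top, bottom)):
        if WC_COMPLEMENT.get(x) != y:
            raise ValueError(f"non-Watson-Crick pair {x}:{y} at position {i}")

    dg = DUPLEX_INIT
    for i in range(len(top) - 1):
        dg += WC_STACK[top[i : i + 2]]
    for end in (top[0], top[-1]):
        if end in "AU":
            dg += TERMINAL_AU
    if top == bottom[::-1]:  # both strands have the same 5'->3' sequence
        dg += SYMMETRY
    return dg
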