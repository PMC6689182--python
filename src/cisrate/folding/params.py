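"""Embedded thermodynamic constants.

Watson-Crick nearest-neighbor stacking terms, duplex initiation, terminal-AU
penalty and the self-complementary symmetry correction are the published
DeltaG(37C) RNA parameters (kcal/mol). The loop penalties below them are the
*builtin simplified folder's* documented constants: they are deliberately
plain affine forms, not the full Turner loop tables.
"""

from __future__ import annotations

import numpy as np

# -- nearest-neighbor duplex model ------------------------------------------

#: DeltaG(37C) for a Watson-Crick stack, keyed by the top-strand dinucleotide
#: read 5'->3' (the bottom strand is forced by complementarity).
WC_STACK = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}

DUPLEX_INIT = 4.09
TERMINAL_AU = 0.45
SYMMETRY = 0.43

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# -- builtin folder constants ------------------------------------------------

#: stacks involving a G.U wobble pair (simplified flat values)
GU_STACK_ONE = -1.2   # one of the two pairs is G.U
GU_STACK_BOTH = -0.5  # both pairs are G.U

MIN_HAIRPIN = 3        # minimum unpaired nt closed by a hairpin
MAX_INTERIOR = 8       # cap on unpaired nt in bulge/interior loops

HAIRPIN_A, HAIRPIN_B = 4.5, 0.15     # hairpin: A + B * loop_size
INTERIOR_A, INTERIOR_B = 2.0, 0.5    # bulge/interior: A + B * unpaired
MULTI_A, MULTI_B, MULTI_C = 4.0, 0.3, 1.0  # multiloop: A + B*unpaired + C*branch

# -- integer encodings for the dynamic program -------------------------------

NT_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
NT_LETTERS = "ACGU"

#: legal pairs (Watson-Crick + wobble); PAIRABLE[a, b] is True if a:b can pair
PAIRABLE = np.zeros((4, 4), dtype=np.bool_)
for _x, _y in [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]:
    PAIRABLE[NT_INDEX[_x], NT_INDEX[_y]] = True

_WOBBLE = {("G", "U"), ("U", "G")}


def stack_energy(a: str, b: str, c: str, d: str) -> float:
    """Stack term for outer pair a:b over inner pair c:d (a 5' of c, d 5' of b)."""
    outer_gu = (a, b) in _WOBBLE
    inner_gu = (c, d) in _WOBBLE
    if outer_gu and inner_gu:
        return GU_STACK_BOTH
    if outer_gu or inner_gu:
        return GU_STACK_ONE
    return WC_STACK[a + c]


def _build_stack_table() -> np.ndarray:
    tab = np.zeros((4, 4, 4, 4), dtype=np.float64)
    for a in NT_LETTERS:
        for b in NT_LETTERS:
            if not PAIRABLE[NT_INDEX[a], NT_INDEX[b]]:
                continue
            for c in NT_LETTERS:
                for d in NT_LETTERS:
                    if not PAIRABLE[NT_INDEX[c], NT_INDEX[d]]:
                        continue
                    tab[NT_INDEX[a], NT_INDEX[b], NT_INDEX[c], NT_INDEX[d]] = stack_energy(
                        a, b, c, d
                    )
    return tab


#: STACK[a, b, c, d] = stack term for pair a:b immediately enclosing pair c:d
STACK = _build_stack_table()


def encode(seq: str) -> np.ndarray:
    """RNA string -> int8 array (A=0, C=1, G=2, U=3)."""
    try:
        return np.fromiter((NT_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - guarded by record validation
        raise ValueError(f"non-ACGU character {exc} in sequence") from None
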