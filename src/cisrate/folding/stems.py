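"""Dot-bracket stem statistics."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StemStats:
    n_pairs_all: int
    n_pairs_max_stem: int
    n_pairs_contig_stem: int


def parse_pairs(structure: str) -> list[tuple[int, int]]:
    """Base pairs of a balanced dot-bracket string, sorted by opening index."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced structure at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"illegal character {ch!r} in structure")
    if stack:
        raise ValueError("unbalanced structure: unmatched '('")
    return sorted(pairs)


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Decompose pairs into maximal runs of stacked pairs (i,j),(i+1,j-1),..."""
    pair_set = set(pairs)
    helices = []
    seen: set[tuple[int, int]] = set()
    for p in pairs:
        if p in seen:
            continue
        i, j = p
        if (i - 1, j + 1) in pair_set:  # not the outer pair of its run
            continue
        run = []
        while (i, j) in pair_set:
            run.append((i, j))
            seen.add((i, j))
            i, j = i + 1, j - 1
        helices.append(run)
    return helices


def stem_statistics(structure: str) -> StemStats:
    """Pair counts: all pairs, longest stem allowing <=1-nt bulges/mismatches
    at each junction ("max stem"), and longest contiguous helix ("contig")."""
    pairs = parse_pairs(structure)
    if not pairs:
        return StemStats(0, 0, 0)
    helices = _helices(pairs)
    contig = max(len(h) for h in helices)

    # chain helices across junctions with <=1 unpaired nt on each side;
    # a junction is between a helix's innermost pair and the outer pair of
    # its single directly nested helix.
    children: dict[int, list[int]] = {idx: [] for idx in range(len(helices))}
    # direct enclosure: for each helix, find the smallest enclosing helix inner pair
    for idx, h in enumerate(helices):
        oi, oj = h[0]
        best = None
        for pidx, ph in enumerate(helices):
            ii, ij = ph[-1]  # innermost pair of candidate parent
            if ii < oi and oj < ij:
                if best is None or ii > helices[best][-1][0]:
                    best = pidx
        if best is not None:
            children[best].append(idx)

    def best_chain(idx: int) -> int:
        h = helices[idx]
        total = len(h)
        kids = children[idx]
        if len(kids) == 1:
            k = kids[0]
            ii, ij = h[-1]
            oi, oj = helices[k][0]
            gap5, gap3 = oi - ii - 1, ij - oj - 1
            if gap5 <= 1 and gap3 <= 1:
                total += best_chain(k)
        return total

    max_stem = max(best_chain(idx) for idx in range(len(helices)))
    return StemStats(len(pairs), max_stem, contig)
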