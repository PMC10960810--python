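"""Brute-force oracles, independent of the library's incremental algorithms.

Equivalent deletion placements are found by exhaustive result-string
equality (every start position is tried and the spliced sequences are
compared), not by boundary-shift recursion; microhomology is the longest
flank repeat checked by direct slice comparison at every placement.
"""

from __future__ import annotations


def oracle_placements(ref: str, del_start: int, del_end: int) -> list[tuple[int, int]]:
    """All placements of an equal-length deletion yielding the same sequence."""
    L = del_end - del_start
    target = ref[:del_start] + ref[del_end:]
    return [
        (a, a + L)
        for a in range(len(ref) - L + 1)
        if ref[:a] + ref[a + L :] == target
    ]


def oracle_mh(ref: str, del_start: int, del_end: int) -> tuple[int, list[tuple[int, int]]]:
    """Max flank-repeat length over all equivalent placements."""
    best = 0
    placements = oracle_placements(ref, del_start, del_end)
    for a, b in placements:
        for k in range(1, b - a + 1):
            if b + k <= len(ref) and ref[a : a + k] == ref[b : b + k]:
                best = max(best, k)
            else:
                break
    return best, placements


def oracle_classify(ref: str, cut: int, del_start: int, del_end: int,
                    insertion: str = "") -> str:
    """Decision order WT -> INSRT -> MMEJ -> PEPPR -> DELET."""
    if del_start == del_end and not insertion:
        return "WT"
    if insertion:
        return "INSRT"
    mh, placements = oracle_mh(ref, del_start, del_end)
    if mh >= 2 and any(a <= cut <= b for a, b in placements):
        return "MMEJ"
    if any(b == cut for _, b in placements):
        return "PEPPR"
    return "DELET"
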