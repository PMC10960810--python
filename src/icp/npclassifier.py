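"""Nucleotide Position Classifier (NPClassifier).

Infers the edit carried by each amplicon read from the longest exact
prefix/suffix shared with the reference, then assigns the primary repair
class from the positions of the edit start/end relative to the blunt Cas9
cut:

* ``WT``    — read identical to the reference.
* ``INSRT`` — any inserted bases, alone or with a deletion (an internal
  substitution surfaces as a 1-nt deletion plus 1-nt insertion and is
  therefore INSRT, matching the convention that even single substitutions
  near the cut belong to the insertion class).
* ``MMEJ``  — pure deletion explained by annealing of a >=2-nt
  microhomology spanning the cut (some equivalent placement's closed
  interval contains the cut coordinate).
* ``PEPPR`` — pure deletion extending from the cut only in the PAM-distal
  direction (some equivalent placement ends exactly at the cut), the
  PAM-proximal side having been protected by bound Cas9.
* ``DELET`` — any other pure deletion.

MMEJ is tested before PEPPR, so a cut-abutting deletion with a spanning
microhomology is MMEJ, mirroring the exclusion applied when the synthetic
PEPPR dictionary is constructed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .locus import Edit, ReferenceLocus, allele_id_for_edit, canonicalize_edit

__all__ = [
    "CLASS_LABELS",
    "ClassifiedRead",
    "UnparseableReadError",
    "infer_edit",
    "equivalent_placements",
    "microhomology_len",
    "classify_edit",
    "classify_read",
    "classify_reads",
]

CLASS_LABELS = ("WT", "PEPPR", "MMEJ", "DELET", "INSRT")

MAX_N_FRACTION = 0.10


class UnparseableReadError(ValueError):
    """Read cannot be interpreted against the amplicon reference."""


@dataclass(frozen=True)
class ClassifiedRead:
    read_id: str
    edit: Edit
    class_label: str
    mh_len: int = 0
    spans_cut: bool = False

    @property
    def allele_id(self) -> str:
        return allele_id_for_edit(self.edit)


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def infer_edit(read_seq: str, locus: ReferenceLocus) -> Edit:
    """Infer the edit of ``read_seq`` by maximal prefix/suffix anchoring.

    Let ``p`` be the longest common prefix with the reference and ``s`` the
    longest common suffix, with ``s`` reduced so that ``p + s`` never exceeds
    the shorter of the two sequences.  The deletion is ``ref[p:len(ref)-s]``
    and the insertion ``read[p:len(read)-s]``; pure deletions are returned in
    canonical leftmost placement.  Guarantees
    ``apply_edit(locus, result) == read_seq``.

    Raises :class:`UnparseableReadError` for empty reads, reads shorter than
    the combined primer intervals, or reads with more than 10% ``N`` calls.
    """
    read_seq = read_seq.upper()
    if not read_seq:
        raise UnparseableReadError("empty read")
    if any(b not in "ACGTN" for b in read_seq):
        raise UnparseableReadError("non-ACGTN characters in read")
    if read_seq.count("N") > MAX_N_FRACTION * len(read_seq):
        raise UnparseableReadError("more than 10% N calls")
    min_len = sum(b - a for a, b in locus.primer_intervals)
    if len(read_seq) < min_len:
        raise UnparseableReadError(
            f"read of length {len(read_seq)} shorter than combined primer "
            f"intervals ({min_len} nt)"
        )

    ref = locus.ref_seq
    p = _lcp(read_seq, ref)
    s = _lcp(read_seq[::-1], ref[::-1])
    overlap = min(len(read_seq), len(ref))
    if p + s > overlap:
        s = overlap - p
    edit = Edit(p, len(ref) - s, read_seq[p : len(read_seq) - s])
    return canonicalize_edit(locus, edit)


def equivalent_placements(ref: str, del_start: int, del_end: int) -> list[tuple[int, int]]:
    """All placements of a deletion producing the same spliced sequence.

    Obtained by sliding the interval left/right one base at a time; a shift
    is sequence-preserving iff the base entering the interval equals the base
    leaving it.  Returned left-to-right; the first element is the canonical
    (leftmost) placement.
    """
    n = len(ref)
    s, e = del_start, del_end
    while s > 0 and ref[s - 1] == ref[e - 1]:
        s, e = s - 1, e - 1
    placements = [(s, e)]
    while e < n and ref[s] == ref[e]:
        s, e = s + 1, e + 1
        placements.append((s, e))
    return placements


def microhomology_len(locus: ReferenceLocus, del_start: int, del_end: int) -> tuple[int, bool]:
    """Microhomology length and cut-spanning status of a pure deletion.

    For each equivalent placement ``[a, b)`` the flank repeat is the longest
    ``k <= b - a`` with ``ref[a:a+k] == ref[b:b+k]`` (one repeat copy retained
    at the junction, the other deleted with the intervening bases);
    ``mh_len`` is the maximum over placements.  ``spans_cut`` is true iff
    some placement's closed interval contains the cut coordinate (boundary
    contact counts: annealing can leave the retained copy exactly at the
    cut).
    """
    if not (0 <= del_start < del_end <= len(locus.ref_seq)):
        raise ValueError(f"invalid deletion interval [{del_start}, {del_end})")
    ref = locus.ref_seq
    n = len(ref)
    cut = locus.cut
    mh = 0
    spans = False
    for a, b in equivalent_placements(ref, del_start, del_end):
        k = 0
        while a + k < b and b + k < n and ref[a + k] == ref[b + k]:
            k += 1
        mh = max(mh, k)
        if a <= cut <= b:
            spans = True
    return mh, spans


def classify_edit(locus: ReferenceLocus, edit: Edit) -> tuple[str, int, bool]:
    """Assign the primary class of a canonical edit.

    Returns ``(class_label, mh_len, spans_cut)``; ``mh_len``/``spans_cut``
    are 0/False for WT and INSRT edits.  Decision order: WT, INSRT, MMEJ,
    PEPPR, DELET (see module docstring).
    """
    if edit.is_wt:
        return "WT", 0, False
    if edit.insertion:
        return "INSRT", 0, False
    mh, spans = microhomology_len(locus, edit.del_start, edit.del_end)
    if mh >= 2 and spans:
        return "MMEJ", mh, spans
    if any(b == locus.cut for _, b in
           equivalent_placements(locus.ref_seq, edit.del_start, edit.del_end)):
        return "PEPPR", mh, spans
    return "DELET", mh, spans


def classify_read(read_id: str, read_seq: str, locus: ReferenceLocus) -> ClassifiedRead:
    edit = infer_edit(read_seq, locus)
    label, mh, spans = classify_edit(locus, edit)
    return ClassifiedRead(read_id, edit, label, mh, spans)


def classify_reads(
    reads: Iterable[tuple[str, str]], locus: ReferenceLocus
) -> tuple[list[ClassifiedRead], dict[str, int]]:
    """Classify a read stream; returns (classified reads, per-class tallies).

    Tallies include a ``rejected`` bin for unparseable reads, so the class
    counts plus ``rejected`` always partition the input.
    """
    classified: list[ClassifiedRead] = []
    tallies = {label: 0 for label in CLASS_LABELS}
    tallies["rejected"] = 0
    for read_id, seq in reads:
        try:
            cr = classify_read(read_id, seq, locus)
        except UnparseableReadError:
            tallies["rejected"] += 1
            continue
        classified.append(cr)
        tallies[cr.class_label] += 1
    return classified, tallies
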