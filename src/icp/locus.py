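"""Reference locus geometry and the edit/allele data model.

Everything downstream — edit inference, classification, dictionary
construction, seed derivation — works in the coordinate frame defined here:
0-based half-open intervals on the forward strand of the amplicon reference,
with the protospacer always oriented forward (reverse-strand guides are
normalized at construction by reverse-complementing the whole locus).  The
blunt Cas9 cut is an inter-base coordinate ``cut`` derived as
``pam_start - cut_offset`` (default offset 3, the canonical SpCas9 blunt cut
between protospacer positions 17 and 18).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

__all__ = [
    "Edit",
    "ReferenceLocus",
    "AlleleRecord",
    "LocusError",
    "WT_ID",
    "revcomp",
    "make_locus",
    "apply_edit",
    "canonicalize_edit",
    "allele_id_for_edit",
    "parse_allele_id",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGT")

WT_ID = "WT"


class LocusError(ValueError):
    """Invalid locus geometry or out-of-bounds edit."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Edit:
    """One repair outcome: a deleted reference interval plus an insertion.

    ``del_start == del_end`` means no deletion; an empty ``insertion`` means
    nothing inserted; both together are the wild-type (WT) edit.  The
    insertion is placed at ``del_start``.
    """

    del_start: int
    del_end: int
    insertion: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.del_start <= self.del_end):
            raise LocusError(
                f"invalid deletion interval [{self.del_start}, {self.del_end})"
            )
        if any(b not in "ACGTN" for b in self.insertion):
            raise LocusError(f"non-ACGTN insertion {self.insertion!r}")

    @property
    def is_wt(self) -> bool:
        return self.del_start == self.del_end and not self.insertion

    @property
    def del_len(self) -> int:
        return self.del_end - self.del_start

    @property
    def is_pure_deletion(self) -> bool:
        return self.del_len > 0 and not self.insertion

    def sort_key(self) -> tuple:
        return (self.del_start, self.del_end, self.insertion)


WT_EDIT = Edit(0, 0, "")


@dataclass(frozen=True)
class ReferenceLocus:
    """Amplicon reference with protospacer/PAM geometry, forward-normalized.

    ``strand`` records the orientation of the protospacer as supplied by the
    caller; internally the sequence and all coordinates are stored on the
    strand where the protospacer reads forward with its PAM immediately 3'.
    """

    ref_seq: str
    protospacer_interval: tuple[int, int]
    pam_interval: tuple[int, int]
    strand: str = "+"
    cut_offset: int = 3
    primer_intervals: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (0, 0))
    cut: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cut", self.pam_interval[0] - self.cut_offset)

    def __len__(self) -> int:
        return len(self.ref_seq)

    @property
    def ref_hash(self) -> str:
        """Stable identifier of the reference sequence (for locus/dictionary
        consistency checks)."""
        return hashlib.sha1(self.ref_seq.encode()).hexdigest()[:12]

    def to_original_coord(self, pos: int) -> int:
        """Map an internal (forward-normalized) coordinate back to the
        caller's original frame (identity for + strand loci)."""
        if self.strand == "+":
            return pos
        return len(self.ref_seq) - pos


def make_locus(
    ref_seq: str,
    protospacer_interval: tuple[int, int],
    pam_interval: tuple[int, int],
    strand: str = "+",
    cut_offset: int = 3,
    primer_intervals: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> ReferenceLocus:
    """Build a :class:`ReferenceLocus`, validating geometry.

    For ``strand == "-"`` the protospacer is given on the reverse strand of
    ``ref_seq`` (so the PAM abuts its 5' end in forward coordinates); the
    returned locus stores the reverse complement with all intervals mirrored,
    so downstream code is strand-free.
    """
    ref_seq = ref_seq.upper()
    if not ref_seq or any(b not in _VALID_BASES for b in ref_seq):
        raise LocusError("reference must be non-empty and A/C/G/T only")
    n = len(ref_seq)
    ps, pe = protospacer_interval
    ms, me = pam_interval
    for a, b in ((ps, pe), (ms, me)):
        if not (0 <= a < b <= n):
            raise LocusError(f"interval [{a}, {b}) outside reference of length {n}")
    if me - ms != 3:
        raise LocusError("PAM interval must have length 3")
    if strand not in ("+", "-"):
        raise LocusError(f"strand must be '+' or '-', got {strand!r}")

    if strand == "-":
        # Mirror everything onto the forward strand of the reverse complement.
        flip = lambda iv: (n - iv[1], n - iv[0])  # noqa: E731
        ref_seq = revcomp(ref_seq)
        ps, pe = flip(protospacer_interval)
        ms, me = flip(pam_interval)
        if primer_intervals is not None:
            primer_intervals = tuple(sorted(flip(iv) for iv in primer_intervals))

    if ms != pe:
        raise LocusError("PAM must abut the protospacer on its 3' side")

    cut = ms - cut_offset
    if not (0 < cut < n):
        raise LocusError(f"cut coordinate {cut} outside reference interior")

    if primer_intervals is None:
        primer_intervals = ((0, 0), (0, 0))
    primer_intervals = tuple(tuple(iv) for iv in primer_intervals)
    for a, b in primer_intervals:
        if not (0 <= a <= b <= n):
            raise LocusError(f"primer interval [{a}, {b}) out of bounds")
        if a < pe and b > ps:
            raise LocusError("primer interval overlaps the protospacer")
        if a < cut < b:
            raise LocusError("cut site falls inside a primer interval")

    return ReferenceLocus(
        ref_seq=ref_seq,
        protospacer_interval=(ps, pe),
        pam_interval=(ms, me),
        strand=strand,
        cut_offset=cut_offset,
        primer_intervals=primer_intervals,  # type: ignore[arg-type]
    )


def _ref_of(locus_or_seq) -> str:
    return locus_or_seq if isinstance(locus_or_seq, str) else locus_or_seq.ref_seq


def apply_edit(locus, edit: Edit) -> str:
    """Splice ``edit`` into the reference: delete ``ref[del_start:del_end]``
    and put ``insertion`` in its place.  The WT edit returns the reference
    unchanged.  Accepts a locus or a bare sequence."""
    ref = _ref_of(locus)
    if edit.del_end > len(ref):
        raise LocusError(
            f"edit interval [{edit.del_start}, {edit.del_end}) exceeds "
            f"reference length {len(ref)}"
        )
    return ref[: edit.del_start] + edit.insertion + ref[edit.del_end :]


def canonicalize_edit(locus, edit: Edit) -> Edit:
    """Leftmost placement of a pure deletion within a repeat.

    Shifting a deletion [s, e) one base left preserves the spliced sequence
    iff ``ref[s-1] == ref[e-1]``; the canonical form is the leftmost
    reachable placement.  Edits with an insertion (and the WT edit) are
    returned unchanged.  Idempotent and sequence-preserving.
    """
    if not edit.is_pure_deletion:
        return edit
    ref = _ref_of(locus)
    if edit.del_end > len(ref):
        raise LocusError("edit out of bounds")
    s, e = edit.del_start, edit.del_end
    while s > 0 and ref[s - 1] == ref[e - 1]:
        s -= 1
        e -= 1
    if s == edit.del_start:
        return edit
    return Edit(s, e, "")


def allele_id_for_edit(edit: Edit) -> str:
    """Stable human-readable identifier for a canonical edit.

    Deletions are reported 1-based inclusive (``D:18-47`` deletes reference
    bases 18..47); insertions name the base they follow (``I:37:TT`` inserts
    TT between bases 37 and 38); deletion+insertion combines both.
    """
    if edit.is_wt:
        return WT_ID
    if edit.is_pure_deletion:
        return f"D:{edit.del_start + 1}-{edit.del_end}"
    if edit.del_len == 0:
        return f"I:{edit.del_start}:{edit.insertion}"
    return f"DI:{edit.del_start + 1}-{edit.del_end}:{edit.insertion}"


def parse_allele_id(allele_id: str) -> Edit:
    """Inverse of :func:`allele_id_for_edit`."""
    if allele_id == WT_ID:
        return WT_EDIT
    kind, _, rest = allele_id.partition(":")
    try:
        if kind == "D":
            a, b = rest.split("-")
            return Edit(int(a) - 1, int(b), "")
        if kind == "I":
            pos, ins = rest.split(":")
            return Edit(int(pos), int(pos), ins)
        if kind == "DI":
            iv, ins = rest.split(":")
            a, b = iv.split("-")
            return Edit(int(a) - 1, int(b), ins)
    except ValueError as exc:
        raise LocusError(f"malformed allele id {allele_id!r}") from exc
    raise LocusError(f"malformed allele id {allele_id!r}")


@dataclass(frozen=True)
class AlleleRecord:
    """A named allele: canonical edit, class, full-length mutant sequence and
    its 24-nt junction seed (``None`` when a flank is too short)."""

    allele_id: str
    edit: Edit
    class_label: str
    mutant_seq: str
    seed24: str | None
    seed_offset: int | None
    mh_len: int = 0
    short_seed: bool = False
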