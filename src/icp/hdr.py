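"""HDR (interhomolog gene-conversion) quantification from polymorphism reads.

The three-step amplicon design amplifies only cassette-bearing alleles, from
either the donor chromosome (where the cassette was inserted) or a receiver
chromosome that acquired it by HDR-mediated copying.  Linked colony-specific
polymorphisms distinguish the two haplotypes, so each read can be genotyped
as donor- or receiver-derived; reads mixing the two signatures are
recombinant (Holliday-junction resolution between panel sites).  Because
donor chromosomes are exactly half of all homologs, the fraction of receiver
chromosomes converted by HDR is

    hdr_fraction_pct = (% receiver reads / % donor reads) * 100.

The companion indel library samples only the *non-converted* receiver
chromosomes, so a combined per-sample report scales its WT/mutant split by
``1 - h``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .locus import Edit

__all__ = [
    "PolymorphismPanel",
    "HdrCounts",
    "HdrResult",
    "UndefinedHdrError",
    "genotype_read",
    "genotype_reads",
    "hdr_fraction",
    "combined_report",
]


class UndefinedHdrError(ValueError):
    """HDR fraction undefined (no donor reads observed)."""


@dataclass(frozen=True)
class PolymorphismPanel:
    """Donor/receiver discriminating sites on the HDR amplicon reference.

    ``sites`` are ``(position, donor_base, receiver_base)`` with strictly
    increasing 0-based positions on the *receiver-frame* reference.
    ``min_sites_called`` is the number of cleanly called sites required for
    a confident genotype (default: all of them).
    """

    sites: tuple[tuple[int, str, str], ...]
    min_sites_called: int | None = None

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("panel needs at least one site")
        positions = [p for p, _, _ in self.sites]
        if positions != sorted(set(positions)):
            raise ValueError("site positions must be strictly increasing")
        for pos, d, r in self.sites:
            if d == r:
                raise ValueError(f"site {pos}: donor and receiver base identical")
            if d not in "ACGT" or r not in "ACGT":
                raise ValueError(f"site {pos}: bases must be A/C/G/T")

    @property
    def required_sites(self) -> int:
        return len(self.sites) if self.min_sites_called is None else self.min_sites_called

    def haplotype(self, ref_seq: str, which: str) -> str:
        """Reference sequence rewritten to the donor or receiver haplotype."""
        col = 1 if which == "donor" else 2
        seq = list(ref_seq)
        for site in self.sites:
            seq[site[0]] = site[col]
        return "".join(seq)


def _read_pos(edit: Edit, ref_pos: int) -> int | None:
    """Map a reference position through an edit to a read position, or None
    if the position was deleted."""
    if ref_pos < edit.del_start:
        return ref_pos
    if ref_pos < edit.del_end:
        return None
    return ref_pos - edit.del_len + len(edit.insertion)


def genotype_read(
    read_seq: str,
    hdr_reference,
    panel: PolymorphismPanel,
    cassette_primer_seq: str | None = None,
) -> str:
    """Genotype one read: ``donor``, ``receiver``, ``recombinant``,
    ``ambiguous`` or ``rejected``.

    Panel sites are read off after prefix/suffix anchoring to the amplicon
    reference (receiver frame; polymorphic mismatches surface inside the
    inferred edit region, where bases are looked up on the read directly).
    All clean calls donor -> donor, all receiver -> receiver, a mixture ->
    recombinant; sites deleted/uncovered or showing a third base reduce the
    clean-call count, and below ``min_sites_called`` the read is ambiguous.
    If ``cassette_primer_seq`` is given, reads lacking it are rejected (the
    three-step design only amplifies cassette-bearing alleles).
    """
    read_seq = read_seq.upper()
    ref = hdr_reference if isinstance(hdr_reference, str) else hdr_reference.ref_seq
    if cassette_primer_seq is not None and cassette_primer_seq.upper() not in read_seq:
        return "rejected"
    if len(read_seq) == len(ref):
        # No indel: sites map straight through.
        get = lambda pos: read_seq[pos] if pos < len(read_seq) else None  # noqa: E731
    else:
        # Anchor through the single inferred edit.
        try:
            a = 0
            b = min(len(read_seq), len(ref))
            # prefix/suffix anchoring without locus bookkeeping
            while a < b and read_seq[a] == ref[a]:
                a += 1
            s = 0
            while (
                s < b - a
                and read_seq[len(read_seq) - 1 - s] == ref[len(ref) - 1 - s]
            ):
                s += 1
            edit = Edit(a, len(ref) - s, read_seq[a : len(read_seq) - s])
        except ValueError:
            return "rejected"

        def get(pos):
            rp = _read_pos(edit, pos)
            return read_seq[rp] if rp is not None and rp < len(read_seq) else None

    calls = []
    for pos, donor_base, receiver_base in panel.sites:
        base = get(pos)
        if base == donor_base:
            calls.append("donor")
        elif base == receiver_base:
            calls.append("receiver")
        else:
            calls.append(None)  # deleted, uncovered, N, or a third base
    clean = [c for c in calls if c is not None]
    if len(clean) < panel.required_sites:
        return "ambiguous"
    kinds = set(clean)
    if kinds == {"donor"}:
        return "donor"
    if kinds == {"receiver"}:
        return "receiver"
    return "recombinant"


@dataclass
class HdrCounts:
    donor: int = 0
    receiver: int = 0
    recombinant: int = 0
    ambiguous: int = 0
    rejected: int = 0

    @property
    def total(self) -> int:
        return self.donor + self.receiver + self.recombinant + self.ambiguous + self.rejected


def genotype_reads(
    reads: Iterable[tuple[str, str]],
    hdr_reference,
    panel: PolymorphismPanel,
    cassette_primer_seq: str | None = None,
) -> HdrCounts:
    counts = HdrCounts()
    for _, seq in reads:
        call = genotype_read(seq, hdr_reference, panel, cassette_primer_seq)
        setattr(counts, call, getattr(counts, call) + 1)
    return counts


@dataclass(frozen=True)
class HdrResult:
    donor_reads: int
    receiver_reads: int
    recombinant_reads: int
    ambiguous_reads: int
    hdr_fraction_pct: float
    recombinants_included: bool = False


def hdr_fraction(counts: HdrCounts, include_recombinants: bool = False) -> HdrResult:
    """Convert genotype counts into the HDR percentage.

    ``hdr_fraction_pct = 100 * receiver / donor`` — identical to the
    percentage form since both shares have the same denominator.
    Recombinant reads are excluded from both numerator and denominator by
    default and reported separately; ``include_recombinants`` splits them
    evenly between the two haplotypes instead.
    """
    donor = counts.donor
    receiver = counts.receiver
    if include_recombinants:
        donor += counts.recombinant / 2
        receiver += counts.recombinant / 2
    if donor <= 0:
        raise UndefinedHdrError("no donor reads: HDR fraction undefined")
    return HdrResult(
        donor_reads=counts.donor,
        receiver_reads=counts.receiver,
        recombinant_reads=counts.recombinant,
        ambiguous_reads=counts.ambiguous,
        hdr_fraction_pct=100.0 * receiver / donor,
        recombinants_included=include_recombinants,
    )


def combined_report(hdr_result: HdrResult, indel_profile) -> dict[str, float]:
    """Inferred per-receiver-chromosome composition {HDR, indel, WT}.

    ``h`` is the converted fraction of receiver chromosomes; the indel
    library samples only the remaining ``1 - h``, so its WT/mutant split is
    scaled accordingly.  The three components sum to 1 by construction.
    """
    h = hdr_result.hdr_fraction_pct / 100.0
    if h > 1.0:
        raise ValueError(
            "receiver reads exceed donor reads (h > 1): assay assumption violated"
        )
    totals = (
        indel_profile.class_totals()
        if hasattr(indel_profile, "class_totals")
        else dict(indel_profile)
    )
    wt = totals.get("WT", 0.0)
    mutant = sum(v for k, v in totals.items() if k != "WT")
    norm = wt + mutant
    if norm > 0:
        wt, mutant = wt / norm, mutant / norm
    return {"HDR": h, "indel": (1.0 - h) * mutant, "WT": (1.0 - h) * wt}
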