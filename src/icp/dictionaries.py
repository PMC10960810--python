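"""Allele dictionaries and 24-nt junction seeds.

The single-allele classifier fishes reads with short seeds taken from
full-length allele dictionaries:

* the PEPPR dictionary is synthetic — deletions grown one nucleotide at a
  time PAM-distal from the cut, excluding candidates that classify as MMEJ;
* the MMEJ and DELET dictionaries are observed — unique canonical edits of
  the class pooled across all samples of an experiment, admitted above a
  read-support threshold and after automatic primer-region curation.

Each entry's seed is the k-mer (default 24) of the mutant sequence centred
on the repair junction; sequencing/PCR errors mostly fall outside this
window, so a read whose only errors are outside the seed still matches its
root allele exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .locus import (
    AlleleRecord,
    Edit,
    ReferenceLocus,
    allele_id_for_edit,
    apply_edit,
    canonicalize_edit,
)
from .npclassifier import classify_edit

__all__ = [
    "DEFAULT_SEED_K",
    "DEFAULT_MIN_READS",
    "ShortSeedError",
    "AlleleDictionary",
    "derive_seed",
    "wt_seed",
    "make_allele_record",
    "build_peppr_dictionary",
    "build_observed_dictionary",
    "curate_primer_errors",
]

DEFAULT_SEED_K = 24
DEFAULT_MIN_READS = 2


class ShortSeedError(ValueError):
    """Junction too close to an amplicon end for a full-length seed."""


def derive_seed(mutant_seq: str, junction_pos: int, k: int = DEFAULT_SEED_K) -> str:
    """k-mer of ``mutant_seq`` centred on the repair junction.

    ``junction_pos`` is a coordinate on the *mutant* sequence (the splice
    point of a deletion; the cut for WT).  ``k`` must be even and both
    flanks must hold k/2 nucleotides.
    """
    if k % 2:
        raise ValueError("seed length k must be even")
    half = k // 2
    if junction_pos < half or junction_pos + half > len(mutant_seq):
        raise ShortSeedError(
            f"junction at {junction_pos} leaves <{half} nt of flank"
        )
    return mutant_seq[junction_pos - half : junction_pos + half]


def wt_seed(locus: ReferenceLocus, k: int = DEFAULT_SEED_K) -> str:
    """Reference seed spanning the cut — detects unedited reads."""
    return derive_seed(locus.ref_seq, locus.cut, k)


def make_allele_record(
    locus: ReferenceLocus, edit: Edit, k: int = DEFAULT_SEED_K
) -> AlleleRecord:
    """Canonicalize, classify, splice, and seed one edit."""
    edit = canonicalize_edit(locus, edit)
    label, mh, _ = classify_edit(locus, edit)
    mutant = apply_edit(locus, edit)
    junction = locus.cut if edit.is_wt else edit.del_start
    try:
        seed = derive_seed(mutant, junction, k)
        offset: int | None = junction - k // 2
        short = False
    except ShortSeedError:
        seed, offset, short = None, None, True
    return AlleleRecord(
        allele_id=allele_id_for_edit(edit),
        edit=edit,
        class_label=label,
        mutant_seq=mutant,
        seed24=seed,
        seed_offset=offset,
        mh_len=mh,
        short_seed=short,
    )


@dataclass
class AlleleDictionary:
    """Per-class allele collection with a seed index for read fishing.

    ``seed_index`` maps seed -> allele_id after within-category collision
    resolution (shorter deletion wins); losing claims are kept in
    ``collisions``.  Entries whose seed could not be derived are in the
    index only via ``full_length_index`` (exact full-sequence match).
    """

    category: str
    entries: list[AlleleRecord] = field(default_factory=list)
    seed_index: dict[str, str] = field(default_factory=dict)
    full_length_index: dict[str, str] = field(default_factory=dict)
    collisions: list[tuple[str, str, str]] = field(default_factory=list)
    mmej_excluded: list[AlleleRecord] = field(default_factory=list)
    rejected: list[tuple[AlleleRecord, str]] = field(default_factory=list)
    support: dict[str, dict[str, int]] = field(default_factory=dict)
    ref_hash: str = ""
    k: int = DEFAULT_SEED_K

    def __len__(self) -> int:
        return len(self.entries)

    def allele(self, allele_id: str) -> AlleleRecord:
        for rec in self.entries:
            if rec.allele_id == allele_id:
                return rec
        raise KeyError(allele_id)

    def _index(self) -> None:
        self.seed_index.clear()
        self.full_length_index.clear()
        self.collisions.clear()
        for rec in self.entries:  # entries are sorted by canonical edit
            if rec.seed24 is None:
                self.full_length_index[rec.mutant_seq] = rec.allele_id
                continue
            if rec.seed24 in self.seed_index:
                holder = self.allele(self.seed_index[rec.seed24])
                # Parsimony: the shorter deletion keeps the seed.
                if rec.edit.del_len < holder.edit.del_len:
                    self.collisions.append((rec.seed24, holder.allele_id, rec.allele_id))
                    self.seed_index[rec.seed24] = rec.allele_id
                else:
                    self.collisions.append((rec.seed24, rec.allele_id, holder.allele_id))
            else:
                self.seed_index[rec.seed24] = rec.allele_id


def _sorted_entries(records: Iterable[AlleleRecord]) -> list[AlleleRecord]:
    return sorted(records, key=lambda r: r.edit.sort_key())


def build_peppr_dictionary(
    locus: ReferenceLocus, max_del_len: int, k: int = DEFAULT_SEED_K
) -> AlleleDictionary:
    """Synthetic PEPPR dictionary.

    Candidate edits are the deletions ``[cut - L, cut)`` for
    ``L = 1..max_del_len``; candidates classifying as MMEJ are excluded
    (kept in ``mmej_excluded``), so
    ``len(entries) + len(mmej_excluded) == max_del_len``.
    """
    if max_del_len < 0:
        raise ValueError("max_del_len must be >= 0")
    if max_del_len > locus.cut:
        raise ValueError(
            f"max_del_len {max_del_len} exceeds cut coordinate {locus.cut}"
        )
    if max_del_len and locus.cut - max_del_len < k // 2:
        raise ValueError(
            f"max_del_len {max_del_len} leaves <{k // 2} nt of PAM-distal flank"
        )
    d = AlleleDictionary(category="PEPPR", ref_hash=locus.ref_hash, k=k)
    kept = []
    for L in range(1, max_del_len + 1):
        rec = make_allele_record(locus, Edit(locus.cut - L, locus.cut, ""), k)
        if rec.class_label == "MMEJ":
            d.mmej_excluded.append(rec)
        else:
            kept.append(rec)
    d.entries = _sorted_entries(kept)
    d._index()
    return d


def curate_primer_errors(
    entries: Iterable[AlleleRecord], locus: ReferenceLocus
) -> tuple[list[AlleleRecord], list[tuple[AlleleRecord, str]]]:
    """Drop entries whose edit touches a target-specific primer interval.

    Automated stand-in for manual curation of "obvious primer errors": a
    genuine Cas9 repair product is confined between the primers, so an edit
    overlapping a primer footprint is a synthesis/priming artifact.
    """
    kept: list[AlleleRecord] = []
    rejects: list[tuple[AlleleRecord, str]] = []
    for rec in entries:
        e = rec.edit
        reason = None
        for a, b in locus.primer_intervals:
            if a == b:
                continue
            if e.is_wt:
                continue
            if e.del_len > 0 and e.del_start < b and e.del_end > a:
                reason = f"deletion overlaps primer interval [{a}, {b})"
                break
            if e.del_len == 0 and a < e.del_start < b:
                reason = f"insertion inside primer interval [{a}, {b})"
                break
        if reason is None:
            kept.append(rec)
        else:
            rejects.append((rec, reason))
    return kept, rejects


def build_observed_dictionary(
    classified_reads,
    category: str,
    locus: ReferenceLocus,
    min_reads: int = DEFAULT_MIN_READS,
    k: int = DEFAULT_SEED_K,
) -> AlleleDictionary:
    """Observed dictionary (MMEJ or DELET) from pooled classified reads.

    ``classified_reads`` is either a flat iterable of
    :class:`~icp.npclassifier.ClassifiedRead` or a mapping
    ``sample_id -> iterable`` (per-sample support counts are then retained).
    Unique canonical edits of the requested class with total support
    ``>= min_reads`` become entries; primer-region artifacts are dropped.
    """
    if category not in ("MMEJ", "DELET"):
        raise ValueError("observed dictionaries are built for MMEJ or DELET only")
    if isinstance(classified_reads, Mapping):
        pools = classified_reads.items()
    else:
        pools = [("pooled", classified_reads)]

    support: dict[Edit, dict[str, int]] = {}
    for sample_id, pool in pools:
        for cr in pool:
            if cr.class_label != category:
                continue
            per = support.setdefault(cr.edit, {})
            per[sample_id] = per.get(sample_id, 0) + 1

    d = AlleleDictionary(category=category, ref_hash=locus.ref_hash, k=k)
    candidates = []
    for edit, per in support.items():
        if sum(per.values()) < min_reads:
            continue
        rec = make_allele_record(locus, edit, k)
        candidates.append(rec)
        d.support[rec.allele_id] = dict(sorted(per.items()))
    kept, d.rejected = curate_primer_errors(candidates, locus)
    d.entries = _sorted_entries(kept)
    d._index()
    return d
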