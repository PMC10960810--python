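"""Single Allele-resolution Classifier (SAClassifier).

Fishes raw reads with the 24-nt seed dictionaries: a read carrying a seed is
assigned to that seed's root allele even when it carries additional
errors outside the seed window — this is the automatic technical-error
calling.  Search order is WT seed first, then the MMEJ, PEPPR and DELET
indices (mirroring the MMEJ-over-PEPPR exclusion used at dictionary build
time); the first matching seed wins.  Reads matching no seed are residual
and are assigned to the INSRT class, enumerated as distinct alleles by their
inferred canonical edit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dictionaries import AlleleDictionary, DEFAULT_SEED_K, wt_seed
from .locus import WT_ID, ReferenceLocus, allele_id_for_edit
from .npclassifier import UnparseableReadError, classify_edit, infer_edit

__all__ = [
    "RESIDUAL",
    "DictionaryMismatchError",
    "DictionarySet",
    "SampleProfile",
    "fish_read",
    "classify_sample",
    "profile_to_table",
]

RESIDUAL = "__residual__"

# Fishing priority: WT must not be absorbed by mutant seeds; MMEJ before
# PEPPR mirrors the dictionary-construction exclusion.
CATEGORY_PRIORITY = ("MMEJ", "PEPPR", "DELET")


class DictionaryMismatchError(ValueError):
    """Dictionaries were built against a different reference than the locus."""


@dataclass
class DictionarySet:
    """The three seed dictionaries plus the WT seed, cross-checked.

    Seeds claimed by more than one category are kept only by the highest
    priority one (WT > MMEJ > PEPPR > DELET); displaced claims are logged in
    ``cross_collisions``.
    """

    wt_seed: str
    mmej: AlleleDictionary
    peppr: AlleleDictionary
    delet: AlleleDictionary
    ref_hash: str = ""
    k: int = DEFAULT_SEED_K
    cross_collisions: list[tuple[str, str, str]] = field(default_factory=list)

    @classmethod
    def from_locus(
        cls,
        locus: ReferenceLocus,
        peppr: AlleleDictionary,
        mmej: AlleleDictionary,
        delet: AlleleDictionary,
        k: int = DEFAULT_SEED_K,
    ) -> "DictionarySet":
        hashes = {d.ref_hash for d in (peppr, mmej, delet) if d.ref_hash}
        if hashes - {locus.ref_hash}:
            raise DictionaryMismatchError(
                f"dictionary reference hash {hashes} != locus {locus.ref_hash}"
            )
        ds = cls(
            wt_seed=wt_seed(locus, k),
            mmej=mmej,
            peppr=peppr,
            delet=delet,
            ref_hash=locus.ref_hash,
            k=k,
        )
        ds._resolve_cross_collisions()
        return ds

    def _categories(self) -> list[tuple[str, AlleleDictionary]]:
        by_name = {"MMEJ": self.mmej, "PEPPR": self.peppr, "DELET": self.delet}
        return [(name, by_name[name]) for name in CATEGORY_PRIORITY]

    def _resolve_cross_collisions(self) -> None:
        claimed: dict[str, str] = {self.wt_seed: "WT"}
        for name, d in self._categories():
            for seed in list(d.seed_index):
                if seed in claimed:
                    self.cross_collisions.append(
                        (seed, claimed[seed], f"{name}:{d.seed_index[seed]}")
                    )
                    del d.seed_index[seed]
                else:
                    claimed[seed] = f"{name}:{d.seed_index[seed]}"


def fish_read(read_seq: str, dictionaries: DictionarySet) -> tuple[str, str]:
    """Assign a read by exact seed search; returns ``(allele_id, class)``.

    The WT seed is searched first, then each category index in priority
    order; within a category the leftmost matching k-mer of the read wins
    (deterministic for the rare read matching several seeds).  No match
    returns ``(RESIDUAL, "INSRT")``.
    """
    k = dictionaries.k
    if dictionaries.wt_seed in read_seq:
        return WT_ID, "WT"
    n_kmers = len(read_seq) - k + 1
    for name, d in dictionaries._categories():
        index = d.seed_index
        if index:
            for i in range(n_kmers):
                hit = index.get(read_seq[i : i + k])
                if hit is not None:
                    return hit, name
        if d.full_length_index:
            hit = d.full_length_index.get(read_seq)
            if hit is not None:
                return hit, name
    return RESIDUAL, "INSRT"


@dataclass
class SampleProfile:
    """Per-sample allele counts and read fractions with class labels."""

    sample_id: str
    allele_counts: dict[str, int]
    allele_class: dict[str, str]
    total_reads: int
    rejected_reads: int

    @property
    def classified_reads(self) -> int:
        return self.total_reads - self.rejected_reads

    @property
    def fractions(self) -> dict[str, float]:
        denom = self.classified_reads
        if denom == 0:
            return {a: 0.0 for a in self.allele_counts}
        return {a: c / denom for a, c in self.allele_counts.items()}

    def class_totals(self) -> dict[str, float]:
        """Summed read fraction per class over all alleles."""
        totals: dict[str, float] = {}
        fr = self.fractions
        for allele, f in fr.items():
            label = self.allele_class[allele]
            totals[label] = totals.get(label, 0.0) + f
        return totals


def classify_sample(
    reads,
    dictionaries: DictionarySet,
    locus: ReferenceLocus,
    sample_id: str = "sample",
    residual_by_npc: bool = False,
) -> SampleProfile:
    """Fish every read and tally root alleles into a :class:`SampleProfile`.

    Residual reads are run through the position classifier to enumerate
    distinct alleles by canonical edit; they are labeled INSRT regardless of
    their own inferred class (the pipeline's residual rule — residual pure
    deletions are seed-region error casualties but stay INSRT for fidelity)
    unless ``residual_by_npc`` is set, in which case residuals keep their
    position-classifier class.  Unparseable reads are counted as rejected.
    """
    if dictionaries.ref_hash and dictionaries.ref_hash != locus.ref_hash:
        raise DictionaryMismatchError(
            f"dictionary hash {dictionaries.ref_hash} != locus {locus.ref_hash}"
        )
    counts: dict[str, int] = {}
    classes: dict[str, str] = {}
    total = 0
    rejected = 0
    for read_id, seq in reads:
        total += 1
        seq = seq.upper()
        allele, label = fish_read(seq, dictionaries)
        if allele == RESIDUAL:
            try:
                edit = infer_edit(seq, locus)
            except UnparseableReadError:
                rejected += 1
                continue
            allele = allele_id_for_edit(edit)
            if residual_by_npc:
                label = classify_edit(locus, edit)[0]
            else:
                label = "WT" if edit.is_wt else "INSRT"
        counts[allele] = counts.get(allele, 0) + 1
        classes.setdefault(allele, label)
    # Deterministic ordering: descending count, then allele id.
    order = sorted(counts, key=lambda a: (-counts[a], a))
    return SampleProfile(
        sample_id=sample_id,
        allele_counts={a: counts[a] for a in order},
        allele_class={a: classes[a] for a in order},
        total_reads=total,
        rejected_reads=rejected,
    )


def profile_to_table(profile: SampleProfile, top_n: int | None = None):
    """Ranked allele table (pandas DataFrame): allele_id, class, count,
    fraction, rank.  Sorted by descending fraction, ties broken by
    allele_id; ``top_n`` rows retained when given."""
    import pandas as pd

    fr = profile.fractions
    rows = sorted(
        (
            (a, profile.allele_class[a], profile.allele_counts[a], fr[a])
            for a in profile.allele_counts
        ),
        key=lambda r: (-r[3], r[0]),
    )
    if top_n is not None:
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        rows = rows[:top_n]
    df = pd.DataFrame(rows, columns=["allele_id", "class", "count", "fraction"])
    df.insert(0, "rank", range(1, len(df) + 1))
    return df
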