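"""Readers/writers for the formats the pipeline touches.

FASTQ (optionally gzipped) via Biopython, FASTA references, a YAML locus
specification, TSV dictionaries/profiles/panels with round-trippable
loaders, and JSON run logs.  All tables are TSV with a one-line header;
dictionary and profile files carry ``#``-prefixed metadata lines (reference
hash, seed length) used for locus/dictionary consistency checks.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .dictionaries import AlleleDictionary, DEFAULT_SEED_K, make_allele_record
from .locus import Edit, ReferenceLocus, make_locus
from .saclassifier import DictionarySet, SampleProfile, profile_to_table
from .hdr import PolymorphismPanel

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "load_locus_config",
    "write_dictionaries",
    "load_dictionaries",
    "write_profile",
    "load_profile",
    "load_panel",
    "file_sha1",
    "write_run_log",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Stream ``(read_id, sequence)`` pairs from a FASTQ(.gz) file.

    Malformed records raise :class:`ValueError` naming the record number.
    """
    with _open_text(path) as handle:
        record_no = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                record_no += 1
                if len(seq) != len(qual):
                    raise ValueError(
                        f"record {record_no}: sequence/quality length mismatch"
                    )
                yield title.split()[0], seq.upper()
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ near record {record_no + 1}: {exc}") from exc


def write_fastq(reads: Iterable[tuple[str, str]], path, quality_char: str = "I") -> int:
    """Write ``(read_id, sequence)`` pairs as 4-line FASTQ with a constant
    quality string (the classifiers are quality-blind)."""
    n = 0
    with _open_text(path, "wt") as out:
        for read_id, seq in reads:
            out.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def read_fasta(path) -> dict[str, str]:
    """All records of a FASTA file as ``{id: uppercase sequence}``."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def load_locus_config(path) -> ReferenceLocus:
    """Build a locus from a YAML specification.

    Keys: ``reference_fasta`` (+ optional ``record``) or inline ``ref_seq``;
    ``protospacer: [start, end]``; ``pam: [start, end]``; optional
    ``strand``, ``cut_offset``, ``primers: [[a, b], [c, d]]`` (0-based
    half-open throughout).
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "ref_seq" in cfg:
        ref_seq = cfg["ref_seq"]
    else:
        records = read_fasta(path.parent / cfg["reference_fasta"])
        name = cfg.get("record")
        ref_seq = records[name] if name else next(iter(records.values()))
    return make_locus(
        ref_seq=ref_seq,
        protospacer_interval=tuple(cfg["protospacer"]),
        pam_interval=tuple(cfg["pam"]),
        strand=cfg.get("strand", "+"),
        cut_offset=cfg.get("cut_offset", 3),
        primer_intervals=tuple(tuple(iv) for iv in cfg["primers"]) if "primers" in cfg else None,
    )


_DICT_COLUMNS = [
    "allele_id", "category", "del_start", "del_end", "insertion",
    "mh_len", "mutant_seq", "seed24",
]


def write_dictionaries(dictionaries: DictionarySet, path) -> None:
    """Write all dictionary entries to one TSV (plus metadata header)."""
    rows = []
    for name, d in (("MMEJ", dictionaries.mmej), ("PEPPR", dictionaries.peppr),
                    ("DELET", dictionaries.delet)):
        for rec in d.entries:
            rows.append(
                {
                    "allele_id": rec.allele_id,
                    "category": name,
                    "del_start": rec.edit.del_start,
                    "del_end": rec.edit.del_end,
                    "insertion": rec.edit.insertion or ".",
                    "mh_len": rec.mh_len,
                    "mutant_seq": rec.mutant_seq,
                    "seed24": rec.seed24 or ".",
                }
            )
    df = pd.DataFrame(rows, columns=_DICT_COLUMNS)
    with open(path, "w") as out:
        out.write(f"# ref_hash={dictionaries.ref_hash}\tk={dictionaries.k}\n")
        df.to_csv(out, sep="\t", index=False)


def _read_metadata(path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].strip().split("\t"):
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    return meta


def load_dictionaries(path, locus: ReferenceLocus) -> DictionarySet:
    """Round-trip loader for :func:`write_dictionaries`.

    Entries are rebuilt from their canonical edits against ``locus`` (and
    cross-checked against the stored mutant sequence), so a dictionary file
    cannot silently be applied to the wrong amplicon.
    """
    from .saclassifier import DictionaryMismatchError

    meta = _read_metadata(path)
    k = int(meta.get("k", DEFAULT_SEED_K))
    if meta.get("ref_hash") and meta["ref_hash"] != locus.ref_hash:
        raise DictionaryMismatchError(
            f"dictionary file hash {meta['ref_hash']} != locus {locus.ref_hash}"
        )
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, dtype=str)
    dicts = {
        name: AlleleDictionary(category=name, ref_hash=locus.ref_hash, k=k)
        for name in ("MMEJ", "PEPPR", "DELET")
    }
    for _, row in df.iterrows():
        ins = "" if row["insertion"] == "." else row["insertion"]
        edit = Edit(int(row["del_start"]), int(row["del_end"]), ins)
        rec = make_allele_record(locus, edit, k)
        if rec.mutant_seq != row["mutant_seq"]:
            raise DictionaryMismatchError(
                f"entry {row['allele_id']}: stored mutant sequence does not "
                f"match the locus reference"
            )
        dicts[row["category"]].entries.append(rec)
    for d in dicts.values():
        d.entries.sort(key=lambda r: r.edit.sort_key())
        d._index()
    return DictionarySet.from_locus(
        locus, peppr=dicts["PEPPR"], mmej=dicts["MMEJ"], delet=dicts["DELET"], k=k
    )


def write_profile(profile: SampleProfile, path, top_n: int | None = None) -> None:
    df = profile_to_table(profile, top_n)
    with open(path, "w") as out:
        out.write(
            f"# sample={profile.sample_id}\ttotal_reads={profile.total_reads}"
            f"\trejected_reads={profile.rejected_reads}\n"
        )
        df.to_csv(out, sep="\t", index=False)


def load_profile(path) -> SampleProfile:
    meta = _read_metadata(path)
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    counts = dict(zip(df["allele_id"], df["count"].astype(int)))
    classes = dict(zip(df["allele_id"], df["class"]))
    total = int(meta.get("total_reads", sum(counts.values())))
    rejected = int(meta.get("rejected_reads", 0))
    return SampleProfile(
        sample_id=meta.get("sample", Path(path).stem),
        allele_counts=counts,
        allele_class=classes,
        total_reads=total,
        rejected_reads=rejected,
    )


def load_panel(path) -> PolymorphismPanel:
    """Panel TSV: columns position, donor_base, receiver_base."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    sites = tuple(
        (int(r["position"]), str(r["donor_base"]), str(r["receiver_base"]))
        for _, r in df.iterrows()
    )
    return PolymorphismPanel(sites=sites)


def file_sha1(path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_log(path, **fields) -> None:
    """JSON run log (seeds, hashes, settings) for byte-identical reruns."""
    with open(path, "w") as out:
        json.dump(fields, out, indent=2, sort_keys=True, default=str)
        out.write("\n")
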