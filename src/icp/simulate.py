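"""Synthetic amplicon read generator with ground-truth tables.

Stands in for the insect amplicon libraries the pipeline was designed for:
reads are drawn multinomially from a ground-truth allele mixture over a
reference locus, then corrupted by an independent per-base substitution
error model (uniform over the three alternative bases), optionally with
extra substitutions confined to the primer footprints.  Read length follows
the amplicon (100 bp scale by default in the bundled loci); quality strings
are constant because the classifiers are quality-blind.  Indel sequencing
errors are off by default and available as a stress mode for the
residual-to-INSRT pathway.

Every sample comes with a truth table (read_id, source allele, error
positions) from which each read can be reconstructed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .locus import Edit, ReferenceLocus, allele_id_for_edit, apply_edit, canonicalize_edit
from .hdr import PolymorphismPanel

__all__ = [
    "MixtureComponent",
    "TruthMixture",
    "SimulatedSample",
    "simulate_indel_sample",
    "simulate_hdr_sample",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MixtureComponent:
    """One ground-truth allele and its mixing fraction."""

    edit: Edit
    fraction: float

    @property
    def allele_id(self) -> str:
        return allele_id_for_edit(self.edit)


@dataclass
class TruthMixture:
    """Ground-truth allele mixture and error model for one sample."""

    components: list[MixtureComponent]
    n_reads: int
    per_base_error_rate: float = 0.0
    primer_error_rate: float = 0.0
    indel_error_rate: float = 0.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(c.fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixing fractions sum to {total}, expected 1")
        for rate in (self.per_base_error_rate, self.primer_error_rate, self.indel_error_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")


@dataclass
class SimulatedSample:
    """Reads plus the truth table that generated them."""

    reads: list[tuple[str, str]]
    truth: pd.DataFrame
    seed: int


def _substitute(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    """Substitute each position with a uniformly drawn *different* base."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for pos in positions:
        current = arr[pos]
        choices = _BASES[_BASES != current]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_indel_sample(
    locus: ReferenceLocus, mixture: TruthMixture, shuffle: bool = True
) -> SimulatedSample:
    """Draw a synthetic indel-library sample from a truth mixture.

    Reads are allocated multinomially across components; each read's bases
    are independently substituted at ``per_base_error_rate``; positions
    inside the primer footprints suffer additional substitutions at
    ``primer_error_rate``; with ``indel_error_rate`` a read additionally
    gains a random 1-nt deletion or insertion.  Deterministic under a fixed
    ``random_seed``.
    """
    rng = np.random.default_rng(mixture.random_seed)
    fractions = np.array([c.fraction for c in mixture.components])
    counts = rng.multinomial(mixture.n_reads, fractions)

    canonical = [canonicalize_edit(locus, c.edit) for c in mixture.components]
    mutants = [apply_edit(locus, e) for e in canonical]
    canonical_ids = [allele_id_for_edit(e) for e in canonical]
    # Primer footprints on each mutant sequence (edits never overlap primers
    # in curated mixtures; map reference footprints through the edit).
    rows = []
    reads: list[tuple[str, str]] = []
    order = np.arange(int(counts.sum()))
    if shuffle:
        rng.shuffle(order)
    idx = 0
    for comp, n, template, allele_id in zip(
        mixture.components, counts, mutants, canonical_ids
    ):
        L = len(template)
        for _ in range(int(n)):
            read_id = f"r{order[idx]:06d}"
            idx += 1
            err = np.flatnonzero(rng.random(L) < mixture.per_base_error_rate)
            if mixture.primer_error_rate:
                shiftedness = len(template) - len(locus.ref_seq)
                for a, b in locus.primer_intervals:
                    # right-end primer shifts with the net edit length
                    if a > comp.edit.del_end:
                        a, b = a + shiftedness, b + shiftedness
                    a, b = max(a, 0), min(b, L)
                    if b > a:
                        extra = a + np.flatnonzero(
                            rng.random(b - a) < mixture.primer_error_rate
                        )
                        err = np.union1d(err, extra)
            seq = _substitute(template, err, rng) if err.size else template
            indel_note = ""
            if mixture.indel_error_rate and rng.random() < mixture.indel_error_rate:
                pos = int(rng.integers(0, len(seq)))
                if rng.random() < 0.5 and len(seq) > 1:
                    seq = seq[:pos] + seq[pos + 1 :]
                    indel_note = f"del@{pos}"
                else:
                    base = chr(int(rng.choice(_BASES)))
                    seq = seq[:pos] + base + seq[pos:]
                    indel_note = f"ins@{pos}"
            reads.append((read_id, seq))
            rows.append(
                {
                    "read_id": read_id,
                    "allele_id": allele_id,
                    "error_positions": ",".join(map(str, err.tolist())),
                    "indel_error": indel_note,
                }
            )
    if shuffle:
        # restore the shuffled emission order for both reads and truth
        perm = np.argsort([int(r[0][1:]) for r in reads])
        reads = [reads[i] for i in perm]
        rows = [rows[i] for i in perm]
    truth = pd.DataFrame(rows, columns=["read_id", "allele_id", "error_positions", "indel_error"])
    return SimulatedSample(reads=reads, truth=truth, seed=mixture.random_seed)


def simulate_hdr_sample(
    hdr_reference: str,
    panel: PolymorphismPanel,
    true_h: float,
    n_reads: int,
    error_rate: float = 0.0,
    recombinant_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedSample:
    """Synthetic three-step HDR amplicon sample.

    Reads are donor haplotype with probability ``1/(1+h)`` and receiver with
    ``h/(1+h)`` so that the expected receiver/donor count ratio equals
    ``true_h``; a ``recombinant_rate`` fraction instead switches haplotype
    between two adjacent panel sites.  Per-base substitution errors as in
    the indel simulator.
    """
    if not (0.0 <= true_h <= 1.0):
        raise ValueError("true_h must lie in [0, 1]")
    if len(panel.sites) < 2 and recombinant_rate > 0:
        raise ValueError("recombinant reads need at least two panel sites")
    for pos, _, _ in panel.sites:
        if pos >= len(hdr_reference):
            raise ValueError("panel site outside the HDR reference")
    rng = np.random.default_rng(seed)
    donor_seq = panel.haplotype(hdr_reference, "donor")
    receiver_seq = panel.haplotype(hdr_reference, "receiver")

    p_receiver = true_h / (1.0 + true_h)
    labels = []
    reads = []
    rows = []
    L = len(hdr_reference)
    for i in range(n_reads):
        u = rng.random()
        if u < recombinant_rate:
            # switch haplotype between two adjacent panel sites
            j = int(rng.integers(0, len(panel.sites) - 1))
            switch = (panel.sites[j][0] + panel.sites[j + 1][0]) // 2 + 1
            left, right = (
                (donor_seq, receiver_seq) if rng.random() < 0.5 else (receiver_seq, donor_seq)
            )
            template = left[:switch] + right[switch:]
            label = "recombinant"
        elif rng.random() < p_receiver:
            template, label = receiver_seq, "receiver"
        else:
            template, label = donor_seq, "donor"
        err = np.flatnonzero(rng.random(L) < error_rate)
        seq = _substitute(template, err, rng) if err.size else template
        read_id = f"h{i:06d}"
        reads.append((read_id, seq))
        rows.append(
            {
                "read_id": read_id,
                "haplotype": label,
                "error_positions": ",".join(map(str, err.tolist())),
            }
        )
        labels.append(label)
    truth = pd.DataFrame(rows, columns=["read_id", "haplotype", "error_positions"])
    return SimulatedSample(reads=reads, truth=truth, seed=seed)
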