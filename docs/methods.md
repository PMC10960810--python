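# Methods

## Coordinate model and edit normalization

All internal coordinates are 0-based half-open on the forward strand of the
amplicon reference; reported allele ids use 1-based inclusive deletion
intervals (`D:39-50`), the convention genomics reports use. Reverse-strand
protospacers are normalized at locus construction by reverse-complementing
the whole amplicon and mirroring every interval, so one strand-free code
path serves all loci; `ReferenceLocus.to_original_coord` maps positions
back when needed.

The blunt Cas9 cut is derived as `cut = pam_start − cut_offset` with
`cut_offset = 3` by default — the canonical SpCas9 blunt cut between
protospacer positions 17 and 18. The offset is configurable because
descriptions of the cleavage position in the literature vary in whether the
three PAM bases are included when counting from the PAM side (a cut quoted
six to seven nucleotides from the PAM side coincides with the 3-bp-upstream
blunt cut only under PAM-inclusive counting); rather than guess, the
geometry is a locus parameter.

An `Edit` is a deleted reference interval plus an insertion placed at its
start; a substitution is represented as a 1-nt deletion plus 1-nt
insertion, which is what prefix/suffix anchoring naturally produces.
Deletions inside repeats are ambiguous in placement; the canonical form is
the leftmost placement (standard variant left-alignment). Canonicalization
is idempotent and sequence-preserving, and classification never trusts it
alone: every operation that depends on placement (microhomology detection,
cut-spanning, cut-abutting) enumerates *all* equivalent placements, so
left-alignment cannot hide an MMEJ signature or a PEPPR junction.

## Edit inference from reads

`infer_edit` anchors a read by its longest common prefix *p* and suffix *s*
with the reference, reducing *s* first when *p* + *s* would exceed either
sequence. This is exact and parameter-free for amplicon reads that cover
both primer-bound ends, which is the sequencing design this pipeline
assumes; it is not an aligner, and reads with multiple widely separated
edits collapse into one composite deletion+insertion (hence INSRT — the
behaviour we want, see class rules). Reads shorter than the combined primer
footprints and reads with >10% `N` calls are rejected and reported in a
separate bin; an `N` never matches the reference, so occasional internal
`N`s surface inside the edit and land in INSRT.

## Class decision order

`WT → INSRT → MMEJ → PEPPR → DELET`, applied to the inferred canonical
edit:

* **MMEJ** requires a flank repeat of ≥2 nt at some equivalent placement
  (`ref[a:a+k] == ref[b:b+k]`, k ≤ deletion length) *and* that some
  placement's closed interval contains the cut. Boundary contact counts,
  because annealing retains one repeat copy which may sit exactly at the
  cut. 1-nt repeats are never MMEJ: they are indistinguishable from
  placement ambiguity and are not amenable to automated calling.
* **PEPPR** requires that some equivalent placement end exactly at the cut
  (resection only PAM-distal from the blunt end). Testing "any placement"
  rather than the canonical one keeps the classifier consistent with the
  synthetic dictionary construction, whose candidates are literally
  `[cut − L, cut)` before left-alignment. Deletions lying PAM-distal but
  not reaching the cut fall to DELET.
* MMEJ is tested before PEPPR so a cut-abutting deletion with a spanning
  ≥2-nt microhomology is MMEJ; the synthetic PEPPR dictionary applies the
  same exclusion, keeping the two modules consistent by construction.

A brute-force oracle (exhaustive placement enumeration by result-string
equality, exhaustive flank-repeat scan) lives in the test suite and in
`scripts/acceptance.py`; the implementation must agree with it on 1,000
random reference × deletion instances.

## Dictionaries and seeds

The synthetic PEPPR dictionary enumerates deletion lengths 1..`max_del_len`
(default 30, bounded by the cut position and by the requirement that a
12-nt flank remain for the seed). Observed MMEJ and DELET dictionaries pool
position-classifier outputs across all samples of an experiment; an allele
needs `min_reads ≥ 2` supporting reads (an explicit, reproducible stand-in
for manual curation of one-off artifacts — the read-support threshold is a
knob the protocol itself does not fix) and must not touch a primer
footprint (automatic version of primer-error curation: a real repair
product cannot alter the primer-binding region, so edits overlapping a
primer interval are synthesis artifacts).

Seeds are the k-mer (k = 24, configurable, split 12+12) of the mutant
sequence centred on the repair junction — the splice point of a deletion,
the cut for WT. The window size reflects the empirical observation that
technical errors concentrate >12 nt away from the cut. Alleles whose
junction sits within 12 nt of an amplicon end get no seed and are matched
by full-length sequence only. Seed collisions are resolved by category
priority WT > MMEJ > PEPPR > DELET across dictionaries (mirroring the
MMEJ-over-PEPPR exclusion) and by shorter-deletion parsimony within a
dictionary; every displaced claim is logged.

## Read fishing

A read is searched for the WT seed first, then each category's seed index
in priority order; matching is exact substring search anywhere in the read
(floating, so small upstream indels do not break the match), and within a
category the leftmost matching k-mer wins, making multi-seed reads
deterministic. No match → residual → INSRT, grouped into alleles by
inferred canonical edit so insertion diversity remains reportable.
`residual_by_npc=True` instead lets residuals keep their position-classifier
class, for users who want residual pure deletions reported separately.

Two consequences worth knowing:

* a residual read whose true source is a dictionary allele with an
  *in-seed* error is knowingly misattributed to INSRT — that is the
  pipeline's stated residual rule, and the price of exact matching (see
  Limitations);
* a deletion lying entirely outside the ±12-nt cut window leaves the WT
  seed intact, so such (biologically implausible, artifact-grade) alleles
  would fish as WT.

## Fingerprint statistics

Landscapes rank alleles by read fraction (ties broken lexicographically by
allele id, making outputs byte-stable). Class Fraction reports *raw* summed
fractions over the top-N alleles by default with an optional
renormalization flag, and WT inclusion is an explicit parameter, because
rendered figures differ on both conventions. The shared-allele feature
matrix holds raw read fractions (no rescaling) — embedding and clustering
are deliberately external; this package only builds the matrix and
consumes cluster labels back for deletion-size summaries. Replicate
correlation is the ordinary Pearson product-moment coefficient with its
two-sided t-transform p-value (`scipy.stats.pearsonr`), flagged rather than
raised on zero-variance input.

## HDR quantification

Panel sites are given in the receiver frame; reads are genotyped by direct
site lookup when indel-free and through single-edit anchoring otherwise. A
site showing a third base (sequencing error) or falling in a deleted
region is uncallable; with fewer than `min_sites_called` clean sites
(default: all of them) the read is ambiguous. Mixed donor/receiver
signatures are recombinant — consistent with Holliday-junction resolution
between sites — and are excluded from both numerator and denominator of
`(% receiver / % donor) × 100` by default, since the ratio formula names
only pure haplotypes; `include_recombinants=True` splits them evenly
instead. Both policies are exposed because the assay itself does not fix
one. The combined report formalizes the HDR/indel/WT bars as
`{h, (1−h)·mutant, (1−h)·WT}`: the indel library amplifies only
non-converted receiver chromosomes, so its composition is scaled by `1−h`.
`h > 1` (receiver reads exceeding donor reads) violates the assay's design
and raises.

## Synthetic data

The simulator emulates demultiplexed single-end amplicon libraries: reads
drawn multinomially from a planted allele mixture, independent per-base
substitutions uniform over the three alternative bases (default rate 0.001
in the recovery studies, the scale of Illumina + high-fidelity PCR error),
optional extra substitutions confined to primer footprints, and an optional
1-nt indel error mode to stress the residual pathway. Read length follows
the amplicon (100 nt in the bundled study conditions); quality strings are
constant because both classifiers are quality-blind. Every sample ships a
truth table from which each read is exactly reconstructible (verified in
tests). The HDR simulator draws donor/receiver haplotypes at odds 1 : h
(so the expected count ratio is h) with optional recombinants switching
haplotype midway between two adjacent panel sites.

What the simulator does *not* model: PCR amplification bias and chimeras,
platform-specific error spectra, quality-correlated errors, large
structural variants, and paired-end artifacts. Passing recovery tests
therefore demonstrate correctness of the classification machinery under
the stated error model, not robustness to every real-library pathology.

## Problem sizes and determinism

The bundled studies use 100-nt amplicons with the cut mid-amplicon, 10,000
reads per simulated sample, 20 replicates per HDR condition, 1,000
instances for oracle equivalence, and 20 loci for the dictionary identity
— sizes at which every recovery property is measured with comfortable
binomial resolution. All randomness flows through explicit integer seeds
(NumPy `default_rng`); identical inputs produce byte-identical tables, and
`scripts/acceptance.py` derives independent sub-seeds for each study from
its single `--seed`.

## Known limitations

* **In-seed errors inflate INSRT.** Exact 24-nt matching means a read with
  any substitution inside its root's seed window becomes residual INSRT.
  At per-base error rate e the expected loss per dictionary-allele read is
  `1 − (1−e)^24` (≈2.4% at e = 0.001), shifting roughly
  `0.8 × 2.4 ≈ 1.9` percentage points of a mixture like
  {WT 15, PEPPR 40, MMEJ 25, INSRT 20} into INSRT. This is inherent to the
  exact-seed design (the same property that guarantees in-seed mutations
  are never silently absorbed); class fractions at realistic error rates
  carry this small, predictable bias, and the corresponding recovery test
  documents it.
* Substitutions are classified INSRT regardless of distance from the cut;
  the pipeline makes no attempt to separate distant sequencing errors from
  bona fide near-cut substitution repair products at the NPClassifier
  stage (seed fishing handles the distant ones).
* 1-nt microhomologies are not called MMEJ; MMEJ dictionaries are
  observed, not predicted from sequence.
* No paired-end merging, quality trimming, UMI handling, or recovery of
  lesions larger than the amplicon (large deletions, translocations).
* Cas9 cut-site variability (non-blunt RuvC nicks, ±1 nt cleavage slip) is
  not modelled; the locus assumes a single blunt cut.
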