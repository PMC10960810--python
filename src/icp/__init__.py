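"""icp — integrated classification of CRISPR/Cas9 DSB repair outcomes.

Decomposes targeted amplicon deep-sequencing reads into single-allele
resolution repair profiles: a nucleotide-position classifier infers the
edit in each read and assigns WT/PEPPR/MMEJ/DELET/INSRT, 24-nt junction
seed dictionaries absorb technical errors by fishing reads back to their
root alleles, fingerprint statistics summarize allelic landscapes and
class compositions, and a polymorphism-based module quantifies
HDR-mediated gene-cassette copying.  A truth-known read simulator backs
all of it.
"""

__version__ = "0.1.0"

from .locus import (
    AlleleRecord,
    Edit,
    ReferenceLocus,
    allele_id_for_edit,
    apply_edit,
    canonicalize_edit,
    make_locus,
    parse_allele_id,
    revcomp,
)
from .npclassifier import (
    CLASS_LABELS,
    ClassifiedRead,
    UnparseableReadError,
    classify_edit,
    classify_reads,
    infer_edit,
    microhomology_len,
)
from .dictionaries import (
    AlleleDictionary,
    build_observed_dictionary,
    build_peppr_dictionary,
    curate_primer_errors,
    derive_seed,
    make_allele_record,
    wt_seed,
)
from .saclassifier import (
    DictionarySet,
    SampleProfile,
    classify_sample,
    fish_read,
    profile_to_table,
)
from .fingerprints import (
    class_fraction,
    common_alleles,
    deletion_size_summary,
    landscape,
    replicate_correlation,
)
from .hdr import (
    HdrCounts,
    HdrResult,
    PolymorphismPanel,
    combined_report,
    genotype_read,
    genotype_reads,
    hdr_fraction,
)
from .simulate import (
    MixtureComponent,
    TruthMixture,
    simulate_hdr_sample,
    simulate_indel_sample,
)
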