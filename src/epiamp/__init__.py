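"""epiamp: read-level epiallele analysis of bisulfite amplicon sequencing.

Targeted deep bisulfite sequencing reads each amplified molecule's full
CpG methylation pattern (its *epiallele*). This package merges and aligns
paired-end bisulfite reads, calls per-molecule profiles with conversion-
efficiency QC, builds rarefied epiallele count tables, summarizes them as
class distributions and per-CpG levels, estimates 5hmC from paired
BS/oxBS libraries, and tests group differences and methylation-behavior
correlations — plus a seeded cohort simulator providing exact ground
truth for every stage.
"""

from .amplicon import (AmpliconSpec, ConvertedRefs, bisulfite_convert_reference,
                       find_cpg_sites, from_tss_coord, load_amplicon, revcomp,
                       to_tss_coord)
from .epialleles import (ClassDistribution, EpialleleTable, class_distribution,
                         estimate_5hmc, mean_methylation, per_cpg_methylation,
                         rarefy, tabulate)
from .reads import (Alignment, FastqRead, FilterThresholds, MergedRead,
                    MethProfile, QCReport, align_to_amplicon, call_profile,
                    control_conversion, filter_profiles, merge_pairs,
                    process_pairs, read_fastq)
from .simulate import (BehaviorCoupling, CohortConfig, CohortSim,
                       IndependentModel, MixtureModel, NoiseModel,
                       emit_control_reads, emit_reads, expected_class_freqs,
                       expected_per_cpg_p, make_amplicon, patterns_to_strings,
                       poisson_binomial, sample_epialleles, simulate_cohort,
                       write_cohort)
from .stats import (TestResult, behavior_correlogram, correlogram_matrix,
                    holm_sidak, per_class_comparison, per_cpg_comparison,
                    two_group_ttest)
from .pipeline import (CohortAnalysis, analyze_cohort_sim, cohort_frame,
                       run_cohort, run_sample)

__version__ = "0.1.0"
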