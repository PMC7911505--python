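"""Simulate the study-condition cohort and write it to disk.

Generates the two-tissue (brain/gut), two-group (CTRL/PROBIO), five-fish
cohort: Tph1A-like amplicon (BS + oxBS libraries), BDNF-like amplicon
(BS), an unmethylated spike-in control, behavior scores, and the exact
ground truth. FASTQ output goes under scratch/ (large, regenerable);
the sample sheet and truth are what downstream steps consume.
"""

from pathlib import Path

from epiamp import CohortConfig, simulate_cohort
from epiamp.simulate import write_cohort

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"
SEED = 20260927
READS_PER_SAMPLE = 1500   # desk-scale stand-in for ~100k reads/sample


def main():
    cfg = CohortConfig(reads_per_sample=READS_PER_SAMPLE)
    sim = simulate_cohort(cfg, seed=SEED)
    write_cohort(sim, OUT)
    n_reads = sum(len(s.pairs) for s in sim.samples)
    print(f"wrote {len(sim.samples)} samples ({n_reads} read pairs) "
          f"+ control to {OUT}")
    for name, spec in sim.amplicons.items():
        print(f"  {name}: {spec.length_bp} bp, {spec.n_cpg} CpGs, "
              f"TSS labels {spec.cpg_coords[0]:+d}..{spec.cpg_coords[-1]:+d}")


if __name__ == "__main__":
    main()
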