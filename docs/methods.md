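# Methods

## Amplicon model

An amplicon is a primer-defined promoter region sequenced on the top
bisulfite strand only (the primer design fixes the strand; the bottom
strand carries no extra information for a fixed pair). CpG cytosines are
located by exact `CG` scan and labelled TSS-relative: the TSS base is +1,
upstream positions are negative, and 0 does not exist. Primers written
against the converted strand are matched in three-letter space (C
collapsed to T on both sides) and trimmed before any CpG calling, because
primer bases are synthesis-determined and would bias calls. References
may contain N, but a C or G adjacent to an N makes CpG status ambiguous
and the reference is rejected at load time.

## Read processing

1. **Merging.** Mate 2 is reverse-complemented and slid ungapped along
   mate 1; candidate offsets come from exact 16-mer anchors with an
   exhaustive scan as fallback. The best match-minus-mismatch layout
   wins; overlaps shorter than `min_overlap` (default 20 bp) or with
   more than 25 % mismatches are rejected. Disagreements resolve toward
   the higher base quality. An ungapped model is appropriate because
   251×2 chemistry over ≤ 417 bp amplicons guarantees a long overlap and
   the platform's indel rate is negligible at amplicon scale; indel-aware
   merging is out of scope.
2. **Alignment.** The merged molecule is aligned semi-globally (free end
   gaps on the reference) in three-letter space: read C→T; reference
   non-CpG C→T; reference CpG C matched two-state (C or T), since its
   read base encodes methylation rather than sequence. Both orientations
   are tried; identity is matching columns over aligned read length. The
   edit-distance primitive is edlib; the bisulfite-space encoding,
   two-state CpG matching and per-position calling are this package's.
3. **Calling.** At each CpG: read C → M, T → U, anything else or
   uncovered → X. The per-read conversion rate is the T fraction at
   covered non-CpG reference cytosines; reads covering none are
   uninformative and dropped.
4. **Filtering.** In order: conversion rate ≥ 0.98, identity ≥ 0.90,
   merged length ≥ 80 % of the amplicon, zero X calls. The thresholds are
   conventional amplicon-bisulfite values, configurable in
   `FilterThresholds`; attrition is logged per filter. Excluding any
   profile with an ambiguous CpG from *both* the epiallele table and the
   per-CpG averages makes the class-weighted mean identity exact, at the
   cost of a small loss of marginal reads.
5. **Spike-in control.** A fully unmethylated control amplicon
   (M13mp18-style role) yields a global conversion efficiency: the T
   fraction at *all* of its C positions, CpG or not.

## Epiallele tables and summaries

Complete profiles become binary patterns counted per sample. Samples are
made comparable by rarefaction — a multivariate-hypergeometric draw
without replacement to a common depth (default: the minimum sample
depth), deterministic given a seed. Class distributions, average and
per-CpG methylation follow the definitions in the README; the identity
`mean = 100·Σ k·f_k/N` is exact by construction and is enforced by tests
to 1e−9. 5hmC is the per-CpG BS − oxBS difference of fish-matched
libraries, clipped at zero with the raw difference reported, because
sampling noise makes small negative differences routine.

## Statistics

Group tests are two-sided pooled-variance t-tests (both groups assumed
to share an SD — the convention for these small-cohort designs; n = 5
per group). Per-CpG families are Holm–Šidák adjusted over the amplicon's
CpGs: sort ascending, `adj_(i) = 1 − (1 − p_(i))^(m−i+1)`, enforce
monotonicity, unsort. Per-class comparisons are conventionally read on
raw p (class distributions are exploratory); both raw and adjusted values
are always reported side by side, and classes absent in every sample are
flagged and excluded from the family size m. Correlations pool CTRL and
PROBIO within a tissue — the treatment provides the biological range the
correlation exploits — using Pearson r with two-sided p from the
t-distribution on n − 2 df; zero-variance features report missing r.
Degenerate t-tests (zero variance, equal means) return p = 1.

## Simulator

Per fish and tissue, molecules are drawn from one of two models:

- **Epitype mixture** (Tph1A-like): epitypes are binary patterns
  representing cell subpopulations; a molecule inherits one epitype by
  weight and then flips each site with rate ε = 0.03. Group-level class
  weights are binomial shapes (CTRL), a binomial plus a high-class
  component (brain PROBIO: class reshuffling at nearly fixed mean), or a
  binomial plus a concentrated responsive-class component (gut PROBIO).
  Each class with appreciable weight is materialized as 3 random
  patterns of that Hamming weight, which also produces naturally uneven
  per-CpG profiles.
- **Site-independent Bernoulli** (BDNF-like): per-CpG probabilities with
  the two most upstream sites 4× the rest, scaled to the tiny target
  mean.

**Calibration.** Default group means and spreads are the emulated study
conditions: Tph1A-like 51.24 ± 0.8 (brain CTRL), 53.2 ± 2.1 (brain
PROBIO), 70.38 ± 4 (gut CTRL), 62.1 ± 1.4 (gut PROBIO) %, and BDNF-like
0.72 ± 0.06 (gut) / 0.41 ± 0.034 (brain) % — mean ± SE over five fish.
Because those printed values are *observed* quantities, the generator
inverts the observation chain once, analytically: the conversion-noise
floor (`m_true = (m_obs − inc)/(1 − over − inc)`) and the flip-noise pull
toward N/2 (`μ* = (μ − εN)/(1 − 2ε)`). Between-fish variability is a
Dirichlet jitter of epitype weights whose concentration is solved from
the target SE via `Var(fish mean) = Var_w(μ_e)/(c+1)` (gamma-jittered p
for the independent model). Nothing about this calibration is fitted to
data; it is closed-form algebra over the configured targets.

**Noise defaults** (per site / base): incomplete conversion 0.002 —
typical commercial-kit efficiency (~99.8 %); over-conversion 0.005;
sequencing error 0.002 with uniform miscalls; 5hmC fraction 0.02 of
methylated sites (reads methylated in BS, unmethylated in oxBS).
Qualities come from a fixed high-quality profile (92 % Q40 / 6 % Q20 /
2 % Q2) used only for overlap arbitration.

**Behavior scores.** DV, OA, CP are `α + β·f₆ + N(0, σ)` of the fish's
true class-6 frequency, with β = +40, +30, −35 and σ = 1.0, 0.8, 0.9
(arbitrary tracking units): DV and OA couple positively, CP negatively,
matching the treatment directions of the emulated design. Each
(fish, tissue) is an independent unit with its own scores — a deliberate
simplification; real fish would share scores across their tissues.

**Problem sizes.** Default depth is 5,000 reads/sample — a desk-scale
choice standing in for ~100,000 reads/sample, keeping full-cohort runs
in minutes while leaving multinomial SEs far below the effect sizes. The
acceptance script runs at 2,500 reads/sample and the analysis scripts at
1,500; all depths are configurable up to study scale.

## What the simulator does and does not emulate

It reproduces read geometry, conversion chemistry (BS and oxBS),
epiallele heterogeneity, between-fish variability and score coupling. It
does **not** model PCR bias or chimeras, quality-score degradation along
the read, indels, microbiome composition or actual behavior dynamics.
Passing tests therefore demonstrate correctness of the computational
pipeline under realistic noise, not robustness to every artifact of real
libraries.

## Numerical and design choices

- Rarefaction uses numpy's multivariate hypergeometric generator; one
  child stream per sample in column order, bit-reproducible per seed.
- Holm–Šidák and the pooled t are implemented from their formulas and
  cross-checked in tests against statsmodels/scipy — keeping the
  implementation and the oracle on separate routes.
- BIOM export writes the documented BIOM 1.0 JSON schema directly; TSV
  is the primary interchange format.
- Epiallele patterns absent everywhere are dropped from tables; empty
  samples carry depth 0 and any downstream summary on them raises.
- The library surface plus the numbered `analysis/` scripts *are* the
  orchestration interface; no console CLI is shipped, as the intended
  users drive the package from Python or the scripts.
- Ties in merge arbitration keep the mate-1 base; alignment ties keep
  the forward orientation.

## Known limitations

Single-amplicon phasing only (no cross-amplicon haplotypes); no
epipolymorphism/entropy metrics; no indel-aware alignment; the 5hmC
estimator is the simple subtraction method, which is noisy at low true
levels and reports clipped values whose average is biased slightly
upward; per-class t-tests on rare classes are conservative because class
frequencies are discrete at finite depth.
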