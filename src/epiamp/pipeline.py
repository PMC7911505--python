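"""Sample- and cohort-level orchestration.

`run_sample` turns one FASTQ pair into filtered per-molecule profiles with
a QC report; `run_cohort` drives the whole study layout from a sample
sheet: tabulation, rarefaction, class distributions, tissue-wise group
statistics, 5hmC estimation where BS/oxBS pairs exist, and the behavior
correlogram. `analyze_cohort_sim` runs the identical analysis directly on
an in-memory simulated cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .amplicon import AmpliconSpec, bisulfite_convert_reference
from .epialleles import (EpialleleTable, class_distribution, estimate_5hmc,
                         mean_methylation, per_cpg_methylation, rarefy,
                         tabulate)
from .reads import (FilterThresholds, QCReport, control_conversion,
                    process_pairs, read_fastq)
from .stats import (behavior_correlogram, per_class_comparison,
                    per_cpg_comparison, two_group_ttest)

SCORE_COLUMNS = ["DV", "OA", "CP"]


def run_sample(pairs_or_fastqs, spec: AmpliconSpec,
               thresholds: FilterThresholds | None = None,
               sample_id: str = "") -> tuple[pd.DataFrame, QCReport]:
    """Process one sample's read pairs against one amplicon.

    Accepts either an in-memory list of read pairs or a (fastq1, fastq2)
    path tuple. Returns a per-read profile frame (pattern, conversion_rate,
    identity) and the QC report.
    """
    if (isinstance(pairs_or_fastqs, tuple) and len(pairs_or_fastqs) == 2
            and isinstance(pairs_or_fastqs[0], (str, Path))):
        r1 = read_fastq(pairs_or_fastqs[0])
        r2 = read_fastq(pairs_or_fastqs[1])
        if len(r1) != len(r2):
            raise ValueError("FASTQ mates differ in read count")
        pairs = list(zip(r1, r2))
    else:
        pairs = list(pairs_or_fastqs)
    refs = bisulfite_convert_reference(spec)
    profiles, qc = process_pairs(pairs, spec, refs, thresholds, sample_id)
    frame = pd.DataFrame({
        "pattern": [p.pattern for p in profiles],
        "conversion_rate": [p.conversion_rate for p in profiles],
        "identity": [p.identity for p in profiles],
    })
    return frame, qc


def cohort_frame(table: EpialleleTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Samples x features frame for statistics.

    One row per sample: tissue/group/chemistry, behavior scores, mean
    methylation, per-CpG percentages (columns ``cpg_<TSS label>``) and
    class frequencies (columns ``class_<k>``).
    """
    rows = []
    for sample in table.samples:
        meta = metadata.loc[sample]
        row = {"sample_id": sample, "tissue": meta["tissue"],
               "group": meta["group"], "chemistry": meta["chemistry"]}
        for c in SCORE_COLUMNS:
            row[c] = meta.get(c, float("nan"))
        row["mean_meth"] = mean_methylation(table, sample)
        for coord, pct in per_cpg_methylation(table, sample).items():
            row[f"cpg_{coord:+d}" if isinstance(coord, int) else f"cpg_{coord}"] \
                = pct
        for k, f in enumerate(class_distribution(table, sample).freqs):
            row[f"class_{k}"] = f
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


@dataclass
class CohortAnalysis:
    tables: dict = field(default_factory=dict)       # (amplicon, chem) -> raw
    rarefied: dict = field(default_factory=dict)     # (amplicon, chem) -> table
    frames: dict = field(default_factory=dict)       # amplicon -> BS frame
    mean_tests: dict = field(default_factory=dict)   # (amplicon, tissue)
    per_cpg: dict = field(default_factory=dict)
    per_class: dict = field(default_factory=dict)
    correlograms: dict = field(default_factory=dict)
    hmc: dict = field(default_factory=dict)          # amplicon -> tidy frame
    qc: dict = field(default_factory=dict)           # sample_id -> QCReport
    control_efficiency: float | None = None


def _analyze(patterns_by_key: dict, metadata: pd.DataFrame,
             specs: dict, depth: int | None, rarefy_seed: int,
             analysis: CohortAnalysis) -> CohortAnalysis:
    for (amplicon, chem), by_sample in patterns_by_key.items():
        empty = [s for s, pats in by_sample.items() if not pats]
        if empty:
            raise ValueError(
                f"no reads passed QC for sample(s) {empty} ({amplicon}/{chem})")
        spec = specs[amplicon]
        table = tabulate(by_sample, amplicon, spec.cpg_coords)
        analysis.tables[(amplicon, chem)] = table
        analysis.rarefied[(amplicon, chem)] = rarefy(table, depth, rarefy_seed)

    for amplicon in {a for a, _ in patterns_by_key}:
        bs = analysis.rarefied.get((amplicon, "BS"))
        if bs is None:
            continue
        frame = cohort_frame(bs, metadata)
        analysis.frames[amplicon] = frame
        for tissue in sorted(frame["tissue"].unique()):
            sub = frame[frame["tissue"] == tissue]
            if sub["group"].nunique() == 2 and sub["group"].value_counts().min() >= 2:
                x = sub[sub["group"] == "CTRL"]["mean_meth"]
                y = sub[sub["group"] == "PROBIO"]["mean_meth"]
                analysis.mean_tests[(amplicon, tissue)] = two_group_ttest(
                    x, y, feature="mean_meth")
                analysis.per_cpg[(amplicon, tissue)] = per_cpg_comparison(
                    frame, tissue)
                analysis.per_class[(amplicon, tissue)] = per_class_comparison(
                    frame, tissue)
            if sub[SCORE_COLUMNS].notna().all(axis=None) and len(sub) >= 3:
                analysis.correlograms[(amplicon, tissue)] = \
                    behavior_correlogram(frame, tissue)

        ox = analysis.rarefied.get((amplicon, "oxBS"))
        if ox is not None:
            pairs = _match_bs_oxbs(metadata, bs, ox)
            if pairs:
                analysis.hmc[amplicon] = estimate_5hmc(bs, ox, pairs)
    return analysis


def _match_bs_oxbs(metadata: pd.DataFrame, bs: EpialleleTable,
                   ox: EpialleleTable) -> list[tuple[str, str]]:
    """Pair BS and oxBS samples of the same fish."""
    if "fish" not in metadata.columns:
        return []
    fish_of = metadata["fish"]
    ox_by_fish = {fish_of[s]: s for s in ox.samples if s in fish_of.index}
    return [(s, ox_by_fish[fish_of[s]]) for s in bs.samples
            if fish_of.get(s) in ox_by_fish]


def analyze_cohort_sim(sim, thresholds: FilterThresholds | None = None,
                       depth: int | None = None, rarefy_seed: int = 0
                       ) -> tuple[CohortAnalysis, pd.DataFrame]:
    """Run the full pipeline on an in-memory simulated cohort."""
    analysis = CohortAnalysis()
    metadata = pd.DataFrame([
        {"sample_id": s.sample_id, "fish": s.fish, "tissue": s.tissue,
         "group": s.group, "chemistry": s.chemistry, "amplicon": s.amplicon,
         **s.scores}
        for s in sim.samples
    ]).set_index("sample_id", drop=False)
    patterns_by_key: dict = {}
    for s in sim.samples:
        frame, qc = run_sample(s.pairs, sim.amplicons[s.amplicon],
                               thresholds, s.sample_id)
        analysis.qc[s.sample_id] = qc
        patterns_by_key.setdefault((s.amplicon, s.chemistry), {})[
            s.sample_id] = list(frame["pattern"])
    if sim.control_pairs:
        analysis.control_efficiency = control_conversion(
            sim.control_pairs, sim.amplicons["unmeth_control"])
    _analyze(patterns_by_key, metadata, sim.amplicons, depth, rarefy_seed,
             analysis)
    return analysis, metadata


def run_cohort(sample_sheet, fastq_dir, specs: dict,
               thresholds: FilterThresholds | None = None,
               depth: int | None = None, rarefy_seed: int = 0,
               outdir=None) -> tuple[CohortAnalysis, pd.DataFrame]:
    """File-based cohort run from a sample sheet TSV.

    The sheet needs columns sample_id, fastq1, fastq2, tissue, group,
    chemistry, amplicon and optionally fish + DV/OA/CP. FASTQ paths are
    resolved against ``fastq_dir``. With ``outdir`` set, all tables, stats
    and QC reports are written under it (tables/, stats/, qc/).
    """
    fastq_dir = Path(fastq_dir)
    metadata = pd.read_csv(sample_sheet, sep="\t").set_index(
        "sample_id", drop=False)
    required = {"sample_id", "fastq1", "fastq2", "tissue", "group",
                "chemistry", "amplicon"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    analysis = CohortAnalysis()
    patterns_by_key: dict = {}
    for sid, row in metadata.iterrows():
        if row["amplicon"] not in specs:
            raise ValueError(f"unknown amplicon {row['amplicon']!r} for {sid}")
        frame, qc = run_sample(
            (fastq_dir / row["fastq1"], fastq_dir / row["fastq2"]),
            specs[row["amplicon"]], thresholds, sid)
        analysis.qc[sid] = qc
        patterns_by_key.setdefault((row["amplicon"], row["chemistry"]), {})[
            sid] = list(frame["pattern"])
    control1 = fastq_dir / "control_R1.fastq.gz"
    control2 = fastq_dir / "control_R2.fastq.gz"
    if control1.exists() and "unmeth_control" in specs:
        analysis.control_efficiency = control_conversion(
            list(zip(read_fastq(control1), read_fastq(control2))),
            specs["unmeth_control"])
    _analyze(patterns_by_key, metadata, specs, depth, rarefy_seed, analysis)
    if outdir is not None:
        write_outputs(analysis, Path(outdir))
    return analysis, metadata


def write_outputs(analysis: CohortAnalysis, outdir: Path) -> None:
    """Fixed output layout: qc/, tables/, stats/."""
    for sub in ("qc", "tables", "stats"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    for sid, qc in analysis.qc.items():
        qc.control_conversion = analysis.control_efficiency
        (outdir / "qc" / f"{sid}.json").write_text(qc.to_json())
    for (amplicon, chem), table in analysis.tables.items():
        table.to_tsv(outdir / "tables" / f"{amplicon}_{chem}_counts.tsv")
        table.to_biom_json(outdir / "tables" / f"{amplicon}_{chem}_counts.biom.json")
    for (amplicon, chem), table in analysis.rarefied.items():
        table.to_tsv(outdir / "tables" / f"{amplicon}_{chem}_rarefied.tsv")
    for amplicon, frame in analysis.frames.items():
        frame.to_csv(outdir / "tables" / f"{amplicon}_cohort_frame.tsv",
                     sep="\t", index=False)
    for (amplicon, tissue), res in analysis.mean_tests.items():
        pd.DataFrame([res.__dict__]).to_csv(
            outdir / "stats" / f"{amplicon}_{tissue}_mean.tsv", sep="\t",
            index=False)
    for name, coll in (("per_cpg", analysis.per_cpg),
                       ("per_class", analysis.per_class),
                       ("correlogram", analysis.correlograms)):
        for (amplicon, tissue), df in coll.items():
            df.to_csv(outdir / "stats" / f"{amplicon}_{tissue}_{name}.tsv",
                      sep="\t", index=False)
    for amplicon, df in analysis.hmc.items():
        df.to_csv(outdir / "tables" / f"{amplicon}_hmc.tsv", sep="\t",
                  index=False)
    summary = {
        "control_efficiency": analysis.control_efficiency,
        "samples": {sid: qc.n_pass for sid, qc in analysis.qc.items()},
    }
    (outdir / "qc" / "summary.json").write_text(json.dumps(summary, indent=2))
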