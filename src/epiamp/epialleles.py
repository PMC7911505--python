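"""Epiallele tables, class distributions and oxBS-based 5hmC estimation.

An *epiallele* is the specific arrangement of methylated CpGs along one
sequenced molecule, written as a binary pattern over the amplicon's CpG
sites ("10110..."). Collapsing epialleles by their number of methylated
CpGs, irrespective of position, gives *epiallele classes* 0..N — the
read-level heterogeneity summary this package is built around. Counts are
made comparable across samples by rarefaction (subsampling without
replacement to a common depth).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EpialleleTable:
    """Per-sample counts of binary methylation patterns.

    ``counts`` is a patterns x samples integer DataFrame (index: pattern
    strings of equal length N = CpG count). ``cpg_coords`` carries the
    TSS-relative CpG labels for per-site summaries.
    """

    counts: pd.DataFrame
    amplicon: str = ""
    cpg_coords: tuple[int, ...] = ()

    def __post_init__(self):
        lengths = {len(p) for p in self.counts.index}
        if len(lengths) > 1:
            raise ValueError(f"mixed pattern lengths in table: {sorted(lengths)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative pattern counts")
        self.counts = self.counts.astype(int)

    @property
    def n_cpg(self) -> int:
        return len(self.counts.index[0]) if len(self.counts) else 0

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def depth(self, sample: str) -> int:
        return int(self.counts[sample].sum())

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("pattern").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, amplicon: str = "", cpg_coords=()) -> "EpialleleTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        df.index = df.index.astype(str)
        return cls(df, amplicon, tuple(cpg_coords))

    def to_biom_json(self, path) -> None:
        """Write the table in BIOM format 1.0 (sparse OTU-table layout)."""
        counts = self.counts
        rows, cols = np.nonzero(counts.to_numpy())
        data = [[int(r), int(c), int(counts.iat[r, c])] for r, c in zip(rows, cols)]
        biom = {
            "id": self.amplicon or None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "epiamp",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": list(counts.shape),
            "rows": [{"id": p, "metadata": None} for p in counts.index],
            "columns": [{"id": s, "metadata": None} for s in counts.columns],
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(biom, fh)


def tabulate(profiles_by_sample: dict[str, list[str]],
             amplicon: str = "", cpg_coords=()) -> EpialleleTable:
    """Count binary epiallele patterns per sample.

    ``profiles_by_sample`` maps sample id to the complete (no ambiguous
    call) binary patterns of its reads. Patterns observed nowhere are
    omitted; a sample with no reads keeps a zero column and is flagged by
    ``depth() == 0``.
    """
    lengths = {len(p) for pats in profiles_by_sample.values() for p in pats}
    if len(lengths) > 1:
        raise ValueError(f"mixed amplicon pattern lengths: {sorted(lengths)}")
    series = {
        sample: pd.Series(pats, dtype=str).value_counts()
        for sample, pats in profiles_by_sample.items()
    }
    df = pd.DataFrame(series).fillna(0).astype(int)
    df = df.sort_index()
    df.columns = list(profiles_by_sample)
    return EpialleleTable(df, amplicon, tuple(cpg_coords))


def rarefy(table: EpialleleTable, depth: int | None = None,
           seed: int = 0) -> EpialleleTable:
    """Subsample every sample without replacement to a common depth.

    Default depth is the minimum sample depth. Reproducible given ``seed``
    (one child generator per sample, in column order).
    """
    depths = {s: table.depth(s) for s in table.samples}
    if depth is None:
        depth = min(depths.values())
    shallow = [s for s, d in depths.items() if d < depth]
    if shallow:
        raise ValueError(
            f"rarefaction depth {depth} exceeds depth of sample(s) {shallow}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for s in table.samples:
        col = table.counts[s].to_numpy()
        # multivariate hypergeometric draw: choose `depth` reads from the
        # expanded multiset of this sample's reads
        out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.counts.index)
    df = df[(df.sum(axis=1) > 0)]
    return EpialleleTable(df, table.amplicon, table.cpg_coords)


@dataclass(frozen=True)
class ClassDistribution:
    """Relative abundance of epiallele classes 0..N for one sample."""

    freqs: np.ndarray
    depth: int

    @property
    def n_classes(self) -> int:
        return len(self.freqs)


def _pattern_matrix(table: EpialleleTable) -> np.ndarray:
    """Patterns as a (n_patterns, N) 0/1 matrix."""
    return np.array([[int(ch) for ch in p] for p in table.counts.index], dtype=int)


def class_distribution(table: EpialleleTable, sample: str) -> ClassDistribution:
    """Class-k frequency = (reads with exactly k methylated CpGs) / depth."""
    depth = table.depth(sample)
    if depth == 0:
        raise ValueError(f"sample {sample!r} has zero depth")
    n = table.n_cpg
    weights = _pattern_matrix(table).sum(axis=1)
    counts = np.bincount(weights, weights=table.counts[sample].to_numpy(),
                         minlength=n + 1)
    return ClassDistribution(counts / depth, depth)


def mean_methylation(table: EpialleleTable, sample: str) -> float:
    """Average methylation (%): methylated calls over all calls.

    Identical to the class-weighted mean 100 * sum(k * f_k) / N because
    every counted read is complete.
    """
    depth = table.depth(sample)
    if depth == 0:
        raise ValueError(f"sample {sample!r} has zero depth")
    weights = _pattern_matrix(table).sum(axis=1)
    n_meth = float(weights @ table.counts[sample].to_numpy())
    return 100.0 * n_meth / (table.n_cpg * depth)


def per_cpg_methylation(table: EpialleleTable, sample: str) -> pd.Series:
    """Per-CpG methylation (%), indexed by TSS-relative coordinate."""
    depth = table.depth(sample)
    if depth == 0:
        raise ValueError(f"sample {sample!r} has zero depth")
    mat = _pattern_matrix(table)
    col = table.counts[sample].to_numpy()
    pct = 100.0 * (mat.T @ col) / depth
    index = list(table.cpg_coords) if table.cpg_coords else list(range(table.n_cpg))
    return pd.Series(pct, index=index, name=sample)


def estimate_5hmc(bs_table: EpialleleTable, oxbs_table: EpialleleTable,
                  pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Per-CpG 5hmC estimate from paired BS / oxBS samples.

    Standard bisulfite cannot tell 5mC from 5hmC; oxidative bisulfite
    converts 5hmC so it reads unmethylated. The per-CpG 5hmC level is the
    BS-minus-oxBS methylation difference, clipped at zero (sampling noise
    can drive it negative); the raw difference is reported alongside.

    ``pairs`` lists (bs_sample, oxbs_sample) couples. Returns a tidy frame
    with columns sample, cpg, bs_pct, oxbs_pct, hmc_pct, raw_diff_pct.
    """
    if bs_table.cpg_coords != oxbs_table.cpg_coords or \
            bs_table.n_cpg != oxbs_table.n_cpg:
        raise ValueError("BS and oxBS tables have mismatched CpG maps")
    rows = []
    for bs_s, ox_s in pairs:
        bs = per_cpg_methylation(bs_table, bs_s)
        ox = per_cpg_methylation(oxbs_table, ox_s)
        diff = bs - ox
        for cpg in bs.index:
            rows.append({
                "sample": bs_s,
                "cpg": cpg,
                "bs_pct": bs[cpg],
                "oxbs_pct": ox[cpg],
                "hmc_pct": max(0.0, diff[cpg]),
                "raw_diff_pct": diff[cpg],
            })
    return pd.DataFrame(rows)
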