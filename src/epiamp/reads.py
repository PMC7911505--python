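"""Paired-end FASTQ to per-molecule methylation profiles.

The stages mirror a standard deep-amplicon bisulfite workflow: merge each
read pair on its overlap, align the merged molecule to the in-silico
converted amplicon in three-letter (bisulfite) space, call the methylation
state of every CpG, estimate the per-read bisulfite conversion efficiency
from non-CpG cytosines, then filter on conversion, identity and call
completeness. Attrition at every stage is tracked so a run is auditable.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .amplicon import AmpliconSpec, ConvertedRefs, revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _as_bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class FastqRead:
    id: str
    sequence: str
    qualities: str


@dataclass(frozen=True)
class MergedRead:
    sequence: str
    qualities: str
    merged: bool
    pair_id: str


@dataclass(frozen=True)
class Alignment:
    offset: int            # reference index of the first aligned read base
    orientation: str       # '+' read as given, '-' reverse-complemented
    identity: float        # matches / aligned read length, three-letter space
    ref_bases: np.ndarray  # per reference position: oriented read base, 0 = uncovered


@dataclass(frozen=True)
class MethProfile:
    """Per-molecule CpG call vector.

    ``calls`` holds one character per amplicon CpG: M (methylated),
    U (unmethylated) or X (ambiguous/uncovered). ``conversion_rate`` is the
    fraction of covered non-CpG reference cytosines read as T — the
    per-read bisulfite efficiency.
    """

    calls: str
    conversion_rate: float
    identity: float
    sample_id: str = ""

    @property
    def complete(self) -> bool:
        return "X" not in self.calls

    @property
    def pattern(self) -> str:
        """Binary epiallele pattern; only valid for complete profiles."""
        return self.calls.replace("M", "1").replace("U", "0")


@dataclass
class FilterThresholds:
    """QC thresholds; conventional values for amplicon bisulfite data."""

    conv_min: float = 0.98
    id_min: float = 0.90
    min_len_frac: float = 0.80   # merged length / amplicon length
    min_overlap: int = 20


@dataclass
class QCReport:
    n_input_pairs: int = 0
    n_merged: int = 0
    n_aligned: int = 0
    n_pass: int = 0
    attrition: dict = field(default_factory=dict)
    control_conversion: float | None = None

    def add_rejection(self, reason: str):
        self.attrition[reason] = self.attrition.get(reason, 0) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input_pairs": self.n_input_pairs,
                "n_merged": self.n_merged,
                "n_aligned": self.n_aligned,
                "n_pass": self.n_pass,
                "attrition": self.attrition,
                "control_conversion": self.control_conversion,
            },
            indent=2,
        )


def read_fastq(path) -> list[FastqRead]:
    """Read a plain or gzipped FASTQ file."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [FastqRead(i.split()[0], s.upper(), q)
                for i, s, q in FastqGeneralIterator(fh)]


def _candidate_offsets(s1: str, s2: str, min_overlap: int, k: int = 16) -> set[int]:
    """Exact k-mer anchors from read 2 located in read 1.

    Two anchor start points tolerate a sequencing error inside the first
    k-mer. Offsets outside the admissible overlap range are dropped.
    """
    n1, n2 = len(s1), len(s2)
    lo, hi = -(n2 - min_overlap), n1 - min_overlap
    cands = set()
    for j in (0, k):
        if j + k > n2:
            continue
        kmer = s2[j:j + k]
        pos = s1.find(kmer)
        while pos != -1:
            off = pos - j
            if lo <= off <= hi:
                cands.add(off)
            pos = s1.find(kmer, pos + 1)
    return cands


def merge_pairs(
    r1: FastqRead, r2: FastqRead, min_overlap: int = 20,
    max_mismatch_frac: float = 0.25,
) -> MergedRead | None:
    """Merge a read pair on the best ungapped overlap.

    Read 2 is reverse-complemented and slid along read 1; the layout with
    the highest match-minus-mismatch score over an overlap of at least
    ``min_overlap`` bases wins. Candidate offsets come from exact k-mer
    anchors, with an exhaustive scan as fallback. Overlap disagreements are
    resolved toward the higher base quality. Returns None when no
    acceptable overlap exists.
    """
    if not r1.sequence or not r2.sequence:
        return None
    s1, q1 = r1.sequence, r1.qualities
    s2, q2 = revcomp(r2.sequence), r2.qualities[::-1]
    n1, n2 = len(s1), len(s2)
    if min(n1, n2) < min_overlap:
        return None

    a1, a2 = _as_bytes(s1), _as_bytes(s2)
    offsets = _candidate_offsets(s1, s2, min_overlap)
    if not offsets:
        offsets = range(-(n2 - min_overlap), n1 - min_overlap + 1)

    best_score, best_off, best_mm = None, None, None
    for off in offsets:
        lo, hi = max(0, off), min(n1, off + n2)
        m = int(np.count_nonzero(a1[lo:hi] == a2[lo - off:hi - off]))
        score = 2 * m - (hi - lo)
        if best_score is None or score > best_score:
            best_score, best_off = score, off
            best_mm = (hi - lo - m) / (hi - lo)
    if best_score is None or best_mm > max_mismatch_frac:
        return None

    off = best_off
    b1, b2 = _as_bytes(q1), _as_bytes(q2)
    start, end = min(0, off), max(n1, off + n2)
    length = end - start
    seq = np.zeros(length, dtype=np.uint8)
    qual = np.zeros(length, dtype=np.uint8)
    i1 = slice(-start, -start + n1)                  # read-1 span in output
    i2 = slice(off - start, off - start + n2)        # read-2 span in output
    seq[i2], qual[i2] = a2, b2
    # in the overlap keep read 1's base unless read 2 has strictly higher Q
    keep1 = np.ones(n1, dtype=bool)
    ov1 = slice(max(0, off), min(n1, off + n2))      # overlap within read 1
    ov2 = slice(max(0, -off), max(0, -off) + (ov1.stop - ov1.start))
    keep1[ov1] = b1[ov1] >= b2[ov2]
    out1 = np.arange(-start, -start + n1)[keep1]
    seq[out1] = a1[keep1]
    qual[i1] = np.maximum(qual[i1], b1)
    return MergedRead(seq.tobytes().decode("ascii"),
                      qual.tobytes().decode("ascii"), True, r1.id)


def _walk_cigar(cigar: str, read: str, ref_start: int, ref_len: int) -> np.ndarray:
    """Per-reference-position read bases from an edlib cigar (0 = uncovered)."""
    ref_bases = np.zeros(ref_len, dtype=np.uint8)
    rbytes = _as_bytes(read)
    rpos, gpos = 0, ref_start
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op in "=XM":
            ref_bases[gpos:gpos + n] = rbytes[rpos:rpos + n]
            rpos += n
            gpos += n
        elif op == "I":   # extra read bases, absent from reference
            rpos += n
        else:             # 'D': reference bases not covered by the read
            gpos += n
    return ref_bases


_EQUALITIES = [("Y", "C"), ("Y", "T")]


def align_to_amplicon(read: MergedRead, refs: ConvertedRefs) -> Alignment | None:
    """Semi-global alignment of a merged read in three-letter space.

    Both read and reference are compared with cytosines collapsed to T,
    except CpG-context reference cytosines, which match either C or T
    (their read base encodes methylation, not sequence). Both orientations
    are tried; identity is matches over aligned read length.
    """
    target = refs.two_state
    best = None
    for orient in "+-":
        seq = read.sequence if orient == "+" else revcomp(read.sequence)
        query = seq.replace("C", "T")
        res = edlib.align(query, target, mode="HW", task="path",
                          additionalEqualities=_EQUALITIES)
        if res["editDistance"] < 0:
            continue
        identity = 1.0 - res["editDistance"] / len(query)
        if best is None or identity > best[0]:
            start = res["locations"][0][0]
            best = (identity, orient, start, res["cigar"], seq)
    if best is None:
        return None
    identity, orient, start, cigar, oriented = best
    return Alignment(
        offset=start,
        orientation=orient,
        identity=identity,
        ref_bases=_walk_cigar(cigar, oriented, start, len(target)),
    )


_C, _T = ord("C"), ord("T")


def call_profile(
    alignment: Alignment, spec: AmpliconSpec, sample_id: str = ""
) -> MethProfile | None:
    """Call the CpG methylation vector and per-read conversion rate.

    At each CpG cytosine: read C -> M, read T -> U, anything else
    (or uncovered) -> X. The conversion rate is the T fraction over covered
    non-CpG reference cytosines; a read covering none is uninformative and
    rejected (None).
    """
    bases = alignment.ref_bases
    cpg = bases[np.array(spec.cpg_indices, dtype=int)]
    calls = np.where(cpg == _C, "M", np.where(cpg == _T, "U", "X"))
    noncpg = bases[np.array(spec.noncpg_c_indices, dtype=int)]
    covered = noncpg[noncpg != 0]
    if covered.size == 0:
        return None
    conv = float(np.count_nonzero(covered == _T) / covered.size)
    return MethProfile("".join(calls), conv, alignment.identity, sample_id)


def filter_profiles(
    profiles: list[MethProfile], thresholds: FilterThresholds, qc: QCReport
) -> list[MethProfile]:
    """Apply conversion, identity and completeness filters in order."""
    passing = []
    for p in profiles:
        if p.conversion_rate < thresholds.conv_min:
            qc.add_rejection("conversion")
        elif p.identity < thresholds.id_min:
            qc.add_rejection("identity")
        elif not p.complete:
            qc.add_rejection("ambiguous_cpg")
        else:
            passing.append(p)
    qc.n_pass = len(passing)
    return passing


def process_pairs(
    pairs: list[tuple[FastqRead, FastqRead]],
    spec: AmpliconSpec,
    refs: ConvertedRefs,
    thresholds: FilterThresholds | None = None,
    sample_id: str = "",
) -> tuple[list[MethProfile], QCReport]:
    """Full per-sample stage: merge -> align -> call -> filter."""
    thresholds = thresholds or FilterThresholds()
    qc = QCReport(n_input_pairs=len(pairs))
    min_len = thresholds.min_len_frac * spec.length_bp
    profiles = []
    for r1, r2 in pairs:
        merged = merge_pairs(r1, r2, thresholds.min_overlap)
        if merged is None:
            qc.add_rejection("merge")
            continue
        qc.n_merged += 1
        if len(merged.sequence) < min_len:
            qc.add_rejection("length")
            continue
        aln = align_to_amplicon(merged, refs)
        if aln is None or aln.identity < thresholds.id_min:
            qc.add_rejection("identity")
            continue
        qc.n_aligned += 1
        prof = call_profile(aln, spec, sample_id)
        if prof is None:
            qc.add_rejection("no_noncpg_c")
            continue
        profiles.append(prof)
    kept = filter_profiles(profiles, thresholds, qc)
    return kept, qc


def control_conversion(
    pairs: list[tuple[FastqRead, FastqRead]],
    control_spec: AmpliconSpec,
    min_overlap: int = 20,
) -> float | None:
    """Global bisulfite efficiency from an unmethylated spike-in control.

    The control (an M13mp18-style fully unmethylated amplicon) should read
    T at *every* cytosine, CpG or not; the efficiency is the overall T
    fraction at reference C positions. Returns None without control reads.
    """
    if not pairs:
        return None
    from .amplicon import bisulfite_convert_reference

    refs = bisulfite_convert_reference(control_spec)
    c_idx = np.array(
        sorted(set(control_spec.cpg_indices) | set(control_spec.noncpg_c_indices)),
        dtype=int,
    )
    n_t = n_cov = 0
    for r1, r2 in pairs:
        merged = merge_pairs(r1, r2, min_overlap)
        if merged is None:
            continue
        aln = align_to_amplicon(merged, refs)
        if aln is None:
            continue
        obs = aln.ref_bases[c_idx]
        covered = obs[obs != 0]
        n_cov += covered.size
        n_t += int(np.count_nonzero(covered == _T))
    return n_t / n_cov if n_cov else None
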