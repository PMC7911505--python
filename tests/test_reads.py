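"""Read processing: merging, alignment, calling, filtering, control QC."""

import numpy as np
import pytest

from epiamp import (FastqRead, FilterThresholds, MergedRead, NoiseModel,
                    QCReport, align_to_amplicon, bisulfite_convert_reference,
                    call_profile, control_conversion, emit_control_reads,
                    emit_reads, filter_profiles, make_amplicon, merge_pairs,
                    patterns_to_strings, process_pairs, revcomp,
                    sample_epialleles)
from epiamp.simulate import IndependentModel


def _fq(seq, qual=None, rid="r"):
    return FastqRead(rid, seq, qual or "I" * len(seq))


def _brute_force_merge(s1, s2_rc, min_overlap):
    """Enumerate every ungapped layout, pick max match-minus-mismatch."""
    n1, n2 = len(s1), len(s2_rc)
    best = None
    for off in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        lo, hi = max(0, off), min(n1, off + n2)
        score = sum(1 if s1[i] == s2_rc[i - off] else -1 for i in range(lo, hi))
        if best is None or score > best[0]:
            best = (score, off)
    return best


def test_merge_overlap_matches_bruteforce_oracle():
    r1 = _fq("ACGTACGT")
    r2 = _fq(revcomp("GTACGTTT"))
    merged = merge_pairs(r1, r2, min_overlap=6)
    score, off = _brute_force_merge("ACGTACGT", "GTACGTTT", 6)
    assert off == 2
    assert merged.sequence == "ACGTACGTTT"
    assert len(merged.sequence) == max(8, off + 8)


def test_merge_identical_duplicates():
    seq = "ACGTTAGGCATT"
    merged = merge_pairs(_fq(seq), _fq(revcomp(seq)), min_overlap=6)
    assert merged.sequence == seq


def test_merge_disjoint_rejected():
    assert merge_pairs(_fq("AAAAAAAA"), _fq("CCCCCCCC"), min_overlap=8) is None
    assert merge_pairs(_fq(""), _fq("ACGT")) is None


def test_merge_symmetry_under_mate_swap(rng):
    # the mate-swapped, orientation-adjusted pair merges to the revcomp
    mol = "".join(rng.choice(list("ACGT"), size=60))
    r1 = _fq(mol[:40], rid="a")
    r2 = _fq(revcomp(mol[20:]), rid="b")
    fwd = merge_pairs(r1, r2, min_overlap=15)
    swapped = merge_pairs(r2, r1, min_overlap=15)
    assert fwd.sequence == mol
    assert swapped.sequence == revcomp(fwd.sequence)


def test_merge_disagreement_resolved_by_quality(rng):
    mol = "".join(rng.choice(list("ACGT"), size=40))
    s2 = list(mol[8:])
    s2[0] = {"A": "T", "T": "A", "C": "G", "G": "C"}[s2[0]]  # clash at pos 8
    qual1 = "I" * 8 + "#" + "I" * 31               # read 1 low Q at the clash
    r1 = _fq(mol, qual=qual1)
    r2 = FastqRead("r2", revcomp("".join(s2)), "I" * 32)
    merged = merge_pairs(r1, r2, min_overlap=10)
    assert merged.sequence[8] == s2[0]             # higher-quality base wins
    # and the mirror case: read 1 confident, read 2 weak
    r1b = _fq(mol)
    # quality strings follow the stored (revcomp) orientation
    r2b = FastqRead("r2", revcomp("".join(s2)), "I" * 31 + "#")
    merged = merge_pairs(r1b, r2b, min_overlap=10)
    assert merged.sequence[8] == mol[8]


def test_align_unmethylated_and_methylated_identity(small_spec):
    refs = bisulfite_convert_reference(small_spec)
    unmeth = refs.forward_bs.replace("C", "T")     # every CpG converted
    meth = refs.forward_bs                         # CpG cytosines retained
    for seq in (unmeth, meth):
        aln = align_to_amplicon(MergedRead(seq, "I" * len(seq), True, "m"), refs)
        assert aln.identity == 1.0
        assert aln.offset == 0


def test_align_reverse_orientation(small_spec):
    refs = bisulfite_convert_reference(small_spec)
    seq = revcomp(refs.forward_bs)
    aln = align_to_amplicon(MergedRead(seq, "I" * len(seq), True, "m"), refs)
    assert aln.orientation == "-"
    assert aln.identity == 1.0


def test_align_identity_counts_substitutions(small_spec, rng):
    refs = bisulfite_convert_reference(small_spec)
    seq = list(refs.forward_bs.replace("C", "T"))
    # isolated substitutions at A/G positions, spaced so gapped alignments
    # cannot absorb them more cheaply than mismatches
    targets, last = [], -20
    for i, b in enumerate(seq):
        if b in "AG" and i - last >= 15:
            targets.append(i)
            last = i
    for i in targets:
        seq[i] = "T" if seq[i] == "A" else "A"
    aln = align_to_amplicon(MergedRead("".join(seq), "I" * len(seq), True, "m"),
                            refs)
    assert aln.identity == pytest.approx(1 - len(targets) / len(seq))


def test_call_profile_states(small_spec):
    refs = bisulfite_convert_reference(small_spec)
    n = small_spec.n_cpg
    meth = refs.forward_bs                       # all CpGs methylated
    aln = align_to_amplicon(MergedRead(meth, "I" * len(meth), True, "m"), refs)
    prof = call_profile(aln, small_spec)
    assert prof.calls == "M" * n
    assert prof.conversion_rate == 1.0

    unmeth = list(refs.forward_bs.replace("C", "T"))
    unmeth[small_spec.cpg_indices[0]] = "G"      # non-C/T base at first CpG
    aln = align_to_amplicon(
        MergedRead("".join(unmeth), "I" * len(unmeth), True, "m"), refs)
    prof = call_profile(aln, small_spec)
    assert prof.calls == "X" + "U" * (n - 1)

    partial = list(refs.forward_bs.replace("C", "T"))
    partial[small_spec.noncpg_c_indices[0]] = "C"   # one unconverted C
    aln = align_to_amplicon(
        MergedRead("".join(partial), "I" * len(partial), True, "m"), refs)
    prof = call_profile(aln, small_spec)
    k = len(small_spec.noncpg_c_indices)
    assert prof.conversion_rate == pytest.approx((k - 1) / k)


def test_filter_attrition_accounting(small_spec, rng):
    model = IndependentModel(np.full(small_spec.n_cpg, 0.5))
    pats = sample_epialleles(model, 300, rng)
    noise = NoiseModel(incomplete_conversion=0.05, over_conversion=0.01,
                       seq_error=0.01, hmc_fraction=0.0)
    pairs = emit_reads(pats, small_spec, noise, "BS", rng, read_len=100)
    refs = bisulfite_convert_reference(small_spec)
    profiles, qc = process_pairs(pairs, small_spec, refs,
                                 FilterThresholds(conv_min=0.99))
    assert qc.n_input_pairs == 300
    assert qc.n_input_pairs >= qc.n_merged >= qc.n_aligned >= qc.n_pass
    assert qc.n_pass + sum(qc.attrition.values()) == qc.n_input_pairs
    assert qc.attrition.get("conversion", 0) > 0


def test_filter_reasons(small_spec):
    from epiamp.reads import MethProfile
    thr = FilterThresholds(conv_min=0.98, id_min=0.90)
    profiles = [
        MethProfile("M" * small_spec.n_cpg, 1.0, 1.0),
        MethProfile("M" * small_spec.n_cpg, 0.90, 1.0),
        MethProfile("M" * small_spec.n_cpg, 1.0, 0.5),
        MethProfile("MX" + "M" * (small_spec.n_cpg - 2), 1.0, 1.0),
    ]
    qc = QCReport(n_input_pairs=4, n_merged=4, n_aligned=4)
    kept = filter_profiles(profiles, thr, qc)
    assert len(kept) == 1
    assert qc.attrition == {"conversion": 1, "identity": 1, "ambiguous_cpg": 1}


def test_zero_noise_roundtrip_recovers_patterns(small_spec, rng, no_noise):
    model = IndependentModel(np.linspace(0.1, 0.9, small_spec.n_cpg))
    pats = sample_epialleles(model, 300, rng)
    pairs = emit_reads(pats, small_spec, no_noise, "BS", rng, read_len=100)
    refs = bisulfite_convert_reference(small_spec)
    profiles, qc = process_pairs(pairs, small_spec, refs)
    assert qc.n_pass == 300
    assert [p.pattern for p in profiles] == patterns_to_strings(pats)


def test_conversion_rate_calibration(small_spec, rng):
    """Mean per-read (1 - conversion_rate) matches the simulated rate."""
    c = 0.02
    model = IndependentModel(np.zeros(small_spec.n_cpg))
    pats = sample_epialleles(model, 400, rng)
    noise = NoiseModel(incomplete_conversion=c, over_conversion=0.0,
                       seq_error=0.0, hmc_fraction=0.0)
    pairs = emit_reads(pats, small_spec, noise, "BS", rng, read_len=100)
    refs = bisulfite_convert_reference(small_spec)
    profiles, _ = process_pairs(pairs, small_spec, refs,
                                FilterThresholds(conv_min=0.0))
    fail = np.mean([1 - p.conversion_rate for p in profiles])
    n_obs = 400 * len(small_spec.noncpg_c_indices)
    se = np.sqrt(c * (1 - c) / n_obs)
    assert abs(fail - c) < 3 * se


def test_control_conversion(rng, no_noise):
    control = make_amplicon(4, 150, seed=5, name="ctrl")
    perfect = emit_control_reads(control, 50, no_noise, rng, read_len=100)
    assert control_conversion(perfect, control) == 1.0
    assert control_conversion([], control) is None

    c = 0.02
    noisy = emit_control_reads(
        control, 200,
        NoiseModel(incomplete_conversion=c, over_conversion=0.0,
                   seq_error=0.0, hmc_fraction=0.0), rng, read_len=100)
    eff = control_conversion(noisy, control)
    n_c = len(control.cpg_indices) + len(control.noncpg_c_indices)
    se = np.sqrt(c * (1 - c) / (200 * n_c))
    assert abs(eff - (1 - c)) < 3 * se
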