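"""Amplicon reference model for targeted bisulfite sequencing.

An amplicon is a short promoter region (a few hundred bp) amplified from
bisulfite-converted DNA. CpG cytosines within it are the methylation-
informative positions; they are labelled relative to the transcriptional
start site (TSS = +1, upstream negative, no zero), following the usual
promoter-coordinate convention.

Only the primer-defined top bisulfite strand is modelled: the amplicon
design fixes which strand is sequenced, and the reverse strand carries no
additional information for a fixed primer pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_tss_coord(i: int, tss_index: int) -> int:
    """Convert a 0-based sequence index to a TSS-relative coordinate.

    The TSS base itself is +1; there is no coordinate 0: the base
    immediately upstream of the TSS is -1.
    """
    if i < 0:
        raise ValueError(f"negative sequence index {i}")
    return i - tss_index + 1 if i >= tss_index else i - tss_index


def from_tss_coord(coord: int, tss_index: int) -> int:
    """Inverse of :func:`to_tss_coord`; coordinate 0 does not exist."""
    if coord == 0:
        raise ValueError("TSS-relative coordinate 0 is undefined (TSS is +1)")
    i = coord + tss_index - 1 if coord > 0 else coord + tss_index
    if i < 0:
        raise ValueError(f"coordinate {coord} lies upstream of the sequence")
    return i


def find_cpg_sites(sequence: str, tss_index: int) -> list[tuple[int, int]]:
    """Locate every CpG cytosine in ``sequence``.

    Returns ``(0-based index of the C, TSS-relative coordinate)`` pairs in
    sequence order. Rejects characters outside A/C/G/T/N.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    if not 0 <= tss_index < len(seq):
        raise ValueError(f"tss_index {tss_index} out of range for length {len(seq)}")
    sites = []
    pos = seq.find("CG")
    while pos != -1:
        sites.append((pos, to_tss_coord(pos, tss_index)))
        pos = seq.find("CG", pos + 1)
    return sites


@dataclass(frozen=True)
class AmpliconSpec:
    """Reference amplicon with its CpG coordinate map.

    ``cpg_indices`` are 0-based positions of CpG cytosines within
    ``sequence``; ``cpg_coords`` are the matching TSS-relative labels.
    """

    name: str
    sequence: str
    tss_index: int
    cpg_indices: tuple[int, ...] = field(init=False)
    cpg_coords: tuple[int, ...] = field(init=False)

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        # CpG status next to an N is ambiguous: refuse rather than guess.
        if "CN" in seq or "NG" in seq:
            raise ValueError(f"{self.name}: CpG context overlapping N is ambiguous")
        sites = find_cpg_sites(seq, self.tss_index)
        object.__setattr__(self, "cpg_indices", tuple(i for i, _ in sites))
        object.__setattr__(self, "cpg_coords", tuple(c for _, c in sites))

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_indices)

    @property
    def noncpg_c_indices(self) -> tuple[int, ...]:
        cpg = set(self.cpg_indices)
        return tuple(
            i for i, b in enumerate(self.sequence) if b == "C" and i not in cpg
        )

    def cpg_map_tsv(self) -> str:
        """BED-like CpG map: 0-based half-open interval + TSS label."""
        lines = ["#amplicon\tstart\tend\ttss_label"]
        for i, coord in zip(self.cpg_indices, self.cpg_coords):
            lines.append(f"{self.name}\t{i}\t{i + 1}\t{coord:+d}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ConvertedRefs:
    """In-silico bisulfite-converted view of an amplicon.

    ``forward_bs`` has every cytosine outside CpG context deaminated to T;
    CpG cytosines are kept as C and matched in two-state mode (C or T)
    during alignment, since their read base depends on methylation.
    """

    forward_bs: str
    pattern_mask: tuple[int, ...]  # CpG C indices
    noncpg_c_indices: tuple[int, ...]

    @property
    def two_state(self) -> str:
        """Alignment target: CpG cytosines as the pyrimidine wildcard Y."""
        chars = list(self.forward_bs)
        for i in self.pattern_mask:
            chars[i] = "Y"
        return "".join(chars)


def bisulfite_convert_reference(spec: AmpliconSpec) -> ConvertedRefs:
    """Model complete bisulfite conversion of the unmethylated reference.

    Non-CpG cytosines always read as T; CpG cytosines are left symbolic
    (methylation-dependent) and are resolved per read at calling time.
    """
    cpg = set(spec.cpg_indices)
    chars = [
        "T" if b == "C" and i not in cpg else b
        for i, b in enumerate(spec.sequence)
    ]
    return ConvertedRefs(
        forward_bs="".join(chars),
        pattern_mask=spec.cpg_indices,
        noncpg_c_indices=spec.noncpg_c_indices,
    )


def _three_letter(seq: str) -> str:
    return seq.replace("C", "T")


def _locate_primer(ref3: str, primer3: str, label: str) -> int:
    pos = ref3.find(primer3)
    if pos == -1:
        raise ValueError(f"{label} primer not found in bisulfite-space reference")
    if ref3.find(primer3, pos + 1) != -1:
        raise ValueError(f"{label} primer matches the reference more than once")
    return pos


def trim_to_insert(
    reference: str, tss_offset: int, fw_primer: str, rv_primer: str, name: str
) -> AmpliconSpec:
    """Build an AmpliconSpec for the primer-enclosed insert.

    Primers are written against the converted top strand (they contain
    degenerate bisulfite bases), so matching is done in three-letter space:
    both reference and primers with C collapsed to T, the reverse primer as
    its reverse complement. Primer bases are trimmed before CpG calling to
    avoid primer-encoded bias.
    """
    ref = reference.upper()
    ref3 = _three_letter(ref)
    fw = _three_letter(fw_primer.upper())
    rv = _three_letter(revcomp(rv_primer.upper()))
    fw_pos = _locate_primer(ref3, fw, "forward")
    rv_pos = _locate_primer(ref3, rv, "reverse")
    start = fw_pos + len(fw)
    end = rv_pos
    if end <= start:
        raise ValueError("primers do not enclose a positive-length insert")
    if not start <= tss_offset < end:
        raise ValueError("TSS falls outside the primer-enclosed insert")
    return AmpliconSpec(
        name=name, sequence=ref[start:end], tss_index=tss_offset - start
    )


def load_amplicon(
    fasta_path, name: str, tss_offset: int, fw_primer: str | None = None,
    rv_primer: str | None = None,
) -> AmpliconSpec:
    """Load one amplicon reference from FASTA by record name.

    With a primer pair the spec covers the enclosed insert only; without
    primers the full record is used and ``tss_offset`` indexes into it.
    """
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id == name:
            seq = str(rec.seq).upper()
            if fw_primer and rv_primer:
                return trim_to_insert(seq, tss_offset, fw_primer, rv_primer, name)
            return AmpliconSpec(name=name, sequence=seq, tss_index=tss_offset)
    raise ValueError(f"record {name!r} not found in {fasta_path}")
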