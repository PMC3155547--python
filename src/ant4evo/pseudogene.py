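"""Pseudogene lesion scanning.

Identifies the marks of gene death on a candidate sequence: premature stop
codons (read in the frame of a functional reference CDS projected through a
pairwise alignment), frame-disrupting indels (gap lengths not divisible by
3), and loss of the canonical GT/AG splice dinucleotides. Also the
translated-fragment matching and percent-identity arithmetic used to locate
degenerate coding fragments in genomic sequence.

All coordinates are 0-based, half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Seq import Seq

from .seqio import GAP, GeneticCode, STANDARD_CODE

_IUPAC_NT = set("ACGTRYSWKMBDHVN-")


class ScanError(ValueError):
    pass


@dataclass
class Frameshift:
    position: int  # candidate-sequence coordinate of the first indel base
    indel_length: int
    type: str  # "insertion" | "deletion"

    def __post_init__(self):
        if self.indel_length % 3 == 0:
            raise ScanError("a frameshift indel length must not be divisible by 3")
        if self.type not in ("insertion", "deletion"):
            raise ScanError(f"indel type must be insertion/deletion, got {self.type!r}")


@dataclass
class SpliceDefect:
    role: str  # "donor" | "acceptor"
    observed: str  # dinucleotide seen in place of GT / AG


@dataclass
class LesionReport:
    region_id: str
    premature_stops: list[tuple[int, str]] = field(default_factory=list)
    frameshifts: list[Frameshift] = field(default_factory=list)
    splice_defects: list[SpliceDefect] = field(default_factory=list)

    @property
    def intact(self) -> bool:
        return not (self.premature_stops or self.frameshifts or self.splice_defects)

    def to_dict(self) -> dict:
        return {
            "region_id": self.region_id,
            "intact": self.intact,
            "premature_stops": [
                {"codon_index": i, "stop_codon": c} for i, c in self.premature_stops
            ],
            "frameshifts": [
                {"position": f.position, "indel_length": f.indel_length, "type": f.type}
                for f in self.frameshifts
            ],
            "splice_defects": [
                {"role": d.role, "observed": d.observed} for d in self.splice_defects
            ],
        }


@dataclass
class FragmentMatch:
    frame: int  # 0-2 forward, 3-5 reverse-complement
    query_span: tuple[int, int]  # nucleotides on the query, 0-based half-open
    subject_span: tuple[int, int]  # amino acids on the subject
    aligned_length: int
    percent_identity: float


def translate_frames(seq: str, code: GeneticCode = STANDARD_CODE) -> list[str]:
    """Six-frame translation; frames 3-5 read the reverse complement.

    Stops render as '*'; trailing partial codons are dropped.
    """
    seq = seq.upper()
    if len(seq) < 3:
        raise ScanError("sequence shorter than one codon")
    bad = set(seq) - _IUPAC_NT
    if bad:
        raise ScanError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    rc = str(Seq(seq).reverse_complement())
    out = []
    for strand_seq in (seq, rc):
        for offset in range(3):
            sub = strand_seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            out.append(str(Seq(sub).translate(table=code.table_id)))
    return out


def percent_identity(a: str, b: str) -> float:
    """Identity (0-100) over columns where neither sequence has a gap."""
    if len(a) != len(b):
        raise ScanError(f"aligned strings differ in length: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not pairs:
        raise ScanError("no gap-free columns to compare")
    matches = sum(x == y for x, y in pairs)
    return 100.0 * matches / len(pairs)


def find_fragment_matches(
    query_nt: str,
    subject_aa: str,
    min_length: int = 10,
    min_identity: float = 40.0,
    code: GeneticCode = STANDARD_CODE,
) -> list[FragmentMatch]:
    """Locate translatable fragments of a genomic query matching a protein.

    Each of the six reading frames is locally aligned (BLOSUM62, affine
    gaps) against the subject protein; matches above the length and identity
    floors are reported with nucleotide coordinates on the forward strand of
    the query. This is a small-scale scan for a candidate locus, not a
    genome-wide homology search.
    """
    aligner = Align.PairwiseAligner(scoring="blastp")
    aligner.mode = "local"
    frames = translate_frames(query_nt, code)
    L = len(query_nt)
    out: list[FragmentMatch] = []
    for frame, aa in enumerate(frames):
        if not aa:
            continue
        alignments = aligner.align(aa.replace("*", "X"), subject_aa)
        if len(alignments) == 0:
            continue
        best = alignments[0]
        qs, qe = int(best.aligned[0][0][0]), int(best.aligned[0][-1][1])
        ss, se = int(best.aligned[1][0][0]), int(best.aligned[1][-1][1])
        a_str, b_str = str(best[0]), str(best[1])
        ident = percent_identity(a_str, b_str)
        length = qe - qs
        if length < min_length or ident < min_identity:
            continue
        offset = frame % 3
        if frame < 3:
            nt_span = (offset + 3 * qs, offset + 3 * qe)
        else:
            nt_span = (L - (offset + 3 * qe), L - (offset + 3 * qs))
        out.append(FragmentMatch(frame, nt_span, (ss, se), length, ident))
    return sorted(out, key=lambda m: -m.percent_identity)


def detect_lesions(
    candidate: str,
    reference_cds: str,
    pairwise_aln: tuple[str, str],
    region_id: str = "candidate",
    code: GeneticCode = STANDARD_CODE,
) -> LesionReport:
    """Read the reference frame through a pairwise alignment and list lesions.

    ``pairwise_aln`` is (aligned candidate, aligned reference): equal-length
    strings whose ungapped contents match ``candidate`` / ``reference_cds``.
    In-frame candidate codons that are stops (where the reference codon is
    not) are premature stops, indexed by reference codon. Gap runs whose
    length is not divisible by 3 are frameshifts, positioned at the
    candidate coordinate of the first inserted/deleted base. The reference
    must be a clean CDS (no internal stops).
    """
    cand_aln, ref_aln = (s.upper() for s in pairwise_aln)
    if len(cand_aln) != len(ref_aln):
        raise ScanError("aligned pair rows differ in length")
    candidate, reference_cds = candidate.upper(), reference_cds.upper()
    if cand_aln.replace(GAP, "") != candidate:
        raise ScanError("aligned candidate does not match candidate sequence")
    if ref_aln.replace(GAP, "") != reference_cds:
        raise ScanError("aligned reference does not match reference CDS")
    ref_codons = [
        reference_cds[i : i + 3] for i in range(0, len(reference_cds) - 2, 3)
    ]
    if any(code.is_stop(c) for c in ref_codons[:-1]):
        raise ScanError("reference CDS contains internal stop codons")

    report = LesionReport(region_id)
    # candidate bases substituting each reference position (None under deletion)
    by_ref_pos: list[str | None] = [None] * len(reference_cds)
    cand_pos = ref_pos = 0
    run_type: str | None = None
    run_len = 0
    run_start_cand = 0

    def close_run():
        nonlocal run_type, run_len
        if run_type is not None and run_len % 3 != 0:
            report.frameshifts.append(Frameshift(run_start_cand, run_len, run_type))
        run_type, run_len = None, 0

    for c, r in zip(cand_aln, ref_aln):
        if c != GAP and r != GAP:
            close_run()
            by_ref_pos[ref_pos] = c
            cand_pos += 1
            ref_pos += 1
        elif r == GAP:  # insertion in candidate
            if run_type != "insertion":
                close_run()
                run_type, run_start_cand = "insertion", cand_pos
            run_len += 1
            cand_pos += 1
        else:  # deletion from candidate
            if run_type != "deletion":
                close_run()
                run_type, run_start_cand = "deletion", cand_pos
            run_len += 1
            ref_pos += 1
    close_run()

    for idx in range(len(ref_codons)):
        bases = by_ref_pos[3 * idx : 3 * idx + 3]
        if any(b is None for b in bases) or len(bases) < 3:
            continue
        codon = "".join(bases)  # type: ignore[arg-type]
        if codon in code.stops and not code.is_stop(ref_codons[idx]):
            report.premature_stops.append((idx, codon))
    return report


def check_splice_sites(
    genomic: str, intron_span: tuple[int, int]
) -> tuple[bool, bool]:
    """Canonical GT..AG check on an intron given as a 0-based half-open span."""
    start, end = intron_span
    genomic = genomic.upper()
    if not (0 <= start < end <= len(genomic)):
        raise ScanError(f"intron span {intron_span} outside sequence bounds")
    if end - start < 4:
        raise ScanError(f"intron span {intron_span} shorter than 4 nt")
    donor_ok = genomic[start : start + 2] == "GT"
    acceptor_ok = genomic[end - 2 : end] == "AG"
    return donor_ok, acceptor_ok
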