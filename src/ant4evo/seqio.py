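"""Sequence I/O and codon-alignment construction.

FASTA reading/writing goes through Bio.SeqIO; genetic codes come from NCBI
translation tables via Bio.Data.CodonTable. Codon alignments are the unit of
likelihood computation: each cell is a sense codon, the fully ambiguous
marker ``NNN``, or all-gap ``---`` (stop-containing and partial codons are
masked to ambiguous at construction so no stop state ever enters the model).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

GAP = "-"
AMBIGUOUS = "NNN"
ALL_GAP = "---"

_NUCS = "TCAG"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class FormatError(ValueError):
    """Malformed sequence input."""


class AlignmentError(ValueError):
    """Records that do not form a valid alignment."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise FormatError("empty record id")
        if not self.seq:
            raise FormatError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "seq", self.seq.upper())


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate record ids in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    out = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(out)


class NucAlignment:
    """Equal-length nucleotide records; gap character is '-' only."""

    def __init__(self, records: list[SequenceRecord]):
        if len(records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        lengths = {r.id: len(r.seq) for r in records}
        if len(set(lengths.values())) != 1:
            raise AlignmentError(f"ragged alignment, lengths per record: {lengths}")
        self.records = list(records)
        self.length = len(records[0].seq)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return self.length


def read_alignment(path: str | Path) -> NucAlignment:
    return NucAlignment(read_fasta(path))


class GeneticCode:
    """Codon -> amino-acid map for an NCBI translation table.

    Also caches the structural tensors codon models need: which sense-codon
    pairs differ at exactly one position, which of those are transitions, and
    which are nonsynonymous.
    """

    def __init__(self, table_id: int = 1):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.stops: frozenset[str] = frozenset(table.stop_codons)
        self.table: dict[str, str] = dict(table.forward_table)
        all_codons = [a + b + c for a in _NUCS for b in _NUCS for c in _NUCS]
        if set(self.table) | self.stops != set(all_codons):
            raise ValueError(f"translation table {table_id} does not cover 64 codons")
        self.sense_codons: list[str] = [c for c in all_codons if c not in self.stops]
        self.codon_index = {c: i for i, c in enumerate(self.sense_codons)}
        self.n = len(self.sense_codons)
        self._build_structure()

    def _build_structure(self) -> None:
        n = self.n
        single = np.zeros((n, n), dtype=bool)
        transition = np.zeros((n, n), dtype=bool)
        nonsyn = np.zeros((n, n), dtype=bool)
        for i, ci in enumerate(self.sense_codons):
            for j, cj in enumerate(self.sense_codons):
                if i == j:
                    continue
                diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diffs) != 1:
                    continue
                single[i, j] = True
                transition[i, j] = diffs[0] in _TRANSITIONS
                nonsyn[i, j] = self.table[ci] != self.table[cj]
        self.single_diff = single
        self.is_transition = transition
        self.is_nonsyn = nonsyn

    def aa(self, codon: str) -> str:
        return "*" if codon in self.stops else self.table[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops


@lru_cache(maxsize=8)
def genetic_code(table_id: int = 1) -> GeneticCode:
    return GeneticCode(table_id)


STANDARD_CODE = genetic_code(1)


@dataclass
class CodonAlignment:
    """Codon-columns over taxa. Cells are sense codons, 'NNN', or '---'."""

    taxa: list[str]
    codons: list[list[str]]  # per taxon, n_sites codon strings
    stop_masked: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(row) for row in self.codons}
        if len(lengths) != 1:
            raise AlignmentError("ragged codon matrix")
        if len(self.taxa) != len(self.codons):
            raise AlignmentError("taxa / codon-row count mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.codons[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> list[str]:
        try:
            return self.codons[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def indices(self, code: GeneticCode) -> np.ndarray:
        """(n_taxa, n_sites) sense-codon indices; -1 marks ambiguous/gap."""
        out = np.full((self.n_taxa, self.n_sites), -1, dtype=np.int64)
        for t, row in enumerate(self.codons):
            for s, codon in enumerate(row):
                out[t, s] = code.codon_index.get(codon, -1)
        return out

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        return CodonAlignment(list(taxa), [list(self.row(t)) for t in taxa])


def codonize(
    aln: NucAlignment, frame_offset: int = 0, code: GeneticCode = STANDARD_CODE
) -> CodonAlignment:
    """Slice an in-frame nucleotide alignment into codon columns.

    Trailing bases beyond the last full codon are dropped. Cells containing a
    stop codon or any gap/ambiguity are masked to 'NNN' (all-gap cells stay
    '---'); per-taxon stop counts are recorded and logged.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    usable = aln.length - frame_offset
    n_sites = usable // 3
    if n_sites < 1:
        raise AlignmentError("alignment shorter than one codon after frame offset")
    taxa = aln.ids
    matrix: list[list[str]] = []
    stop_masked: dict[str, int] = {}
    for rec in aln.records:
        row = []
        stops = 0
        for s in range(n_sites):
            start = frame_offset + 3 * s
            cell = rec.seq[start : start + 3]
            if cell == ALL_GAP:
                row.append(ALL_GAP)
            elif code.is_stop(cell):
                stops += 1
                row.append(AMBIGUOUS)
            elif cell in code.codon_index:
                row.append(cell)
            else:
                row.append(AMBIGUOUS)
        if stops:
            stop_masked[rec.id] = stops
            log.warning("masked %d stop codon(s) in %s", stops, rec.id)
        matrix.append(row)
    return CodonAlignment(taxa, matrix, stop_masked)


def alignment_from_codons(aln: CodonAlignment) -> NucAlignment:
    """Back-convert codon columns to a nucleotide alignment ('NNN' kept as-is)."""
    return NucAlignment(
        [SequenceRecord(t, "".join(row)) for t, row in zip(aln.taxa, aln.codons)]
    )
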