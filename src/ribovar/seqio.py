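"""Sequence I/O, reference-anchored pairwise alignment, and locus partitioning.

The amplicon under study is the ~1400 bp ITS1–5.8S–ITS2–LSU D1/D2 region of
the fungal rDNA operon.  Every downstream analysis is anchored to a single
reference coordinate system: each clone (or type strain) is aligned globally
to the reference once, and all per-locus extraction, distance computation and
SNP calling happens in reference coordinates.  Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._align import gotoh_global

LOCUS_NAMES = ("ITS1", "5.8S", "ITS2", "LSU")

#: Characters legal in an unaligned DNA sequence: canonical bases, N and the
#: IUPAC two/three-base ambiguity codes (produced by the iupac consensus
#: policy).  '-' is additionally legal inside alignments.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN")
GAP = "-"


class SequenceError(ValueError):
    """Malformed sequence input (illegal residue, empty record, ...)."""


@dataclasses.dataclass(frozen=True)
class Sequence:
    """A named DNA sequence (uppercase, IUPAC alphabet, no gaps)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - IUPAC_CHARS
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise SequenceError(
                f"sequence {self.id!r} has illegal residue "
                f"{self.residues[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass(frozen=True)
class LocusAnnotation:
    """Named locus intervals on a reference, 0-based half-open.

    All four loci (ITS1, 5.8S, ITS2, LSU) must be present exactly once,
    sorted and non-overlapping.
    """

    reference_id: str
    intervals: tuple  # of (locus_name, start, end)

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(tuple(iv) for iv in self.intervals))
        names = [iv[0] for iv in self.intervals]
        if sorted(names) != sorted(LOCUS_NAMES):
            raise ValueError(
                f"annotation must contain each of {LOCUS_NAMES} exactly once, got {names}"
            )
        prev_end = -1
        for name, start, end in self.intervals:
            if not (0 <= start < end):
                raise ValueError(f"bad interval for {name}: ({start}, {end})")
            if start < prev_end:
                raise ValueError("annotation intervals overlap or are unsorted")
            prev_end = end

    def with_reference(self, reference_id: str) -> "LocusAnnotation":
        """Same intervals re-anchored to another (coordinate-identical) id."""
        return dataclasses.replace(self, reference_id=reference_id)

    def interval(self, locus: str) -> tuple:
        for name, start, end in self.intervals:
            if name == locus:
                return (start, end)
        raise KeyError(locus)

    @property
    def loci(self) -> tuple:
        return tuple(iv[0] for iv in self.intervals)


@dataclasses.dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment scoring. A gap of length k costs open + (k-1)*extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclasses.dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of a query against a reference.

    ``ref_coords[j]`` is the reference position consumed at alignment column
    j, or -1 where the reference has a gap (a query insertion).
    """

    ref_id: str
    qry_id: str
    aligned_ref: str
    aligned_qry: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_qry):
            raise ValueError("aligned strings differ in length")

    @property
    def ref_coords(self) -> np.ndarray:
        coords = np.full(len(self.aligned_ref), -1, dtype=np.int64)
        pos = 0
        for j, c in enumerate(self.aligned_ref):
            if c != GAP:
                coords[j] = pos
                pos += 1
        return coords

    def project_to_reference(self) -> str:
        """Query residues in reference coordinates.

        Returns a string of the reference length: at each reference position
        the aligned query base, or '-' where the query is deleted.  Query
        insertions (columns where the reference is gapped) are dropped, which
        is the natural frame for pairwise-deletion distances and site calling.
        """
        out = []
        for r, q in zip(self.aligned_ref, self.aligned_qry):
            if r != GAP:
                out.append(q)
        return "".join(out)


def read_fasta(path) -> list:
    """Read a (multi-)FASTA file into a list of :class:`Sequence`.

    Residues are uppercased; record order is preserved.  Raises
    :class:`SequenceError` on an empty file or illegal residues.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return [Sequence(id=r.id, residues=str(r.seq)) for r in records]


def write_fasta(seqs: Iterable[Sequence], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_annotation(path) -> LocusAnnotation:
    """Read a locus annotation TSV: reference_id, locus, start, end."""
    intervals = []
    ref_ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ref_id, locus, start, end = line.split("\t")
            if locus == "locus":  # header
                continue
            ref_ids.add(ref_id)
            intervals.append((locus, int(start), int(end)))
    if len(ref_ids) != 1:
        raise ValueError(f"annotation must refer to exactly one reference, got {ref_ids}")
    return LocusAnnotation(reference_id=ref_ids.pop(), intervals=tuple(intervals))


def write_annotation(ann: LocusAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("reference_id\tlocus\tstart\tend\n")
        for locus, start, end in ann.intervals:
            fh.write(f"{ann.reference_id}\t{locus}\t{start}\t{end}\n")


def align_to_reference(
    ref: Sequence,
    qry: Sequence,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> PairwiseAlignment:
    """Global (Needleman–Wunsch, affine-gap) alignment of query to reference.

    Ties are broken deterministically: at equal score a match/mismatch column
    is preferred over a gap in the query, which is preferred over a gap in
    the reference.
    """
    aligned_ref, aligned_qry, score = gotoh_global(
        ref.residues,
        qry.residues,
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    return PairwiseAlignment(
        ref_id=ref.id,
        qry_id=qry.id,
        aligned_ref=aligned_ref,
        aligned_qry=aligned_qry,
        score=score,
    )


def partition_loci(
    aln: PairwiseAlignment, ann: LocusAnnotation
) -> dict:
    """Split the aligned query into per-locus (ungapped) subsequences.

    Query insertions between two reference positions are assigned to the
    locus of the left flanking position.  A locus whose interval is entirely
    deleted in the query yields an entry with residues ``""`` — callers must
    treat empty strings as a deleted-locus warning (``Sequence`` itself
    forbids empty residues, so the raw dict holds plain strings).
    """
    if ann.reference_id != aln.ref_id:
        raise ValueError(
            f"annotation is for {ann.reference_id!r}, alignment for {aln.ref_id!r}"
        )
    pieces = {name: [] for name in ann.loci}

    def locus_of(ref_pos: int):
        for name, start, end in ann.intervals:
            if start <= ref_pos < end:
                return name
        return None

    last_ref_pos = -1
    for r, q in zip(aln.aligned_ref, aln.aligned_qry):
        if r != GAP:
            last_ref_pos += 1
            target = locus_of(last_ref_pos)
        else:
            # insertion: assign to the locus of the left flanking ref position
            target = locus_of(last_ref_pos) if last_ref_pos >= 0 else None
        if target is not None and q != GAP:
            pieces[target].append(q)
    return {name: "".join(chars) for name, chars in pieces.items()}
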