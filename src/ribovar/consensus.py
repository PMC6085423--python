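"""Clone consensus building from forward and reverse Sanger reads.

Each cloned rDNA repeat is sequenced in both directions; standard practice
merges the two strands into a consensus, resolving every disagreement.  That
resolution step is exactly what can hide minority repeat variants, so the
policy used to resolve disagreements is explicit here:

``iupac``
    a disagreement becomes the IUPAC ambiguity code covering both bases;
``fwd_wins``
    the forward base is kept (the reverse read is used only for confirmation);
``reference_biased``
    whichever of the two bases matches a supplied reference/type-strain base
    is kept, falling back to the ambiguity code when neither matches — the
    conservative practice that pulls consensus sequences toward the type
    strain and hides variation the most.

The "original" (non-consensus) sequence of a clone is, by default, its
forward read.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from Bio.Seq import Seq

from .seqio import (
    GAP,
    AlignmentScoring,
    Sequence,
    align_to_reference,
    read_fasta,
)

POLICIES = ("iupac", "fwd_wins", "reference_biased")

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_IUPAC = {frozenset(v): k for k, v in _IUPAC_SETS.items()}


def iupac_union(a: str, b: str) -> str:
    """IUPAC code covering the union of the base sets of two codes."""
    return _SET_TO_IUPAC[frozenset(_IUPAC_SETS[a]) | frozenset(_IUPAC_SETS[b])]


def reverse_complement(s: Sequence) -> Sequence:
    """Watson–Crick reverse complement; IUPAC codes are complemented too."""
    return Sequence(id=s.id, residues=str(Seq(s.residues).reverse_complement()))


@dataclasses.dataclass
class CloneRecord:
    """One cloned repeat copy.

    ``rev`` is stored already reverse-complemented into forward orientation.
    ``discordant_sites`` are positions (consensus coordinates) where forward
    and reverse both had a base but disagreed.
    """

    clone_id: str
    fwd: Sequence
    rev: Sequence
    consensus: Optional[Sequence] = None
    discordant_sites: tuple = ()
    source_copy: Optional[int] = None  # simulation ground truth, if known

    def original(self, strand: str = "fwd") -> Sequence:
        if strand == "fwd":
            return self.fwd
        if strand == "rev":
            return self.rev
        raise ValueError(f"strand must be 'fwd' or 'rev', got {strand!r}")


def build_consensus(
    fwd: Sequence,
    rev: Sequence,
    policy: str = "iupac",
    ref: Optional[Sequence] = None,
    scoring: AlignmentScoring = AlignmentScoring(),
):
    """Merge forward and reverse reads into a consensus.

    Returns ``(consensus Sequence, discordant_sites)`` where discordant
    sites are indices into the consensus where the reads disagreed.  Columns
    where one read is gapped take the other read's base (an indel
    disagreement is not an ambiguity); such columns are not recorded as
    discordant.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if policy == "reference_biased" and ref is None:
        raise ValueError("policy 'reference_biased' requires a reference sequence")

    aln = align_to_reference(fwd, rev, scoring)

    ref_base_at = None
    if policy == "reference_biased":
        # anchor the forward read to the reference once; reference base per
        # forward-read position (None where fwd is inserted relative to ref)
        ref_aln = align_to_reference(ref, fwd, scoring)
        ref_base_at = {}
        fpos = -1
        for r, q in zip(ref_aln.aligned_ref, ref_aln.aligned_qry):
            if q != GAP:
                fpos += 1
                ref_base_at[fpos] = r if r != GAP else None

    out = []
    discordant = []
    fpos = -1
    for f, r in zip(aln.aligned_ref, aln.aligned_qry):
        if f != GAP:
            fpos += 1
        if f == GAP:
            out.append(r)
            continue
        if r == GAP or f == r:
            out.append(f)
            continue
        discordant.append(len(out))
        if policy == "fwd_wins":
            out.append(f)
        elif policy == "iupac":
            out.append(iupac_union(f, r))
        else:  # reference_biased
            rb = ref_base_at.get(fpos)
            if rb == f:
                out.append(f)
            elif rb == r:
                out.append(r)
            else:
                out.append(iupac_union(f, r))
    cons = Sequence(id=fwd.id, residues="".join(out))
    return cons, tuple(discordant)


def load_clone_pairs(
    fwd_path,
    rev_path,
    fwd_suffix: str = "_F",
    rev_suffix: str = "_R",
    rev_is_revcomp: bool = True,
) -> list:
    """Pair forward/reverse FASTA files into :class:`CloneRecord` objects.

    Clone identity is the record id with the strand suffix stripped.  When
    ``rev_is_revcomp`` the reverse file holds raw reverse-strand reads and is
    reverse-complemented into forward orientation on load.
    """
    def strip(seq_id: str, suffix: str) -> str:
        return seq_id[: -len(suffix)] if suffix and seq_id.endswith(suffix) else seq_id

    fwd = {strip(s.id, fwd_suffix): s for s in read_fasta(fwd_path)}
    rev = {strip(s.id, rev_suffix): s for s in read_fasta(rev_path)}
    missing = set(fwd) ^ set(rev)
    if missing:
        raise ValueError(f"unpaired clone ids: {sorted(missing)[:5]} ...")
    records = []
    for clone_id in fwd:
        r = rev[clone_id]
        if rev_is_revcomp:
            r = reverse_complement(r)
        records.append(
            CloneRecord(clone_id=clone_id, fwd=fwd[clone_id], rev=r)
        )
    records.sort(key=lambda c: c.clone_id)
    return records


def add_consensus(
    clones: list,
    policy: str = "iupac",
    ref: Optional[Sequence] = None,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> list:
    """Fill the ``consensus`` field of every clone record (in place)."""
    for c in clones:
        cons, disc = build_consensus(c.fwd, c.rev, policy=policy, ref=ref, scoring=scoring)
        c.consensus = Sequence(id=c.clone_id, residues=cons.residues)
        c.discordant_sites = disc
    return clones
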