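"""SNP frequency spectrum of cloned repeat copies against two type strains.

Every reference-anchored site where clones vary, or where the two type
strains differ, is classified by which type-strain allele(s) the clones'
variant allele departs from:

* ``vs_A_only`` — differs from type strain A but matches B;
* ``vs_B_only`` — differs from B but matches A;
* ``vs_both``   — differs from both;
* ``none``      — all clones match both type strains (no record emitted).

The variant allele of a site is the most frequent clone allele that differs
from at least one type-strain allele, and its frequency is the fraction of
called clones carrying it.  A fixed difference (all clones carry a base the
type strain lacks) therefore scores a frequency of 1.0 — the high-frequency
class — while a minority repeat variant scores the fraction of clones
carrying it (the 2–4% class in default simulations).  The frequency classes
are ``high`` (>= high_cut), ``low`` (<= low_cut) and ``intermediate``;
intermediate records are reported, not suppressed, because their absence is
an empirical finding about the data, not a rule.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .distances import N_CODES, anchored_codes, encode
from .seqio import AlignmentScoring, LocusAnnotation, Sequence, align_to_reference

CATEGORIES = ("vs_A_only", "vs_B_only", "vs_both", "none")
_BASES = "ACGT"


def call_site_alleles(clone_loci, ref_pos: int) -> dict:
    """Allele counts at one anchored site; gap/N/ambiguity are uncalled.

    ``clone_loci`` is a list of reference-anchored sequences (strings or
    :class:`Sequence`) or a pre-encoded uint8 matrix.
    """
    if isinstance(clone_loci, np.ndarray):
        col = clone_loci[:, ref_pos]
    else:
        rows = [s.residues if isinstance(s, Sequence) else s for s in clone_loci]
        col = np.array([encode(r)[ref_pos] for r in rows], dtype=np.uint8)
    counts = {}
    for b in range(4):
        c = int(np.sum(col == b))
        if c:
            counts[_BASES[b]] = c
    return counts


def classify_site(counts: dict, allele_A: str, allele_B: str):
    """Category and frequency of the variant allele at one site.

    The variant allele is the most frequent clone allele differing from
    ``allele_A`` or ``allele_B`` (ties broken by count then alphabet).
    Returns ``("none", 0.0)`` when every called clone matches both type
    strains.
    """
    if not counts:
        raise ValueError("empty allele counts")
    total = sum(counts.values())
    # a base equal to both type alleles is not a variant
    variants = {b: c for b, c in counts.items() if not (b == allele_A and b == allele_B)}
    if not variants:
        return "none", 0.0
    variant_allele = max(variants, key=lambda b: (variants[b], b))
    return (
        _category(variant_allele, allele_A, allele_B),
        variants[variant_allele] / total,
    )


def _category(allele: str, allele_A: str, allele_B: str) -> str:
    diff_a = allele != allele_A
    diff_b = allele != allele_B
    if diff_a and diff_b:
        return "vs_both"
    if diff_a:
        return "vs_A_only"
    if diff_b:
        return "vs_B_only"
    return "none"


def frequency_class(freq: float, high_cut: float = 0.5, low_cut: float = 0.1) -> str:
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency {freq} outside [0, 1]")
    if freq >= high_cut:
        return "high"
    if freq <= low_cut:
        return "low"
    return "intermediate"


@dataclasses.dataclass
class SpectrumReport:
    """Per-site SNP records plus per-locus tallies.

    ``records`` has one row per (site, variant allele); multi-allelic sites
    are decomposed into one record per non-reference allele, the most
    frequent one flagged ``primary``.  ``typestrain_diffs`` maps locus ->
    list of reference positions where the two type strains differ
    (independent of the clones; the "stripes" of a spectrum plot).
    """

    records: pd.DataFrame
    typestrain_diffs: dict
    n_clones: int
    high_cut: float
    low_cut: float

    def summary(self) -> dict:
        """Per-locus counts: type-strain differences and high/low SNP tallies
        versus each type strain (``vs_A`` = differs from A, i.e. categories
        vs_A_only + vs_both; ``shared`` = vs_both)."""
        out = {}
        prim = self.records[self.records["primary"]]
        for locus, stripes in self.typestrain_diffs.items():
            sub = prim[prim["locus"] == locus]
            def count(fc, cats):
                return int(((sub["freq_class"] == fc) & sub["category"].isin(cats)).sum())
            out[locus] = {
                "typestrain_diffs": len(stripes),
                "high_vs_A": count("high", ("vs_A_only", "vs_both")),
                "low_vs_A": count("low", ("vs_A_only", "vs_both")),
                "high_vs_B": count("high", ("vs_B_only", "vs_both")),
                "low_vs_B": count("low", ("vs_B_only", "vs_both")),
                "shared_high": count("high", ("vs_both",)),
                "shared_low": count("low", ("vs_both",)),
                "intermediate": int((sub["freq_class"] == "intermediate").sum()),
            }
        return out

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def build_spectrum(
    clone_seqs,
    refA: Sequence,
    refB: Sequence,
    ann: LocusAnnotation,
    clone_ids: Optional[list] = None,
    high_cut: float = 0.5,
    low_cut: float = 0.1,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> SpectrumReport:
    """Scan every annotated site and build the frequency spectrum.

    ``refA`` is the coordinate anchor (the focal species' type strain);
    ``refB`` is lifted onto refA's coordinates by pairwise alignment.
    ``clone_seqs`` is a list of :class:`Sequence` (anchored here) or a
    pre-anchored uint8 code matrix of width ``len(refA)``.
    """
    if set(ann.loci) != {"ITS1", "5.8S", "ITS2", "LSU"}:
        raise ValueError("annotation must cover all four loci")
    if ann.reference_id != refA.id:
        raise ValueError("annotation must be on refA coordinates")

    if isinstance(clone_seqs, np.ndarray):
        codes = clone_seqs
    else:
        clone_seqs = list(clone_seqs)
        if clone_ids is None:
            clone_ids = [s.id for s in clone_seqs]
        codes = anchored_codes(refA, clone_seqs, scoring)
    n_clones = codes.shape[0]
    if clone_ids is None:
        clone_ids = [f"clone{i}" for i in range(n_clones)]

    codeA = encode(refA.residues)
    b_anch = align_to_reference(refA, refB, scoring).project_to_reference()
    codeB = encode(b_anch)

    rows = []
    typestrain_diffs = {locus: [] for locus in ann.loci}
    for locus, start, end in ann.intervals:
        block = codes[:, start:end]
        # candidate sites: any called clone base differing from refA, or a
        # type-strain difference
        valid = block < N_CODES
        diff_a = valid & (block != codeA[start:end][None, :])
        ab_diff = (codeA[start:end] != codeB[start:end]) & \
                  (codeA[start:end] < N_CODES) & (codeB[start:end] < N_CODES)
        candidates = np.flatnonzero(diff_a.any(axis=0) | ab_diff)
        for off in candidates:
            pos = start + int(off)
            if codeA[pos] >= N_CODES or codeB[pos] >= N_CODES:
                continue  # type allele not callable at this site
            allele_A = _BASES[codeA[pos]]
            allele_B = _BASES[codeB[pos]]
            if ab_diff[off]:
                typestrain_diffs[locus].append(pos)
            counts = call_site_alleles(codes, pos)
            if not counts:
                continue
            total = sum(counts.values())
            variant_alleles = {
                b: c for b, c in counts.items()
                if not (b == allele_A and b == allele_B)
            }
            if not variant_alleles:
                continue
            best = max(variant_alleles, key=lambda b: (variant_alleles[b], b))
            for allele, c in sorted(variant_alleles.items()):
                freq = c / total
                rows.append({
                    "locus": locus,
                    "ref_pos": pos,
                    "allele_A": allele_A,
                    "allele_B": allele_B,
                    "variant_allele": allele,
                    "n_called": total,
                    "freq": freq,
                    "category": _category(allele, allele_A, allele_B),
                    "freq_class": frequency_class(freq, high_cut, low_cut),
                    "primary": allele == best,
                })
    records = pd.DataFrame(
        rows,
        columns=["locus", "ref_pos", "allele_A", "allele_B", "variant_allele",
                 "n_called", "freq", "category", "freq_class", "primary"],
    )
    return SpectrumReport(
        records=records,
        typestrain_diffs=typestrain_diffs,
        n_clones=n_clones,
        high_cut=high_cut,
        low_cut=low_cut,
    )
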