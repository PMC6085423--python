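"""Synthetic rDNA tandem-repeat arrays with the variant structure of a
recently diverged yeast species pair.

The generator emulates the outcome of concerted evolution on a ~1.1 kb
ITS1–5.8S–ITS2–LSU amplicon present in >100 tandem copies per genome:

* two species-defining canonical sequences (type strains A and B) separated
  by a handful of fixed differences per locus;
* within the focal genome (species A), a set of low-frequency repeat
  variants, each carried by ~2% of copies (exact carrier counts by default,
  so planted frequencies are sharp ground truth);
* no intermediate-frequency variants — the bimodal spectrum the clone data
  show;
* a Sanger-style reference obtained by majority call over all copies, with
  minority sites above a detection floor recorded as "secondary peaks";
* a clone library: copies sampled uniformly with replacement, each
  "sequenced" in both directions with independent per-base errors.

Variant positions are drawn independently per locus and are disjoint
between the fixed and low-frequency classes, so the four loci vary
independently by construction.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .consensus import CloneRecord, reverse_complement
from .seqio import LocusAnnotation, Sequence

_BASES = np.array(list("ACGT"))
GAP_CODE = 4  # matches distances.encode: non-ACGT codes are excluded sites

_DEF_LENGTHS = {"ITS1": 180, "5.8S": 160, "ITS2": 230, "LSU": 570}
_DEF_INTERSPECIES = {"ITS1": 5, "5.8S": 0, "ITS2": 3, "LSU": 5}
_DEF_LOWFREQ = {"ITS1": 8, "5.8S": 6, "ITS2": 5, "LSU": 22}
_DEF_INDELS = {"ITS1": 0, "5.8S": 0, "ITS2": 0, "LSU": 0}


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the repeat-array simulation.

    Defaults reproduce the reported structure of the real clone library:
    120 tandem copies, 85 sequenced clones, per-site carrier fraction 2%
    for low-frequency variants, fixed interspecies differences of
    5/0/3/5 and low-frequency site counts of 8/6/5/22 across
    ITS1/5.8S/ITS2/LSU.
    """

    seed: int
    locus_lengths: dict = dataclasses.field(default_factory=lambda: dict(_DEF_LENGTHS))
    n_copies: int = 120
    n_clones: int = 85
    interspecies_diffs: dict = dataclasses.field(default_factory=lambda: dict(_DEF_INTERSPECIES))
    low_freq_sites: dict = dataclasses.field(default_factory=lambda: dict(_DEF_LOWFREQ))
    low_freq: float = 0.02
    bernoulli_carriers: bool = False
    low_freq_indels: dict = dataclasses.field(default_factory=lambda: dict(_DEF_INDELS))
    read_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if set(self.locus_lengths) != set(_DEF_LENGTHS):
            raise ValueError("locus_lengths must name ITS1, 5.8S, ITS2, LSU")
        if not 0.0 < self.low_freq < 0.5:
            raise ValueError("low_freq must lie in (0, 0.5)")
        if self.n_copies < 1 or self.n_clones < 1:
            raise ValueError("n_copies and n_clones must be positive")
        if not 0.0 <= self.read_error_rate < 1.0:
            raise ValueError("read_error_rate must lie in [0, 1)")
        for locus, length in self.locus_lengths.items():
            demand = (self.interspecies_diffs.get(locus, 0)
                      + self.low_freq_sites.get(locus, 0)
                      + self.low_freq_indels.get(locus, 0))
            if any(v < 0 for v in (demand, length)):
                raise ValueError("counts must be non-negative")
            if length < demand:
                raise ValueError(
                    f"locus {locus}: length {length} cannot host {demand} variant sites"
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


def make_annotation(cfg: SimConfig, reference_id: str = "typeA") -> LocusAnnotation:
    intervals = []
    pos = 0
    for locus in ("ITS1", "5.8S", "ITS2", "LSU"):
        length = cfg.locus_lengths[locus]
        intervals.append((locus, pos, pos + length))
        pos += length
    return LocusAnnotation(reference_id=reference_id, intervals=tuple(intervals))


@dataclasses.dataclass
class RepeatArraySim:
    """A simulated genome: C tandem copies plus ground truth.

    ``copy_codes`` is the (C, L) uint8 matrix of all copies anchored to the
    species-A canonical coordinates (deleted bases, when indel variants are
    enabled, carry the excluded code).  ``truth`` has one row per planted
    variant: locus, ref_pos, ref_allele, variant_allele, carrier copy ids
    and class (interspecies_fixed / low_freq / low_freq_indel).
    """

    config: SimConfig
    annotation: LocusAnnotation
    species_A_canonical: Sequence
    species_B_canonical: Sequence
    copy_codes: np.ndarray
    truth: pd.DataFrame
    rng: np.random.Generator

    @property
    def n_copies(self) -> int:
        return self.copy_codes.shape[0]

    def copy_sequences(self) -> list:
        out = []
        for i, row in enumerate(self.copy_codes):
            residues = "".join(_BASES[b] for b in row if b != GAP_CODE)
            out.append(Sequence(id=f"copy{i:03d}", residues=residues))
        return out


def simulate_repeat_array(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> RepeatArraySim:
    """Generate canonical species sequences, the copy array and ground truth.

    All randomness flows from a single generator seeded with ``cfg.seed``
    (subsequent clone sampling continues the same stream, so a fixed seed
    reproduces the whole run byte for byte).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ann = make_annotation(cfg)
    total = sum(cfg.locus_lengths.values())
    canonical = rng.integers(0, 4, size=total).astype(np.uint8)

    b_codes = canonical.copy()
    copies = np.tile(canonical, (cfg.n_copies, 1))
    truth_rows = []
    for locus, start, end in ann.intervals:
        n_fixed = cfg.interspecies_diffs.get(locus, 0)
        n_low = cfg.low_freq_sites.get(locus, 0)
        n_indel = cfg.low_freq_indels.get(locus, 0)
        positions = rng.choice(end - start, size=n_fixed + n_low + n_indel, replace=False) + start
        fixed_pos = positions[:n_fixed]
        low_pos = positions[n_fixed:n_fixed + n_low]
        indel_pos = positions[n_fixed + n_low:]

        for pos in sorted(fixed_pos):
            alt = (b_codes[pos] + rng.integers(1, 4)) % 4
            b_codes[pos] = alt
            truth_rows.append({
                "locus": locus, "ref_pos": int(pos),
                "ref_allele": str(_BASES[canonical[pos]]),
                "variant_allele": str(_BASES[alt]),
                "carriers": tuple(),  # carried by species B, not by A's copies
                "class": "interspecies_fixed",
            })
        for kind, pos_set in (("low_freq", sorted(low_pos)), ("low_freq_indel", sorted(indel_pos))):
            for pos in pos_set:
                if cfg.bernoulli_carriers:
                    mask = rng.random(cfg.n_copies) < cfg.low_freq
                    carriers = np.flatnonzero(mask)
                else:
                    k = int(round(cfg.low_freq * cfg.n_copies))
                    carriers = rng.choice(cfg.n_copies, size=k, replace=False)
                carriers = np.sort(carriers)
                if kind == "low_freq":
                    alt = (canonical[pos] + rng.integers(1, 4)) % 4
                    copies[carriers, pos] = alt
                    allele = str(_BASES[alt])
                else:
                    copies[carriers, pos] = GAP_CODE  # single-base deletion
                    allele = "-"
                truth_rows.append({
                    "locus": locus, "ref_pos": int(pos),
                    "ref_allele": str(_BASES[canonical[pos]]),
                    "variant_allele": allele,
                    "carriers": tuple(int(c) for c in carriers),
                    "class": kind,
                })

    truth = pd.DataFrame(
        truth_rows,
        columns=["locus", "ref_pos", "ref_allele", "variant_allele", "carriers", "class"],
    ).sort_values(["locus", "ref_pos"], kind="stable").reset_index(drop=True)
    to_str = lambda codes: "".join(_BASES[b] for b in codes)
    return RepeatArraySim(
        config=cfg,
        annotation=ann,
        species_A_canonical=Sequence(id="typeA", residues=to_str(canonical)),
        species_B_canonical=Sequence(id="typeB", residues=to_str(b_codes)),
        copy_codes=copies,
        truth=truth,
        rng=rng,
    )


def simulate_sanger_reference(
    sim: RepeatArraySim, secondary_peak_floor: float = 0.1
):
    """Majority-call Sanger-style reference over all copies.

    Returns ``(reference Sequence, secondary_peak_sites)``: sites where the
    minority-base fraction reaches the detection floor are what a
    chromatogram would show as secondary peaks.  With 2% carriers and a 10%
    floor, low-frequency variants stay hidden and the reference equals the
    species-A canonical.
    """
    C, L = sim.copy_codes.shape
    counts = np.zeros((4, L), dtype=np.int64)
    for b in range(4):
        counts[b] = (sim.copy_codes == b).sum(axis=0)
    called = counts.sum(axis=0)
    # majority base; ties resolved toward the lowest base code (deterministic)
    maj = counts.argmax(axis=0).astype(np.uint8)
    minority_frac = np.where(called > 0, 1.0 - counts.max(axis=0) / np.maximum(called, 1), 0.0)
    secondary = [int(i) for i in np.flatnonzero(minority_frac >= secondary_peak_floor)]
    residues = "".join(str(_BASES[b]) for b in maj)
    return Sequence(id="reference", residues=residues), secondary


def simulate_clone_reads(
    sim: RepeatArraySim,
    cfg: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Sample the clone library: n_clones copies, read in both directions.

    Forward and reverse reads are the sampled copy with independent
    per-base substitution errors at ``read_error_rate``; the reverse read
    is stored in forward orientation (see :class:`CloneRecord`).  The
    ground-truth copy index is retained on each record.
    """
    cfg = cfg if cfg is not None else sim.config
    rng = rng if rng is not None else sim.rng
    picks = rng.integers(0, sim.n_copies, size=cfg.n_clones)
    clones = []
    for i, copy_idx in enumerate(picks):
        codes = sim.copy_codes[copy_idx]
        fwd = _with_errors(codes, cfg.read_error_rate, rng)
        rev = _with_errors(codes, cfg.read_error_rate, rng)
        clone_id = f"clone{i:03d}"
        clones.append(CloneRecord(
            clone_id=clone_id,
            fwd=Sequence(id=f"{clone_id}_F", residues=_decode(fwd)),
            rev=Sequence(id=f"{clone_id}_R", residues=_decode(rev)),
            source_copy=int(copy_idx),
        ))
    return clones


def _with_errors(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    if rate > 0:
        present = out != GAP_CODE
        hits = np.flatnonzero(present & (rng.random(out.shape[0]) < rate))
        if hits.size:
            out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(str(_BASES[b]) for b in codes if b != GAP_CODE)


def end_to_end_truth_check(sim: RepeatArraySim, report, clones) -> tuple:
    """Compare a spectrum report against the planted ground truth.

    Returns ``(per_variant DataFrame, summary dict)``.  A low-frequency
    variant none of whose carrier copies were sampled into the clone
    library is counted ``unsampled`` and excluded from the recall
    denominator.  Precision is the fraction of primary spectrum records
    that sit at a planted position (read errors create spurious singleton
    records, so precision < 1 is possible at nonzero error rates).
    """
    picks = [c.source_copy for c in clones]
    if any(p is None for p in picks):
        raise ValueError("clones lack ground-truth copy ids")
    n_clones = len(picks)
    primary = report.records[report.records["primary"]]
    rec_by_pos = {(r.locus, r.ref_pos): r for r in primary.itertuples()}

    from .spectrum import frequency_class

    rows = []
    for t in sim.truth.to_dict("records"):
        cls = t["class"]
        carriers = set(t["carriers"])
        if cls == "interspecies_fixed":
            # every species-A copy differs from species B here
            expected_n = n_clones
            expected_category = "vs_B_only"
        else:
            expected_n = sum(1 for p in picks if p in carriers)
            expected_category = "vs_both"
        sampled = expected_n > 0
        rec = rec_by_pos.get((t["locus"], t["ref_pos"]))
        recovered = rec is not None
        category_ok = recovered and rec.category == expected_category
        freq_ok = False
        class_ok = False
        if recovered and rec.n_called > 0:
            expected_freq = min(1.0, expected_n / rec.n_called)
            freq_ok = abs(rec.freq - expected_freq) < 1e-12
            class_ok = rec.freq_class == frequency_class(
                expected_freq, report.high_cut, report.low_cut
            )
        rows.append({
            "locus": t["locus"], "ref_pos": t["ref_pos"], "class": cls,
            "sampled": sampled, "recovered": recovered,
            "category_ok": category_ok, "freq_ok": freq_ok, "class_ok": class_ok,
            "expected_carrier_clones": expected_n,
            "observed_freq": rec.freq if recovered else np.nan,
        })
    per_variant = pd.DataFrame(rows)
    # indel variants are invisible to the substitution spectrum (gaps are
    # uncalled sites); they are reported per-variant but excluded from recall
    subs = per_variant[per_variant["class"] != "low_freq_indel"]
    sampled = subs[subs["sampled"]]
    planted_pos = set(zip(sim.truth["locus"], sim.truth["ref_pos"]))
    n_primary = len(primary)
    n_at_planted = sum(1 for key in rec_by_pos if key in planted_pos)
    summary = {
        "n_variants": len(per_variant),
        "n_sampled": int(len(sampled)),
        "n_unsampled": int((~subs["sampled"]).sum()),
        "recall": float((sampled["recovered"] & sampled["category_ok"]).mean())
        if len(sampled) else float("nan"),
        "precision": n_at_planted / n_primary if n_primary else float("nan"),
    }
    return per_variant, summary
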