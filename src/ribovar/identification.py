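"""Species attribution of single reads and alpha-diversity overestimation.

In a metabarcoding experiment each read is identified on its own, so
intragenomic repeat variants can push reads of one strain beyond the
species-level distance threshold of its own species.  Published thresholds:
1% for LSU D1/D2, 1.59% for the ITS regions, and an optional 0.69% limit
for the whole-ITS barcode.  Reads are attributed by comparing their distance
to each of two candidate type strains against the locus threshold; the
spurious-OTU count formalises the diversity overestimate as the number of
single-linkage clusters at the threshold minus one (every read derives from
a single strain, so every extra cluster is spurious).
"""

from __future__ import annotations

import dataclasses
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .distances import DistanceMatrix

CALLS = ("A", "B", "ambiguous_both", "novel_neither")


@dataclasses.dataclass(frozen=True)
class ThresholdSet:
    """Per-locus species-identification distance thresholds (fractions).

    5.8S has no dedicated published threshold and inherits the ITS value.
    """

    LSU: float = 0.01
    ITS1: float = 0.0159
    ITS2: float = 0.0159
    s58: float = 0.0159  # 5.8S
    whole_its: float = 0.0069

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"threshold {f.name}={v} outside (0, 1)")

    def for_locus(self, locus: str) -> float:
        key = {"5.8S": "s58", "whole_ITS": "whole_its"}.get(locus, locus)
        return getattr(self, key)


def attribute_read(d_A: float, d_B: float, t: float) -> str:
    """Threshold attribution of one read given distances to two type strains."""
    if d_A < 0 or d_B < 0:
        raise ValueError("distances must be non-negative")
    in_a = d_A <= t
    in_b = d_B <= t
    if in_a and in_b:
        return "ambiguous_both"
    if in_a:
        return "A"
    if in_b:
        return "B"
    return "novel_neither"


def attribute_read_nearest(d_A: float, d_B: float) -> str:
    """Nearest-type-strain attribution (no threshold; ties are ambiguous)."""
    if d_A < d_B:
        return "A"
    if d_B < d_A:
        return "B"
    return "ambiguous_both"


def threshold_exceedance(dm: DistanceMatrix, t: float) -> float:
    """Fraction of pairwise (upper-triangle) distances strictly above t."""
    d = dm.condensed
    if d.size == 0:
        raise ValueError("empty distance matrix")
    return float(np.mean(d[~np.isnan(d)] > t))


def spurious_otu_count(dm: DistanceMatrix, t: float) -> int:
    """Single-linkage OTU clusters at threshold t, minus one.

    All member reads derive from one strain, so any cluster beyond the first
    is a spurious taxon.
    """
    n = len(dm)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return 0
    Z = linkage(dm.condensed, method="single")
    labels = fcluster(Z, t=t, criterion="distance")
    return int(len(np.unique(labels)) - 1)


def diversity_overestimate(
    reads_by_locus: dict,
    thresholds: ThresholdSet = ThresholdSet(),
    mode: str = "threshold",
) -> pd.DataFrame:
    """Per-locus attribution fractions and spurious-OTU counts.

    ``reads_by_locus`` maps locus -> dict with keys ``d_A``, ``d_B`` (arrays
    of each read's distance to type strains A and B) and ``dm`` (the
    read-by-read :class:`DistanceMatrix` for OTU clustering).  ``mode`` is
    ``threshold`` or ``nearest``.
    """
    if not reads_by_locus:
        raise ValueError("no reads supplied")
    rows = []
    for locus, data in reads_by_locus.items():
        d_A = np.asarray(data["d_A"], dtype=float)
        d_B = np.asarray(data["d_B"], dtype=float)
        if d_A.size == 0:
            raise ValueError(f"no reads for locus {locus}")
        t = thresholds.for_locus(locus)
        if mode == "threshold":
            calls = [attribute_read(a, b, t) for a, b in zip(d_A, d_B)]
        elif mode == "nearest":
            calls = [attribute_read_nearest(a, b) for a, b in zip(d_A, d_B)]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        n = len(calls)
        frac = {c: calls.count(c) / n for c in CALLS}
        dm = data.get("dm")
        spurious = spurious_otu_count(dm, t) if dm is not None else np.nan
        rows.append({
            "locus": locus,
            "threshold": t,
            "n_reads": n,
            "pct_A": 100 * frac["A"],
            "pct_B": 100 * frac["B"],
            "pct_ambiguous": 100 * frac["ambiguous_both"],
            "pct_novel": 100 * frac["novel_neither"],
            "spurious_otus": spurious,
        })
    return pd.DataFrame(rows)


def distance_histogram(dm: DistanceMatrix, bins: int = 20) -> pd.DataFrame:
    """Histogram plus cumulative curve of pairwise distances.

    Returns a frame with bin_left, bin_right, count and the cumulative
    fraction of distances at or below bin_right (monotone to 1.0).
    """
    d = dm.condensed
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("empty distance matrix")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    counts, edges = np.histogram(d, bins=bins)
    cum = np.cumsum(counts) / counts.sum()
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
        "cumulative": cum,
    })
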