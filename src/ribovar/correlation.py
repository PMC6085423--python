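"""Independence of variation among the four rDNA loci.

If repeat variants arise independently in ITS1, 5.8S, ITS2 and LSU, then a
clone unusually distant from the reference at one locus should be no more
likely to be distant at another.  This is tested by correlating, across
clones, the per-locus distances to the reference (computed separately for
consensus and original sequences), mirroring a 4x4 correlation table with
Pearson's r in the lower triangle and the two-sided p-value in the upper.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy import stats

from .distances import anchored_codes, distance_set, encode
from .seqio import AlignmentScoring, LocusAnnotation, Sequence

LOCI_ORDER = ("ITS1", "5.8S", "ITS2", "LSU")


class DegenerateVectorError(ValueError):
    """Zero-variance input to a correlation."""


def pearson_r(x, y):
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateVectorError("degenerate vector (zero variance)")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def locus_distance_profiles(
    reference: Sequence,
    clones,
    ann: LocusAnnotation,
    source: str = "consensus",
    metric: str = "p",
    original_strand: str = "fwd",
    scoring: AlignmentScoring = AlignmentScoring(),
) -> pd.DataFrame:
    """Per-clone distance-to-reference for each locus (one row per clone).

    ``source`` selects consensus or original (single-strand) sequences.
    Clones lacking comparable sites at any locus are dropped listwise with a
    warning, since Pearson correlation needs complete profiles.
    """
    clones = list(clones)
    if source == "consensus":
        seqs = [c.consensus for c in clones]
        if any(s is None for s in seqs):
            raise ValueError("clones lack consensus sequences")
    elif source == "original":
        seqs = [c.original(original_strand) for c in clones]
    else:
        raise ValueError(f"source must be 'consensus' or 'original', got {source!r}")
    codes = anchored_codes(reference, seqs, scoring)
    ref_row = encode(reference.residues)[None, :]
    n = len(clones)
    data = {}
    for locus, start, end in ann.intervals:
        block = np.vstack([ref_row[:, start:end], codes[:, start:end]])
        pairs = [(0, k + 1) for k in range(n)]
        data[locus] = distance_set(block, pairs, metric=metric)
    df = pd.DataFrame(data, index=[c.clone_id for c in clones])
    complete = df.notna().all(axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} clone(s) with incomparable loci")
        df = df[complete]
    return df


def correlation_table(profiles: pd.DataFrame, loci=LOCI_ORDER, on_degenerate: str = "raise"):
    """4x4 locus-by-locus table: r below the diagonal, p above.

    Returns ``(table, pairs)`` where ``pairs`` is a tidy frame of the six
    locus pairs with r, raw p, and Bonferroni-adjusted p (the adjustment is
    reported alongside, never substituted for the raw values).  A locus with
    zero variance across clones raises :class:`DegenerateVectorError` by
    default; with ``on_degenerate="nan"`` the affected pairs are reported as
    NaN instead (small clone sets routinely have invariant loci).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 complete clone profiles")
    table = pd.DataFrame("", index=list(loci), columns=list(loci), dtype=object)
    rows = []
    m = len(loci) * (len(loci) - 1) // 2
    for i, la in enumerate(loci):
        for j, lb in enumerate(loci):
            if i <= j:
                continue
            try:
                r, p = pearson_r(profiles[la].to_numpy(), profiles[lb].to_numpy())
            except DegenerateVectorError:
                if on_degenerate != "nan":
                    raise
                warnings.warn(f"degenerate locus pair {la}/{lb}: r reported as NaN")
                r = p = float("nan")
            table.loc[la, lb] = round(r, 4)     # lower triangle: r
            table.loc[lb, la] = round(p, 4)     # upper triangle: p
            rows.append({
                "locus_1": la, "locus_2": lb, "r": r, "p": p,
                "p_bonferroni": min(1.0, p * m) if p == p else float("nan"),
            })
    return table, pd.DataFrame(rows)
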