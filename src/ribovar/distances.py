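"""Per-site substitution distances between rDNA repeat copies.

Distances are expressed as substitutions per site.  Three estimators:

* ``p`` — raw proportion of differing sites;
* ``tn93`` — the Tamura–Nei (1993) closed-form correction, which separates
  the two transition classes (A<->G, C<->T) from transversions and allows
  unequal base frequencies;
* ``tn93_mcl`` — a composite variant of TN93 in which base frequencies are
  estimated once from the counts pooled over every compared pair, and each
  pair's distance is then evaluated with the pooled frequencies and that
  pair's own transition/transversion proportions.  This is the estimator
  used throughout the pipeline's figure-style summaries.

Sites are compared under pairwise deletion: any site with a gap, N or IUPAC
ambiguity code in either member of a pair is excluded from that pair only.
A pair driven past the TN93 logarithm's domain is flagged saturated (NaN)
and excluded from means with a warning, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .seqio import AlignmentScoring, LocusAnnotation, Sequence, align_to_reference

SETTINGS = (
    "ref_vs_consensus",
    "ref_vs_original",
    "pairwise_consensus",
    "pairwise_original",
)

# base codes: A=0 C=1 G=2 T=3; anything else (gap, N, IUPAC) = 4, excluded
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
N_CODES = 4


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_matrix(seqs: Iterable[str]) -> np.ndarray:
    rows = [encode(s) for s in seqs]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not anchored to common coordinates: lengths {sorted(lengths)}")
    return np.vstack(rows)


class NoComparableSitesError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SitePairCounts:
    """Substitution-class counts for one compared pair (or a pooled set).

    L compared sites; P1 purine transitions (A<->G); P2 pyrimidine
    transitions (C<->T); Q transversions; base_freqs the empirical
    frequencies of A, C, G, T over both members' compared sites.
    """

    L: int
    P1: int
    P2: int
    Q: int
    base_freqs: tuple

    def __post_init__(self) -> None:
        if self.P1 + self.P2 + self.Q > self.L:
            raise ValueError("substitution counts exceed compared sites")


def pair_counts(a, b) -> SitePairCounts:
    """Count substitution classes between two anchored sequences.

    ``a``/``b`` may be strings or pre-encoded uint8 arrays of equal length.
    Pairwise deletion: sites where either member is gap/N/ambiguous are
    excluded.  Raises :class:`NoComparableSitesError` when nothing remains.
    """
    ca = encode(a) if isinstance(a, str) else a
    cb = encode(b) if isinstance(b, str) else b
    if ca.shape != cb.shape:
        raise ValueError("sequences are not anchored to common coordinates")
    valid = (ca < N_CODES) & (cb < N_CODES)
    L = int(valid.sum())
    if L == 0:
        raise NoComparableSitesError("no comparable sites in pair")
    ca = ca[valid]
    cb = cb[valid]
    diff = ca != cb
    pair_min = np.minimum(ca, cb)
    pair_max = np.maximum(ca, cb)
    p1 = int(np.sum(diff & (pair_min == 0) & (pair_max == 2)))  # A<->G
    p2 = int(np.sum(diff & (pair_min == 1) & (pair_max == 3)))  # C<->T
    q = int(diff.sum()) - p1 - p2
    counts = np.bincount(ca, minlength=4) + np.bincount(cb, minlength=4)
    freqs = tuple(counts / counts.sum())
    return SitePairCounts(L=L, P1=p1, P2=p2, Q=q, base_freqs=freqs)


def p_distance(c: SitePairCounts) -> float:
    """Proportion of differing sites."""
    return (c.P1 + c.P2 + c.Q) / c.L


def tn93_distance(c: SitePairCounts, base_freqs: Optional[tuple] = None) -> float:
    """Tamura–Nei (1993) distance from substitution-class counts.

    ``base_freqs`` overrides the pair's own frequencies (used by the pooled
    composite estimator).  Returns NaN when the pair is saturated (any
    logarithm argument non-positive).
    """
    pi = np.asarray(base_freqs if base_freqs is not None else c.base_freqs, dtype=float)
    pA, pC, pG, pT = pi
    gR = pA + pG
    gY = pC + pT
    P1 = c.P1 / c.L
    P2 = c.P2 / c.L
    Q = c.Q / c.L

    k1 = 2.0 * pA * pG / gR if gR > 0 else 0.0
    k2 = 2.0 * pC * pT / gY if gY > 0 else 0.0
    k3 = 2.0 * (gR * gY - (pA * pG * gY / gR if gR > 0 else 0.0)
                - (pC * pT * gR / gY if gY > 0 else 0.0))

    d = 0.0
    if k1 > 0:
        w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
        if w1 <= 0:
            return float("nan")
        d -= k1 * np.log(w1)
    elif P1 > 0:
        return float("nan")
    if k2 > 0:
        w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
        if w2 <= 0:
            return float("nan")
        d -= k2 * np.log(w2)
    elif P2 > 0:
        return float("nan")
    if gR > 0 and gY > 0:
        w3 = 1.0 - Q / (2.0 * gR * gY)
        if w3 <= 0:
            return float("nan")
        d -= k3 * np.log(w3)
    elif Q > 0:
        return float("nan")
    return float(d)


def _pairwise_class_counts(codes: np.ndarray):
    """Vectorised pairwise L/P1/P2/Q matrices for n anchored sequences.

    Uses one-hot matmuls: N_ab[i, j] = number of sites where sequence i has
    base a and sequence j has base b (over mutually valid sites).
    """
    onehot = [(codes == b).astype(np.float64) for b in range(N_CODES)]
    N = {}
    for a in range(N_CODES):
        for b in range(N_CODES):
            N[a, b] = onehot[a] @ onehot[b].T
    valid = (codes < N_CODES).astype(np.float64)
    L = valid @ valid.T
    P1 = N[0, 2] + N[2, 0]
    P2 = N[1, 3] + N[3, 1]
    Q = (N[0, 1] + N[1, 0] + N[0, 3] + N[3, 0]
         + N[2, 1] + N[1, 2] + N[2, 3] + N[3, 2])
    return L, P1, P2, Q


def pooled_base_freqs(codes: np.ndarray) -> tuple:
    """Base frequencies pooled over all valid sites of all sequences."""
    flat = codes[codes < N_CODES]
    counts = np.bincount(flat, minlength=4)
    return tuple(counts / counts.sum())


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric matrix of substitutions-per-site distances.

    NaN entries mark saturated pairs.
    """

    ids: tuple
    d: np.ndarray
    locus: str = "concat"
    setting: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.d[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path, locus: str = "concat", setting: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=tuple(df.index), d=df.to_numpy(), locus=locus, setting=setting)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for name, row in zip(self.ids, self.d):
                fh.write(name + "  " + "  ".join(f"{x:.8f}" for x in row) + "\n")


def p_distance_matrix(
    seqs, ids=None, locus: str = "concat", setting: str = ""
) -> DistanceMatrix:
    """All-pairs p-distance on anchored sequences (strings or code matrix)."""
    codes, ids = _as_codes_ids(seqs, ids)
    L, P1, P2, Q = _pairwise_class_counts(codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (P1 + P2 + Q) / L
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=tuple(ids), d=d, locus=locus, setting=setting)


def mcl_distance_matrix(
    seqs, ids=None, locus: str = "concat", setting: str = ""
) -> DistanceMatrix:
    """All-pairs composite TN93 distances with pooled base frequencies.

    Base frequencies are estimated once from all sequences' valid sites;
    each pair's distance uses the TN93 closed form with those pooled
    frequencies and the pair's own P1/P2/Q/L.  With exactly two sequences
    this reduces to the plain TN93 pair distance.
    """
    codes, ids = _as_codes_ids(seqs, ids)
    if codes.shape[0] < 2:
        raise ValueError("need at least 2 sequences")
    freqs = pooled_base_freqs(codes)
    L, P1, P2, Q = _pairwise_class_counts(codes)
    n = codes.shape[0]
    d = np.zeros((n, n))
    n_sat = 0
    for i in range(n):
        for j in range(i + 1, n):
            if L[i, j] == 0:
                raise NoComparableSitesError(f"no comparable sites: {ids[i]} vs {ids[j]}")
            c = SitePairCounts(
                L=int(L[i, j]), P1=int(P1[i, j]), P2=int(P2[i, j]),
                Q=int(Q[i, j]), base_freqs=freqs,
            )
            dij = tn93_distance(c, base_freqs=freqs)
            if np.isnan(dij):
                n_sat += 1
            d[i, j] = d[j, i] = dij
    if n_sat:
        warnings.warn(f"{n_sat} saturated pair(s) flagged NaN in {locus}/{setting}")
    return DistanceMatrix(ids=tuple(ids), d=d, locus=locus, setting=setting)


def _as_codes_ids(seqs, ids):
    if isinstance(seqs, np.ndarray):
        codes = seqs
        if ids is None:
            ids = [f"seq{i}" for i in range(codes.shape[0])]
    else:
        seqs = list(seqs)
        if seqs and isinstance(seqs[0], Sequence):
            if ids is None:
                ids = [s.id for s in seqs]
            seqs = [s.residues for s in seqs]
        elif ids is None:
            ids = [f"seq{i}" for i in range(len(seqs))]
        codes = encode_matrix(seqs)
    return codes, list(ids)


def anchored_codes(
    reference: Sequence,
    seqs: Iterable[Sequence],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> np.ndarray:
    """Project sequences into reference coordinates and encode them.

    Each sequence is globally aligned to the reference; the result is a
    matrix of shape (n, len(reference)) where deletions appear as excluded
    codes and insertions relative to the reference are dropped.
    """
    rows = []
    for s in seqs:
        aln = align_to_reference(reference, s, scoring)
        rows.append(encode(aln.project_to_reference()))
    return np.vstack(rows) if rows else np.empty((0, len(reference)), dtype=np.uint8)


def distance_set(codes: np.ndarray, pairs, metric: str = "tn93_mcl") -> np.ndarray:
    """Distances for an explicit list of (i, j) pairs over anchored codes.

    For ``tn93_mcl`` the base frequencies are pooled over exactly the listed
    pairs' compared sites.
    """
    L, P1, P2, Q = _pairwise_class_counts(codes)
    if metric == "p":
        out = []
        for i, j in pairs:
            if L[i, j] == 0:
                raise NoComparableSitesError("no comparable sites")
            out.append((P1[i, j] + P2[i, j] + Q[i, j]) / L[i, j])
        return np.array(out)
    if metric != "tn93_mcl":
        raise ValueError(f"unknown metric {metric!r}")
    members = sorted({k for ij in pairs for k in ij})
    freqs = pooled_base_freqs(codes[members])
    out = []
    for i, j in pairs:
        if L[i, j] == 0:
            raise NoComparableSitesError("no comparable sites")
        c = SitePairCounts(L=int(L[i, j]), P1=int(P1[i, j]), P2=int(P2[i, j]),
                           Q=int(Q[i, j]), base_freqs=freqs)
        out.append(tn93_distance(c, base_freqs=freqs))
    return np.array(out)


def four_setting_summary(
    reference: Sequence,
    clones,
    ann: LocusAnnotation,
    metric: str = "tn93_mcl",
    original_strand: str = "fwd",
    scoring: AlignmentScoring = AlignmentScoring(),
) -> pd.DataFrame:
    """Mean/max distance table over loci for the four analytical settings.

    Settings: reference vs clone consensus, reference vs original
    (single-strand) clone sequences, and all-pairs among consensus or
    original sequences.  Saturated pairs are excluded from mean/max and
    counted in ``n_saturated``.
    """
    clones = list(clones)
    if any(c.consensus is None for c in clones):
        raise ValueError("clones must carry consensus sequences (run add_consensus)")
    n = len(clones)
    if n < 2:
        warnings.warn("fewer than 2 clones: pairwise settings will be empty")

    cons = anchored_codes(reference, [c.consensus for c in clones], scoring)
    orig = anchored_codes(reference, [c.original(original_strand) for c in clones], scoring)
    ref_row = encode(reference.residues)[None, :]

    rows = []
    for locus, start, end in ann.intervals:
        for setting in SETTINGS:
            mat = cons if "consensus" in setting else orig
            block = np.vstack([ref_row[:, start:end], mat[:, start:end]])
            if setting.startswith("ref_vs"):
                pairs = [(0, k + 1) for k in range(n)]
            else:
                pairs = [(i + 1, j + 1) for i in range(n) for j in range(i + 1, n)]
            if not pairs:
                rows.append((locus, setting, metric, np.nan, np.nan, 0, 0))
                continue
            d = distance_set(block, pairs, metric=metric)
            sat = int(np.isnan(d).sum())
            good = d[~np.isnan(d)]
            rows.append((
                locus, setting, metric,
                float(good.mean()) if good.size else np.nan,
                float(good.max()) if good.size else np.nan,
                len(pairs), sat,
            ))
    return pd.DataFrame(
        rows, columns=["locus", "setting", "metric", "mean", "max", "n", "n_saturated"]
    )
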