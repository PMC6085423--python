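import math

import numpy as np
import pytest

from ribovar.consensus import CloneRecord
from ribovar.distances import (
    DistanceMatrix,
    NoComparableSitesError,
    SitePairCounts,
    four_setting_summary,
    mcl_distance_matrix,
    p_distance,
    p_distance_matrix,
    pair_counts,
    tn93_distance,
)
from ribovar.seqio import LocusAnnotation, Sequence

EQUAL_FREQS = (0.25, 0.25, 0.25, 0.25)


def jc_correction(p):
    return -0.75 * math.log(1 - 4 * p / 3)


def jc_pair_from(ancestor: str, d, rng):
    """Evolve a descendant of an existing sequence at true distance d."""
    a = np.array([("ACGT").index(c) for c in ancestor], dtype=np.uint8)
    p_diff = 0.75 * (1 - math.exp(-4 * d / 3))
    hits = rng.random(a.size) < p_diff
    a[hits] = (a[hits] + rng.integers(1, 4, size=int(hits.sum()))) % 4
    return "".join("ACGT"[c] for c in a)


def jc_pair(L, d, rng):
    """Simulate an anchored pair at true distance d under equal-rate evolution:
    a site differs with probability (3/4)(1 - exp(-4d/3)), uniformly over the
    three alternative bases."""
    a = rng.integers(0, 4, size=L).astype(np.uint8)
    p_diff = 0.75 * (1 - math.exp(-4 * d / 3))
    b = a.copy()
    hits = rng.random(L) < p_diff
    b[hits] = (b[hits] + rng.integers(1, 4, size=int(hits.sum()))) % 4
    to_s = lambda x: "".join("ACGT"[c] for c in x)
    return to_s(a), to_s(b)


class TestPairCounts:
    def test_identical(self):
        c = pair_counts("ACGT", "ACGT")
        assert (c.L, c.P1, c.P2, c.Q) == (4, 0, 0, 0)

    def test_purine_transition(self):
        c = pair_counts("ACGT", "GCGT")
        assert (c.L, c.P1, c.P2, c.Q) == (4, 1, 0, 0)

    def test_pyrimidine_transition_and_transversion(self):
        c = pair_counts("ACGT", "ATGG")
        # C/T transition at pos 1; T/G transversion at pos 3
        assert (c.P1, c.P2, c.Q) == (0, 1, 1)

    def test_pairwise_deletion_excludes_gaps_and_ambiguity(self):
        assert pair_counts("AC-T", "ACGT").L == 3
        assert pair_counts("ACNT", "ACGT").L == 3
        assert pair_counts("ACRT", "ACGT").L == 3

    def test_no_comparable_sites(self):
        with pytest.raises(NoComparableSitesError):
            pair_counts("NNN", "ACG")

    def test_counts_cannot_exceed_sites(self):
        with pytest.raises(ValueError):
            SitePairCounts(L=2, P1=2, P2=1, Q=0, base_freqs=EQUAL_FREQS)


class TestPDistance:
    def test_one_difference_in_four(self):
        assert p_distance(pair_counts("ACGT", "GCGT")) == 0.25

    def test_identical_is_zero(self):
        assert p_distance(pair_counts("ACGT", "ACGT")) == 0.0

    def test_planted_differences(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, size=1000).astype(np.uint8)
        b = a.copy()
        pos = rng.choice(1000, size=10, replace=False)
        b[pos] = (b[pos] + rng.integers(1, 4, size=10)) % 4
        to_s = lambda x: "".join("ACGT"[c] for c in x)
        assert p_distance(pair_counts(to_s(a), to_s(b))) == pytest.approx(0.01)


class TestTn93:
    def test_identical_is_zero(self):
        assert tn93_distance(pair_counts("ACGT", "ACGT")) == 0.0

    def test_reduces_to_jukes_cantor(self):
        # equal frequencies, transition/transversion proportions consistent
        # with a single-rate model: P1 = P2 = p/6, Q = 2p/3
        L, p = 600, 0.05
        c = SitePairCounts(L=L, P1=int(L * p / 6), P2=int(L * p / 6),
                           Q=int(L * 2 * p / 3), base_freqs=EQUAL_FREQS)
        assert tn93_distance(c, base_freqs=EQUAL_FREQS) == pytest.approx(
            jc_correction(p), abs=1e-9
        )

    def test_saturated_pair_flagged_nan(self):
        c = SitePairCounts(L=10, P1=0, P2=0, Q=8, base_freqs=EQUAL_FREQS)
        assert math.isnan(tn93_distance(c))

    @pytest.mark.parametrize("seed", range(5))
    def test_correction_is_expansive(self, seed):
        rng = np.random.default_rng(seed)
        a, b = jc_pair(2000, 0.08, rng)
        c = pair_counts(a, b)
        assert tn93_distance(c) >= p_distance(c)

    def test_recovers_branch_length_under_full_tn93_model(self):
        # independent oracle: evolve a pair under an explicit TN93 rate
        # matrix (unequal frequencies, two transition rates) via the matrix
        # exponential, then check the closed form recovers the branch length
        from scipy.linalg import expm

        pi = np.array([0.35, 0.15, 0.30, 0.20])  # A C G T
        k1, k2 = 4.0, 2.0  # purine / pyrimidine transition rate multipliers
        rates = np.ones((4, 4))
        rates[0, 2] = rates[2, 0] = k1
        rates[1, 3] = rates[3, 1] = k2
        Q = rates * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        Q /= -np.sum(pi * np.diag(Q))  # normalise to 1 substitution/site
        t_true = 0.07
        P = expm(Q * t_true)
        rng = np.random.default_rng(7)
        L = 100_000
        anc = rng.choice(4, size=L, p=pi)
        des = np.array([rng.choice(4, p=P[a]) for a in anc], dtype=np.uint8)
        to_s = lambda x: "".join("ACGT"[c] for c in x)
        est = tn93_distance(pair_counts(to_s(anc.astype(np.uint8)), to_s(des)))
        se = math.sqrt(t_true / L)  # Poisson-scale error of the estimate
        assert abs(est - t_true) < 3 * se

    def test_simulation_recovers_distance(self):
        # 3-point consistency: absolute error of the estimate shrinks with
        # sequence length (median over 20 seeded replicates)
        d_true = 0.05
        med_err = []
        for L in (1_000, 10_000, 100_000):
            errs = []
            for rep in range(20):
                rng = np.random.default_rng(1000 + rep)
                a, b = jc_pair(L, d_true, rng)
                errs.append(abs(tn93_distance(pair_counts(a, b)) - d_true))
            med_err.append(np.median(errs))
        assert med_err[0] > med_err[1] > med_err[2]
        # and the 100 kb estimate is within 3 binomial SEs of the truth
        se = math.sqrt(d_true * (1 - d_true) / 100_000)
        assert med_err[2] < 3 * se


class TestMclMatrix:
    def test_identical_sequences_zero_matrix(self):
        dm = mcl_distance_matrix(["ACGTAC"] * 4)
        assert np.all(dm.d == 0)

    def test_two_sequences_reduce_to_pair_tn93(self):
        rng = np.random.default_rng(3)
        a, b = jc_pair(900, 0.04, rng)
        dm = mcl_distance_matrix([a, b])
        assert dm.d[0, 1] == pytest.approx(tn93_distance(pair_counts(a, b)))

    def test_duplicated_rows_have_zero_mutual_distance(self):
        rng = np.random.default_rng(4)
        a, b = jc_pair(500, 0.05, rng)
        dm = mcl_distance_matrix([a, b, a])
        assert dm.d[0, 2] == 0.0
        assert dm.d[0, 1] == dm.d[2, 1]

    def test_matrix_contract(self):
        rng = np.random.default_rng(5)
        ancestor, first = jc_pair(400, 0.03, rng)
        seqs = [first]
        for _ in range(4):
            seqs.append(jc_pair_from(ancestor, 0.03, rng))
        dm = mcl_distance_matrix(seqs)
        assert np.allclose(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)
        assert np.all(dm.d >= 0)

    def test_round_trip_tsv(self, tmp_path):
        dm = p_distance_matrix(["ACGT", "ACGA", "TCGA"], ids=list("abc"))
        p = tmp_path / "dm.tsv"
        dm.to_tsv(p)
        back = DistanceMatrix.from_tsv(p)
        assert back.ids == dm.ids
        assert np.allclose(back.d, dm.d)


def _make_clone(cid, residues):
    s = Sequence(cid, residues)
    return CloneRecord(clone_id=cid, fwd=s, rev=s, consensus=s)


class TestFourSettingSummary:
    ann = LocusAnnotation(
        reference_id="ref",
        intervals=(("ITS1", 0, 4), ("5.8S", 4, 8), ("ITS2", 8, 12), ("LSU", 12, 16)),
    )
    ref = Sequence("ref", "ACGTACGTACGTACGT")

    def test_identical_clones_all_zero(self):
        clones = [_make_clone(f"c{i}", self.ref.residues) for i in range(3)]
        out = four_setting_summary(self.ref, clones, self.ann, metric="p")
        assert np.all(out["mean"] == 0) and np.all(out["max"] == 0)
        assert set(out["setting"]) == {
            "ref_vs_consensus", "ref_vs_original", "pairwise_consensus", "pairwise_original"
        }

    def test_hand_computed_p_distances(self):
        # ITS1 of c1 has 1 substitution (1/4), c2 has 2 (2/4); c1-vs-c2 share
        # neither site so their ITS1 distance is 3/4
        clones = [
            _make_clone("c0", self.ref.residues),
            _make_clone("c1", "TCGTACGTACGTACGT"),
            _make_clone("c2", "AGCTACGTACGTACGT"),
        ]
        out = four_setting_summary(self.ref, clones, self.ann, metric="p")
        its1 = out[out.locus == "ITS1"].set_index("setting")
        assert its1.loc["ref_vs_consensus", "mean"] == pytest.approx((0 + 0.25 + 0.5) / 3)
        assert its1.loc["ref_vs_consensus", "max"] == 0.5
        assert its1.loc["pairwise_consensus", "mean"] == pytest.approx((0.25 + 0.5 + 0.75) / 3)
        assert its1.loc["pairwise_consensus", "n"] == 3
        lsu = out[out.locus == "LSU"].set_index("setting")
        assert np.all(lsu["mean"] == 0)

    def test_consensus_requirement(self):
        clone = _make_clone("c0", self.ref.residues)
        clone.consensus = None
        with pytest.raises(ValueError, match="consensus"):
            four_setting_summary(self.ref, [clone], self.ann)
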