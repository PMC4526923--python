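import itertools
import math

import numpy as np
import pytest

from sspfam.alphabet import AA, BACKGROUND
from sspfam.msa import Alignment
from sspfam.phmm import (
    CalibrationParams,
    ProfileHMM,
    build_profile_hmm,
    calibrate_hmm,
    forward_score,
    hmm_evalue,
    hmm_search,
    log_probability,
    profile_profile_score,
    shuffle_profile,
    viterbi_score,
)
from sspfam.seqio import ProteinRecord


def delta_emission(residue: str, eps: float = 0.0) -> np.ndarray:
    """Emission vector concentrated on one residue (exact delta at eps=0)."""
    v = np.full(20, eps / 19 if eps else 0.0)
    v[AA.index(residue)] = 1.0 - eps
    return v


def manual_hmm(
    emissions,
    entry=None,
    exit_=None,
    t_mm=None,
    t_md=None,
    t_mi=None,
    t_dm=None,
    t_dd=None,
    t_im=None,
    t_ii=None,
    p_nn=0.0,
    p_cc=0.0,
) -> ProfileHMM:
    L = len(emissions)
    z = np.zeros(L)

    def arr(x, default):
        return np.asarray(x, dtype=float) if x is not None else default

    entry = arr(entry, np.eye(L)[0] if L else z)
    exit_ = arr(exit_, np.eye(L)[L - 1])
    t_mm = arr(t_mm, np.append(np.ones(L - 1), 0.0))
    hmm = ProfileHMM(
        cluster_id="manual",
        match_emissions=np.array(emissions, dtype=float),
        insert_emissions=BACKGROUND.copy(),
        background=BACKGROUND.copy(),
        entry=entry,
        exit_=exit_,
        t_mm=t_mm,
        t_mi=arr(t_mi, z),
        t_md=arr(t_md, z),
        t_im=arr(t_im, np.append(np.ones(L - 1), 0.0)),
        t_ii=arr(t_ii, z),
        t_dm=arr(t_dm, np.append(np.ones(L - 1), 0.0)),
        t_dd=arr(t_dd, z),
        p_nn=p_nn,
        p_cc=p_cc,
    )
    return hmm


def enumerate_logprob(hmm: ProfileHMM, seq: str) -> float:
    """Independent oracle: exhaustive DFS over every state path.

    Sums the probability of all ways the model can emit exactly ``seq``.
    Exponential in sequence length — only for tiny fixtures.
    """
    L = hmm.length
    codes = [AA.index(c) for c in seq]
    n = len(codes)
    f = hmm.background
    total = 0.0

    def emit_m(k, i):
        return hmm.match_emissions[k][codes[i]]

    def walk(state, k, i, p):
        nonlocal total
        if p == 0.0:
            return
        if state == "N":
            if i < n and hmm.p_nn > 0:
                walk("N", k, i + 1, p * hmm.p_nn * f[codes[i]])
            walk("B", 0, i, p * (1 - hmm.p_nn))
        elif state == "B":
            for kk in range(L):
                if hmm.entry[kk] > 0 and i < n:
                    walk("M", kk, i + 1,
                         p * hmm.entry[kk] * emit_m(kk, i))
        elif state == "M":
            walk("E", 0, i, p * hmm.exit_[k])
            if k + 1 < L and i < n and hmm.t_mm[k] > 0:
                walk("M", k + 1, i + 1, p * hmm.t_mm[k] * emit_m(k + 1, i))
            if i < n and hmm.t_mi[k] > 0:
                walk("I", k, i + 1, p * hmm.t_mi[k] * f[codes[i]])
            if k + 1 < L and hmm.t_md[k] > 0:
                walk("D", k + 1, i, p * hmm.t_md[k])
        elif state == "I":
            if k + 1 < L and i < n and hmm.t_im[k] > 0:
                walk("M", k + 1, i + 1, p * hmm.t_im[k] * emit_m(k + 1, i))
            if i < n and hmm.t_ii[k] > 0:
                walk("I", k, i + 1, p * hmm.t_ii[k] * f[codes[i]])
        elif state == "D":
            if k == L - 1:
                walk("E", 0, i, p)
            else:
                if hmm.t_dm[k] > 0 and i < n:
                    walk("M", k + 1, i + 1, p * hmm.t_dm[k] * emit_m(k + 1, i))
                if hmm.t_dd[k] > 0:
                    walk("D", k + 1, i, p * hmm.t_dd[k])
        elif state == "E":
            walk("C", 0, i, p)
        elif state == "C":
            if i < n and hmm.p_cc > 0:
                walk("C", k, i + 1, p * hmm.p_cc * f[codes[i]])
            if i == n:
                total += p * (1 - hmm.p_cc)

    walk("N", 0, 0, 1.0)
    return math.log(total) if total > 0 else -math.inf


class TestBuild:
    def test_single_sequence_three_match_states(self):
        aln = Alignment(member_ids=["a"], rows=["WKY"])
        hmm = build_profile_hmm(aln, cluster_id="c1")
        assert hmm.length == 3
        assert AA[int(np.argmax(hmm.match_emissions[0]))] == "W"
        assert AA[int(np.argmax(hmm.match_emissions[2]))] == "Y"

    def test_identical_rows_argmax_matches_residues(self):
        aln = Alignment(member_ids=list("abcd"), rows=["MKWVY"] * 4)
        hmm = build_profile_hmm(aln)
        consensus = "".join(AA[int(np.argmax(e))] for e in hmm.match_emissions)
        assert consensus == "MKWVY"

    def test_pseudocount_weight_changes_normalized_emissions(self):
        aln = Alignment(member_ids=["a", "b"], rows=["WKY", "WKY"])
        h0 = build_profile_hmm(aln, pseudocount_weight=0.0)
        h1 = build_profile_hmm(aln, pseudocount_weight=1.0)
        assert not np.allclose(h0.match_emissions, h1.match_emissions)
        for h in (h0, h1):
            assert np.allclose(h.match_emissions.sum(axis=1), 1.0, atol=1e-9)

    def test_probability_vectors_normalized(self, toy_segments):
        from sspfam.msa import progressive_align, prune_columns

        aln = prune_columns(progressive_align(toy_segments))
        hmm = build_profile_hmm(aln, cluster_id="c9")
        hmm.validate(atol=1e-9)
        assert (hmm.match_emissions > 0).all()


class TestScoring:
    def test_two_state_no_indel_model_sums_to_one(self):
        hmm = manual_hmm([delta_emission("A", 0.4), delta_emission("C", 0.4)])
        total = 0.0
        for x, y in itertools.product(range(20), repeat=2):
            total += math.exp(log_probability(hmm, AA[x] + AA[y]))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_model_with_deletions_sums_to_one_over_lengths(self):
        hmm = manual_hmm(
            [delta_emission("A", 0.4), delta_emission("C", 0.4)],
            entry=[0.6, 0.4],
            exit_=[0.1, 1.0],
            t_mm=[0.7, 0.0],
            t_md=[0.2, 0.0],
        )
        total = sum(
            math.exp(log_probability(hmm, AA[x])) for x in range(20)
        )
        total += sum(
            math.exp(log_probability(hmm, AA[x] + AA[y]))
            for x, y in itertools.product(range(20), repeat=2)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_forward_matches_path_enumeration_with_flanks_and_indels(self):
        hmm = manual_hmm(
            [delta_emission("W", 0.3), delta_emission("K", 0.3),
             delta_emission("Y", 0.3)],
            entry=[0.5, 0.3, 0.2],
            exit_=[0.05, 0.1, 1.0],
            t_mm=[0.6, 0.6, 0.0],
            t_mi=[0.15, 0.1, 0.0],
            t_md=[0.2, 0.2, 0.0],
            t_im=[0.7, 0.7, 0.0],
            t_ii=[0.3, 0.3, 0.0],
            t_dm=[0.8, 1.0, 0.0],
            t_dd=[0.2, 0.0, 0.0],
            p_nn=0.4,
            p_cc=0.3,
        )
        for seq in ["WKY", "WY", "KWKY", "WKKY", "AWKYA", "K"]:
            assert log_probability(hmm, seq) == pytest.approx(
                enumerate_logprob(hmm, seq), abs=1e-9
            ), seq

    def test_viterbi_never_exceeds_forward(self, toy_segments, rng):
        from sspfam.msa import progressive_align, prune_columns

        aln = prune_columns(progressive_align(toy_segments))
        hmm = build_profile_hmm(aln)
        for _ in range(20):
            seq = "".join(rng.choice(list(AA), size=int(rng.integers(5, 40))))
            assert viterbi_score(hmm, seq) <= forward_score(hmm, seq) + 1e-9

    def test_model_prefers_own_sequence_over_shuffles(self, rng):
        seq = "WKYGHPLMCD"
        aln = Alignment(member_ids=["a"], rows=[seq])
        hmm = build_profile_hmm(aln)
        own = viterbi_score(hmm, seq)
        shuffled = []
        for _ in range(100):
            shuffled.append(
                viterbi_score(hmm, "".join(rng.permutation(list(seq))))
            )
        assert own > np.median(shuffled)

    def test_x_residue_scores_like_background(self):
        aln = Alignment(member_ids=["a"], rows=["WKY"])
        hmm = build_profile_hmm(aln)
        assert np.isfinite(viterbi_score(hmm, "WXY"))
        assert viterbi_score(hmm, "WXY") < viterbi_score(hmm, "WKY")


class TestCalibration:
    def test_recovery_from_known_gumbel(self):
        from scipy.stats import gumbel_r

        from sspfam.evd import fit_gumbel

        scores = gumbel_r.rvs(loc=-5.0, scale=1.5, size=5000,
                              random_state=np.random.default_rng(17))
        evd = fit_gumbel(scores)
        assert evd.mu == pytest.approx(-5.0, abs=0.2)
        assert evd.beta == pytest.approx(1.5, rel=0.10)

    def test_calibrate_deterministic_and_stored(self):
        aln = Alignment(member_ids=["a", "b"], rows=["WKYGH", "WKYGH"])
        hmm = build_profile_hmm(aln)
        p1 = calibrate_hmm(hmm, n_samples=200, sample_length=80, seed=5)
        p2 = calibrate_hmm(hmm, n_samples=200, sample_length=80, seed=5)
        assert (p1.mu, p1.lam) == (p2.mu, p2.lam)
        assert hmm.calibration == p2

    def test_evalue_identity_at_location(self):
        aln = Alignment(member_ids=["a"], rows=["WKYGH"])
        hmm = build_profile_hmm(aln)
        calibrate_hmm(hmm, n_samples=200, sample_length=80, seed=5)
        e = hmm_evalue(hmm, hmm.calibration.mu, 1)
        assert e == pytest.approx(1 - math.exp(-1), abs=1e-9)

    def test_lambda_must_be_positive(self):
        with pytest.raises(ValueError):
            CalibrationParams(mu=0.0, lam=0.0, n_samples=100,
                              sample_length=100, seed=0)


class TestSearch:
    def make_calibrated(self, rows, cid="c1"):
        aln = Alignment(member_ids=[f"m{i}" for i in range(len(rows))], rows=rows)
        hmm = build_profile_hmm(aln, cluster_id=cid)
        calibrate_hmm(hmm, n_samples=200, sample_length=60, seed=3)
        return hmm

    def test_empty_targets_give_empty_hits(self):
        hmm = self.make_calibrated(["WKYGHPLMCD"] * 2)
        assert hmm_search([hmm], [], evalue_cutoff=1.0) == []

    def test_uncalibrated_model_rejected(self):
        aln = Alignment(member_ids=["a"], rows=["WKYGH"])
        hmm = build_profile_hmm(aln)
        with pytest.raises(ValueError, match="not calibrated"):
            hmm_search([hmm], [ProteinRecord("s", "WKYGH")])

    def test_member_sequence_hits_its_own_cluster_best(self):
        h1 = self.make_calibrated(["WKYGHPLMCD", "WKYGHPLMCE"], cid="c1")
        h2 = self.make_calibrated(["QNSTRRDEAG", "QNSTRRDEAG"], cid="c2")
        target = ProteinRecord("s", "AAWKYGHPLMCDAA")
        hits = hmm_search([h1, h2], [target], evalue_cutoff=10.0)
        assert hits and hits[0].cluster_id == "c1"

    def test_all_hits_respect_cutoff(self):
        h1 = self.make_calibrated(["WKYGHPLMCD"] * 3)
        seqs = [ProteinRecord(f"s{i}", "WKYGHPLMCD") for i in range(3)]
        seqs += [ProteinRecord("bg", "QQQQNNNSSS")]
        hits = hmm_search([h1], seqs, evalue_cutoff=0.01)
        assert all(h.evalue <= 0.01 for h in hits)
        assert {h.sequence_id for h in hits} == {"s0", "s1", "s2"}


class TestProfileProfile:
    def make(self, rows, cid):
        aln = Alignment(member_ids=[f"{cid}{i}" for i in range(len(rows))],
                        rows=rows)
        return build_profile_hmm(aln, cluster_id=cid)

    def test_self_scores_at_least_unrelated(self, rng):
        h = self.make(["WKYGHPLMCD"] * 3, "c1")
        other = self.make(
            ["".join(rng.choice(list(AA), size=10)) for _ in range(3)], "c2"
        )
        assert profile_profile_score(h, h) >= profile_profile_score(h, other)

    def test_exact_symmetry(self, rng):
        h1 = self.make(["WKYGHPLMCD", "WKYGHPLMCE"], "c1")
        h2 = self.make(["WKYGHAAMCD", "WKYGQPLMCD", "FKYGHPLMCD"], "c2")
        assert profile_profile_score(h1, h2) == profile_profile_score(h2, h1)

    def test_disjoint_delta_profiles_score_zero(self):
        h1 = manual_hmm([delta_emission("W"), delta_emission("K")])
        h1.cluster_id = "d1"
        h2 = manual_hmm([delta_emission("P"), delta_emission("E")])
        h2.cluster_id = "d2"
        assert profile_profile_score(h1, h2) == 0.0

    def test_joint_reversal_invariance(self):
        h1 = self.make(["WKYGHPLMCD", "WKYGHPLMCE"], "c1")
        h2 = self.make(["WKYGHAAMCD", "WKYGQPLMCD"], "c2")

        def reverse(h, cid):
            out = shuffle_profile(h, np.random.default_rng(0))
            out.match_emissions = h.match_emissions[::-1].copy()
            out.cluster_id = cid
            return out

        assert profile_profile_score(h1, h2) == pytest.approx(
            profile_profile_score(reverse(h1, "c1"), reverse(h2, "c2"))
        )

    def test_column_shuffle_of_related_profiles_drops_score(self, rng):
        h1 = self.make(["WKYGHPLMCDERQNST"] * 3, "c1")
        h2 = self.make(["WKYGHPLMCDERQNST"] * 2, "c2")
        real = profile_profile_score(h1, h2)
        decoy = profile_profile_score(h1, shuffle_profile(h2, rng))
        assert real > decoy
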