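import math
from functools import lru_cache

import numpy as np
import pytest

from sspfam.alphabet import AA, load_matrix
from sspfam.evd import EVDParams, evalue_from_score, fit_gumbel
from sspfam.pairwise import (
    all_vs_all,
    build_graph,
    fit_score_background,
    smith_waterman,
)
from sspfam.seqio import CTerminalSegment

GAP_OPEN, GAP_EXT = 10, 2


def oracle_local_score(a: str, b: str, matrix_name: str = "BLOSUM50") -> float:
    """Independent local-alignment maximum by recursive enumeration.

    Three-state recursion over suffix pairs (memoized); the local score is
    the best over all match start points, floored at 0. The first gap
    residue costs `open`, later ones `extend`, matching the package's
    convention.
    """
    mat = load_matrix(matrix_name)

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, state: str) -> float:
        best = 0.0  # stop anywhere
        if i < len(a) and j < len(b):
            best = max(best, mat[a[i], b[j]] + ext(i + 1, j + 1, "M"))
        if i < len(a):
            cost = GAP_EXT if state == "X" else GAP_OPEN
            best = max(best, -cost + ext(i + 1, j, "X"))
        if j < len(b):
            cost = GAP_EXT if state == "Y" else GAP_OPEN
            best = max(best, -cost + ext(i, j + 1, "Y"))
        return best

    best = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, mat[a[i], b[j]] + ext(i + 1, j + 1, "M"))
    return best


class TestSmithWaterman:
    def test_double_tryptophan_identity(self):
        # BLOSUM50 W-W diagonal is 15; two matches
        assert smith_waterman("WW", "WW") == 30

    def test_all_negative_pairs_floor_at_zero(self):
        score, aln = smith_waterman("WWWW", "PPPP", with_alignment=True)
        assert score == 0
        assert aln is None

    def test_unknown_residue_reported_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            smith_waterman("A1C", "ACD")

    def test_x_scores_zero(self):
        assert smith_waterman("AXA", "AAA") == 10  # two A-A matches, X:0

    def test_matches_enumeration_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            la, lb = rng.integers(1, 13, size=2)
            a = "".join(rng.choice(list(AA), size=la))
            b = "".join(rng.choice(list(AA), size=lb))
            assert smith_waterman(a, b) == oracle_local_score(a, b), (a, b)

    def test_symmetric_and_nonnegative(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(list(AA), size=rng.integers(3, 20)))
            b = "".join(rng.choice(list(AA), size=rng.integers(3, 20)))
            s = smith_waterman(a, b)
            assert s >= 0
            assert s == smith_waterman(b, a)

    def test_identical_flanks_never_decrease_score(self, rng):
        for _ in range(25):
            a = "".join(rng.choice(list(AA), size=10))
            b = "".join(rng.choice(list(AA), size=10))
            flank = "".join(rng.choice(list(AA), size=4))
            s0 = smith_waterman(a, b)
            s1 = smith_waterman(flank + a, flank + b)
            assert s1 >= s0


class TestCalibration:
    def test_gumbel_recovery_from_known_generator(self):
        from scipy.stats import gumbel_r

        samples = gumbel_r.rvs(loc=10.0, scale=2.0, size=5000,
                               random_state=np.random.default_rng(3))
        evd = fit_gumbel(samples)
        assert evd.mu == pytest.approx(10.0, abs=0.2)
        assert evd.beta == pytest.approx(2.0, rel=0.10)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gumbel(np.full(500, 7.0))

    def test_background_fit_deterministic(self, toy_segments):
        a = fit_score_background(toy_segments, n_decoys=150, seed=9)
        b = fit_score_background(toy_segments, n_decoys=150, seed=9)
        assert (a.mu, a.lam) == (b.mu, b.lam)

    def test_evalue_identity_at_location(self):
        evd = EVDParams(mu=25.0, lam=0.3)
        assert evalue_from_score(25.0, evd, 1) == pytest.approx(1 - math.exp(-1), abs=1e-9)

    def test_evalue_floor_and_monotonicity(self):
        evd = EVDParams(mu=25.0, lam=0.3)
        assert evalue_from_score(1e7, evd, 1) == 1e-200
        scores = [10.0, 20.0, 30.0, 60.0]
        evs = [evalue_from_score(s, evd, 10) for s in scores]
        assert evs == sorted(evs, reverse=True)


class TestAllVsAll:
    def test_pair_count(self, toy_segments):
        hits = all_vs_all(toy_segments, seed=5)
        assert len(hits) == 6  # 4*3/2

    def test_hits_stored_per_unordered_pair(self, toy_segments):
        hits = all_vs_all(toy_segments, seed=5)
        assert all(h.query_id < h.target_id for h in hits)

    def test_identical_segments_attain_best_rank(self):
        segs = [
            CTerminalSegment("a", "MKWVYQGKLLPRAAYWCH", 0),
            CTerminalSegment("b", "MKWVYQGKLLPRAAYWCH", 0),
            CTerminalSegment("c", "ADEQNSTHRKGPMLVIFY", 0),
            CTerminalSegment("d", "YFIVLMPGKRHTSNQEDA", 0),
        ]
        hits = all_vs_all(segs, seed=5)
        involving_a = [h for h in hits if "a" in (h.query_id, h.target_id)]
        best = min(involving_a, key=lambda h: h.evalue)
        assert {best.query_id, best.target_id} == {"a", "b"}


class TestBuildGraph:
    def make_hit(self, q, t, e):
        from sspfam.pairwise import AlignmentHit

        return AlignmentHit(query_id=q, target_id=t, raw_score=50,
                            bit_score=1.0, evalue=e)

    def test_weight_is_neg_log10_evalue(self):
        g = build_graph([self.make_hit("a", "b", 1e-4)])
        assert g["a"]["b"]["weight"] == pytest.approx(4.0)

    def test_default_cutoff_excludes_weak_hits(self):
        g = build_graph([self.make_hit("a", "b", 0.01)])
        assert not g.has_edge("a", "b")
        assert set(g.nodes) == {"a", "b"}  # isolated, future singletons

    def test_weight_cap_at_floor(self):
        g = build_graph([self.make_hit("a", "b", 1e-200)])
        assert g["a"]["b"]["weight"] == 200.0

    def test_edges_shrink_as_cutoff_tightens(self):
        hits = [self.make_hit("a", "b", 1e-4), self.make_hit("a", "c", 1e-6),
                self.make_hit("b", "c", 1e-9)]
        sizes = [build_graph(hits, evalue_cutoff=c).number_of_edges()
                 for c in (1e-3, 1e-5, 1e-8, 1e-12)]
        assert sizes == sorted(sizes, reverse=True)
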