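"""All-against-all local alignment of C-terminal segments.

The motif-discovery stage compares the last 50 residues of every candidate
against every other with Smith-Waterman local alignment under BLOSUM50
(chosen to pick up mildly related sequences) and affine gap penalties.
Raw scores are converted to E-values by empirical Gumbel calibration on
shuffled-sequence decoys, and pairs with E <= 1e-3 become edges of a
similarity graph, weighted -log10(E), that the Markov clustering stage
consumes.

The alignment engine is Biopython's ``PairwiseAligner`` (exact affine-gap
Smith-Waterman); heuristic seeding is deliberately not used — at the scale
of short C-terminal segments exactness is affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align

from .alphabet import load_matrix, validate_sequence
from .config import PairwiseConfig
from .evd import EVDParams, evalue_from_score, fit_gumbel
from .seqio import CTerminalSegment


@dataclass(frozen=True)
class AlignmentHit:
    """One all-vs-all hit, stored once per unordered pair (query < target)."""

    query_id: str
    target_id: str
    raw_score: float
    bit_score: float
    evalue: float

    def __post_init__(self):
        if self.query_id >= self.target_id:
            raise ValueError("hits are stored with query_id < target_id")
        if self.raw_score < 0 or self.evalue <= 0:
            raise ValueError("raw_score must be >= 0 and evalue > 0")


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = load_matrix(matrix)
    # open cost includes the first extension
    al.open_gap_score = -float(gap_open)
    al.extend_gap_score = -float(gap_extend)
    return al


def smith_waterman(
    a: str,
    b: str,
    matrix: str = "BLOSUM50",
    gap_open: float = 10,
    gap_extend: float = 2,
    with_alignment: bool = False,
):
    """Maximal affine-gap local alignment score of two sequences.

    The score is floored at 0 (the empty alignment); X scores 0 against
    every residue. Returns the score, or ``(score, alignment)`` when
    ``with_alignment`` is true (``alignment`` is ``None`` for score 0).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    validate_sequence(a)
    validate_sequence(b)
    al = _aligner(matrix, gap_open, gap_extend)
    score = float(al.score(a, b))
    if not with_alignment:
        return score
    if score <= 0:
        return 0.0, None
    return score, next(iter(al.align(a, b)))


class ScoreBackend:
    """Reusable aligner for bulk scoring (avoids per-call setup cost)."""

    def __init__(self, config: PairwiseConfig | None = None):
        self.config = config or PairwiseConfig()
        self._al = _aligner(self.config.matrix, self.config.gap_open,
                            self.config.gap_extend)

    def score(self, a: str, b: str) -> float:
        return float(self._al.score(a, b))


def fit_score_background(
    segments: Sequence[CTerminalSegment],
    n_decoys: int = 1000,
    seed: int = 0,
    config: PairwiseConfig | None = None,
) -> EVDParams:
    """Calibrate the null score distribution on shuffled decoy pairs.

    Draws ``n_decoys`` pairs of segments (with replacement), independently
    shuffles each sequence to destroy motif structure while preserving
    composition and length, scores them, and fits a Gumbel by maximum
    likelihood. Segments are all capped at the C-terminal window and hence
    nearly uniform in length, so a single global fit is used rather than
    per-length classes.
    """
    if n_decoys < 100:
        raise ValueError("n_decoys must be >= 100")
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to calibrate")
    backend = ScoreBackend(config)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    seqs = [np.array(list(s.sequence)) for s in segments]
    for k in range(n_decoys):
        i, j = rng.choice(len(seqs), size=2, replace=True)
        a = "".join(rng.permutation(seqs[i]))
        b = "".join(rng.permutation(seqs[j]))
        scores[k] = backend.score(a, b)
    return fit_gumbel(scores, n_samples=n_decoys, seed=seed)


def all_vs_all(
    segments: Sequence[CTerminalSegment],
    evd: EVDParams | None = None,
    seed: int = 0,
    config: PairwiseConfig | None = None,
) -> list[AlignmentHit]:
    """Score every unordered pair of segments and attach E-values.

    E-values are computed against ``n_comparisons = n*(n-1)/2``, the
    number of pairs actually scored. The reported bit score is
    ``lam * (S - mu) / ln 2`` — the raw score re-expressed in bits above
    the fitted null location, monotone in S and comparable across runs
    with different matrices or gap penalties.
    """
    cfg = config or PairwiseConfig()
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    ids = [s.parent_id for s in segments]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate segment parent_ids")
    if evd is None:
        evd = fit_score_background(segments, n_decoys=cfg.n_decoys,
                                   seed=seed, config=cfg)
    backend = ScoreBackend(cfg)
    n_pairs = len(segments) * (len(segments) - 1) // 2
    hits = []
    for sa, sb in combinations(segments, 2):
        qid, tid = sorted((sa.parent_id, sb.parent_id))
        score = backend.score(sa.sequence, sb.sequence)
        ev = evalue_from_score(score, evd, n_pairs)
        bits = evd.lam * (score - evd.mu) / math.log(2)
        hits.append(AlignmentHit(query_id=qid, target_id=tid,
                                 raw_score=score, bit_score=bits, evalue=ev))
    return hits


def build_graph(
    hits: Sequence[AlignmentHit],
    evalue_cutoff: float = 1e-3,
    weight_cap: float = 200.0,
    nodes: Sequence[str] | None = None,
) -> nx.Graph:
    """Similarity graph: edge iff E <= cutoff, weight = min(cap, -log10 E).

    Nodes with no surviving edge remain as isolated nodes — they are the
    future singletons. ``nodes`` may extend the node set beyond the hits'
    endpoints.
    """
    g = nx.Graph()
    for h in hits:
        g.add_node(h.query_id)
        g.add_node(h.target_id)
        if h.evalue <= evalue_cutoff:
            w = min(weight_cap, -math.log10(h.evalue))
            g.add_edge(h.query_id, h.target_id, weight=w)
    if nodes is not None:
        g.add_nodes_from(nodes)
    return g


def hits_to_frame(hits: Sequence[AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"query": h.query_id, "target": h.target_id,
             "raw_score": h.raw_score, "bit_score": h.bit_score,
             "evalue": h.evalue}
            for h in hits
        ]
    )


def write_hits(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def write_graph(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {"node_a": a, "node_b": b, "weight": d["weight"]}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_graph(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(str(row.node_a), str(row.node_b), weight=float(row.weight))
    return g
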