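"""Per-cluster multiple alignment and conserved-column pruning.

Clusters of C-terminal segments are aligned with a deterministic
progressive aligner: a UPGMA guide tree over Smith-Waterman distances,
then profile-profile global alignment (sum-of-pairs BLOSUM62 scoring,
affine gaps) up the tree. Columns that are mostly gaps or not conserved
under BLOSUM62 are then masked out, so that the profile HMM of a cluster
is built from its conserved core only. Iterative refinement is
deliberately omitted: clusters are small and short, and determinism is
worth more than the marginal accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import encode, matrix_lookup
from .config import MsaConfig
from .seqio import CTerminalSegment

GAP = "-"


class NoConservedRegionError(ValueError):
    """Pruning removed every column: the cluster has no conserved core."""


@dataclass
class Alignment:
    """A gapped alignment plus a boolean mask of retained columns."""

    member_ids: list[str]
    rows: list[str]
    column_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if len(self.member_ids) != len(self.rows):
            raise ValueError("member_ids and rows must correspond")
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("all rows must have equal length")
        if self.column_mask is None:
            self.column_mask = np.ones(width, dtype=bool)
        else:
            self.column_mask = np.asarray(self.column_mask, dtype=bool)
            if self.column_mask.shape != (width,):
                raise ValueError("column_mask length must equal row length")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def masked_rows(self) -> list[str]:
        keep = self.column_mask
        return ["".join(c for c, m in zip(r, keep) if m) for r in self.rows]


# ---------------------------------------------------------------------------
# UPGMA guide tree


def _sw_scores(segments: Sequence[CTerminalSegment], cfg: MsaConfig):
    from .pairwise import smith_waterman  # local import avoids cycle at import time

    def score(a: str, b: str) -> float:
        return smith_waterman(a, b, matrix=cfg.matrix,
                              gap_open=cfg.gap_open, gap_extend=cfg.gap_extend)

    return score


def upgma_guide_tree(
    segments: Sequence[CTerminalSegment], config: MsaConfig | None = None
):
    """UPGMA tree (nested tuples, leaves = segment ids) over SW distances.

    d(a, b) = 1 - S(a, b) / min(S(a, a), S(b, b)), so identical sequences
    are at distance 0. Ties are broken by joining the pair whose
    (smallest-member-id, smallest-member-id) label pair sorts first.
    """
    cfg = config or MsaConfig()
    if len(segments) < 2:
        raise ValueError("need >= 2 segments for a guide tree")
    ids = [s.parent_id for s in segments]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate segment ids")
    score = _sw_scores(segments, cfg)
    self_s = {s.parent_id: max(score(s.sequence, s.sequence), 1e-9) for s in segments}
    dist: dict[frozenset, float] = {}
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            a, b = segments[i], segments[j]
            s = score(a.sequence, b.sequence)
            d = 1.0 - s / min(self_s[a.parent_id], self_s[b.parent_id])
            dist[frozenset((a.parent_id, b.parent_id))] = d

    # active cluster -> (tree, members, size); keyed by smallest member id
    active: dict[str, tuple[object, int]] = {i: (i, 1) for i in ids}
    cdist = {frozenset(k): v for k, v in dist.items()}
    while len(active) > 1:
        best = None
        for a in active:
            for b in active:
                if a >= b:
                    continue
                d = cdist[frozenset((a, b))]
                key = (round(d, 12), a, b)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        ta, na = active.pop(a)
        tb, nb = active.pop(b)
        new_key = min(a, b)
        for c in list(active):
            da = cdist.pop(frozenset((a, c)))
            db = cdist.pop(frozenset((b, c)))
            cdist[frozenset((new_key, c))] = (na * da + nb * db) / (na + nb)
        cdist.pop(frozenset((a, b)), None)
        active[new_key] = ((ta, tb), na + nb)
    (tree, _), = active.values()
    return tree


def tree_leaves(tree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    left, right = tree
    return tree_leaves(left) + tree_leaves(right)


# ---------------------------------------------------------------------------
# progressive profile-profile alignment

_DIAG, _UP, _LEFT = 0, 1, 2


def _column_counts(rows: list[str]) -> np.ndarray:
    """(width, 21) counts of non-gap residues per column (X = code 20)."""
    width = len(rows[0])
    counts = np.zeros((width, 21))
    for r in rows:
        codes = encode(r.replace(GAP, "A"))  # placeholder, masked next line
        for j, (c, raw) in enumerate(zip(codes, r)):
            if raw != GAP:
                counts[j, c] += 1
    return counts


def _merge(rows_a, rows_b, cfg: MsaConfig) -> tuple[list[str], list[str]]:
    """Global affine profile-profile alignment of two row blocks."""
    mat = matrix_lookup(cfg.matrix)
    ca = _column_counts(rows_a)
    cb = _column_counts(rows_b)
    sp = ca @ mat @ cb.T  # sum-of-pairs column-pair scores
    la, lb = sp.shape
    scale = len(rows_a) * len(rows_b)
    go = cfg.gap_open * scale
    ge = cfg.gap_extend * scale

    neg = -1e18
    m = np.full((la + 1, lb + 1), neg)
    ix = np.full((la + 1, lb + 1), neg)  # gap in B (consume A column)
    iy = np.full((la + 1, lb + 1), neg)  # gap in A (consume B column)
    m[0, 0] = 0.0
    for i in range(1, la + 1):
        ix[i, 0] = -go - (i - 1) * ge
    for j in range(1, lb + 1):
        iy[0, j] = -go - (j - 1) * ge
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0: from M, 1: extend
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            # match state: tie-break diagonal source M > Ix (up) > Iy (left)
            cands = (m[i - 1, j - 1], ix[i - 1, j - 1], iy[i - 1, j - 1])
            k = int(np.argmax(cands))
            m[i, j] = sp[i - 1, j - 1] + cands[k]
            ptr_m[i, j] = k
            open_x = m[i - 1, j] - go
            ext_x = ix[i - 1, j] - ge
            if open_x >= ext_x:
                ix[i, j] = open_x
                ptr_x[i, j] = 0
            else:
                ix[i, j] = ext_x
                ptr_x[i, j] = 1
            open_y = m[i, j - 1] - go
            ext_y = iy[i, j - 1] - ge
            if open_y >= ext_y:
                iy[i, j] = open_y
                ptr_y[i, j] = 0
            else:
                iy[i, j] = ext_y
                ptr_y[i, j] = 1

    # traceback from the best end state; diagonal > up > left on ties
    i, j = la, lb
    finals = (m[i, j], ix[i, j], iy[i, j])
    state = int(np.argmax(finals))
    cols_a: list[int | None] = []
    cols_b: list[int | None] = []
    while i > 0 or j > 0:
        if state == _DIAG and i > 0 and j > 0:
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == _UP or (state == _DIAG and j == 0):
            cols_a.append(i - 1)
            cols_b.append(None)
            nxt = ptr_x[i, j]
            i -= 1
            state = _UP if nxt == 1 else _DIAG
            if i == 0 and j > 0:
                state = _LEFT
        else:
            cols_a.append(None)
            cols_b.append(j - 1)
            nxt = ptr_y[i, j]
            j -= 1
            state = _LEFT if nxt == 1 else _DIAG
            if j == 0 and i > 0:
                state = _UP
    cols_a.reverse()
    cols_b.reverse()

    out_a = [
        "".join(r[c] if c is not None else GAP for c in cols_a) for r in rows_a
    ]
    out_b = [
        "".join(r[c] if c is not None else GAP for c in cols_b) for r in rows_b
    ]
    return out_a, out_b


def progressive_align(
    segments: Sequence[CTerminalSegment],
    guide_tree=None,
    config: MsaConfig | None = None,
) -> Alignment:
    """Align a cluster's segments progressively up the guide tree.

    Two-sequence clusters reduce to plain global (Needleman-Wunsch)
    alignment. Ungapping any row reproduces the corresponding input
    sequence exactly.
    """
    cfg = config or MsaConfig()
    seqs = {s.parent_id: s.sequence for s in segments}
    if len(segments) == 1:
        only = segments[0]
        return Alignment(member_ids=[only.parent_id], rows=[only.sequence])
    if guide_tree is None:
        guide_tree = upgma_guide_tree(segments, cfg)
    if sorted(tree_leaves(guide_tree)) != sorted(seqs):
        raise ValueError("guide tree leaves must match segment ids")

    def rec(node) -> tuple[list[str], list[str]]:
        if isinstance(node, str):
            return [node], [seqs[node]]
        left, right = node
        ids_l, rows_l = rec(left)
        ids_r, rows_r = rec(right)
        rows_l, rows_r = _merge(rows_l, rows_r, cfg)
        return ids_l + ids_r, rows_l + rows_r

    ids, rows = rec(guide_tree)
    return Alignment(member_ids=ids, rows=rows)


# ---------------------------------------------------------------------------
# column pruning


def prune_columns(
    aln: Alignment,
    max_gap_frac: float = 0.5,
    min_col_score: float = 0.0,
    matrix: str = "BLOSUM62",
    config: MsaConfig | None = None,
) -> Alignment:
    """Mask gapped and non-conserved columns (rows untouched).

    A column is retained iff its gap fraction is <= ``max_gap_frac``, it
    has >= 2 non-gap residues, and the mean pairwise BLOSUM62 score over
    its non-gap residue pairs exceeds ``min_col_score``. Raises
    :class:`NoConservedRegionError` when nothing survives.
    """
    if config is not None:
        max_gap_frac = config.max_gap_frac
        min_col_score = config.min_col_score
        matrix = config.matrix
    mat = matrix_lookup(matrix)
    nrows = len(aln.rows)
    mask = np.zeros(aln.width, dtype=bool)
    for j in range(aln.width):
        col = [r[j] for r in aln.rows]
        residues = [c for c in col if c != GAP]
        gap_frac = 1.0 - len(residues) / nrows
        if gap_frac > max_gap_frac or len(residues) < 2:
            continue
        codes = encode("".join(residues))
        total = 0.0
        npairs = 0
        for x in range(len(codes)):
            for y in range(x + 1, len(codes)):
                total += mat[codes[x], codes[y]]
                npairs += 1
        if npairs and total / npairs > min_col_score:
            mask[j] = True
    if not mask.any():
        raise NoConservedRegionError(
            "no conserved region: pruning removed every column"
        )
    return Alignment(member_ids=list(aln.member_ids), rows=list(aln.rows),
                     column_mask=mask)


# ---------------------------------------------------------------------------
# Stockholm serialization (column mask as #=GC RF, x = retained, . = removed)


def write_stockholm(aln: Alignment, path: str | Path, name: str = "") -> None:
    pad = max(len("#=GC RF"), max(len(i) for i in aln.member_ids)) + 2
    lines = ["# STOCKHOLM 1.0"]
    if name:
        lines.append(f"#=GF ID {name}")
    for mid, row in zip(aln.member_ids, aln.rows):
        lines.append(f"{mid:<{pad}}{row}")
    rf = "".join("x" if m else "." for m in aln.column_mask)
    lines.append(f"{'#=GC RF':<{pad}}{rf}")
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


def read_stockholm(path: str | Path) -> Alignment:
    ids: list[str] = []
    rows: list[str] = []
    rf = None
    for line in Path(path).read_text().splitlines():
        line = line.rstrip()
        if not line or line == "//" or line.startswith("#=GF"):
            continue
        if line.startswith("# STOCKHOLM"):
            continue
        if line.startswith("#=GC RF"):
            rf = line.split(None, 2)[2]
            continue
        if line.startswith("#"):
            continue
        name, row = line.split(None, 1)
        ids.append(name)
        rows.append(row.strip())
    mask = None
    if rf is not None:
        mask = np.array([c == "x" for c in rf])
    return Alignment(member_ids=ids, rows=rows, column_mask=mask)
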