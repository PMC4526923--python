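"""Profile hidden Markov models of conserved C-terminal motifs.

Each cluster's pruned alignment is compiled into a profile HMM with one
match state per retained column, position-based (Henikoff) sequence
weighting, background-mixture pseudocounts, and a single-hit local
alignment architecture: uniform begin-entry over match states, a small
local-exit mass from every internal match state, and free N/C flanking
states that emit background residues. Scores are log-odds in bits against
a background null model with the same geometric length distribution, so
flank emissions cancel and only the motif contributes.

Raw scores are converted to E-values via Gumbel calibration on random
background sequences, mirroring the classic hmmbuild/hmmcalibrate/
hmmsearch workflow. Viterbi scores are used for calibration and search by
default; Forward is available behind a flag.

Profile-profile comparison (for linking related clusters into families)
uses a local dynamic program over match-state pairs with the co-emission
column score

    s(i, j) = log2( sum_a  p_i(a) * q_j(a) / f(a) )

and affine gaps on either profile, floored at zero, with E-values
calibrated against column-shuffled decoy profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AA, BACKGROUND, encode
from .config import PhmmConfig
from .evd import EVDParams, evalue_from_score, fit_gumbel
from .msa import GAP, Alignment
from .seqio import ProteinRecord

LOG2 = np.log(2.0)
# "log zero" kept finite so the DP never forms inf - inf (NaN); exp(NEG)
# underflows to exactly 0, so the semantics of an impossible path survive
NEG = -1.0e30


@dataclass(frozen=True)
class CalibrationParams:
    """Gumbel null-score parameters from random-sequence calibration."""

    mu: float
    lam: float
    n_samples: int
    sample_length: int
    seed: int

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")

    @property
    def beta(self) -> float:
        return 1.0 / self.lam


@dataclass(frozen=True)
class ProfileHit:
    sequence_id: str
    cluster_id: str
    log_odds_score: float  # bits
    evalue: float

    def __post_init__(self):
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")


@dataclass
class ProfileHMM:
    """Per-cluster probabilistic motif model (match/insert/delete chain).

    All probability vectors are normalized; emissions are pseudocounted
    and strictly positive when built from an alignment. ``length`` is the
    number of match states. Transition arrays are indexed by 0-based match
    node; entries at the last node that have no successor are zero.
    """

    cluster_id: str
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (20,)
    background: np.ndarray  # (20,)
    entry: np.ndarray  # (L,)  B -> M_k
    exit_: np.ndarray  # (L,)  M_k -> E
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray  # D_k -> M_{k+1}; D at the last node exits with prob 1
    t_dd: np.ndarray
    p_nn: float = 350.0 / 351.0
    p_cc: float = 350.0 / 351.0
    calibration: CalibrationParams | None = None

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        L = self.length
        if L < 1:
            raise ValueError("profile HMM needs >= 1 match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=atol):
            raise ValueError("match emissions must normalize to 1")
        for vec, name in ((self.insert_emissions, "insert_emissions"),
                          (self.background, "background"), (self.entry, "entry")):
            if not np.isclose(vec.sum(), 1.0, atol=atol):
                raise ValueError(f"{name} must normalize to 1")
        out = self.t_mm + self.t_mi + self.t_md + self.exit_
        if not np.allclose(out, 1.0, atol=atol):
            raise ValueError("match-state outgoing probabilities must sum to 1")
        if L > 1:
            if not np.allclose((self.t_im + self.t_ii)[:-1], 1.0, atol=atol):
                raise ValueError("insert-state outgoing probabilities must sum to 1")
            if not np.allclose((self.t_dm + self.t_dd)[:-1], 1.0, atol=atol):
                raise ValueError("delete-state outgoing probabilities must sum to 1")
        if not (0 <= self.p_nn < 1 and 0 <= self.p_cc < 1):
            raise ValueError("flank self-loop probabilities must be in [0, 1)")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "cluster_id": self.cluster_id,
            "alphabet": AA,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "background": self.background.tolist(),
            "entry": self.entry.tolist(),
            "exit": self.exit_.tolist(),
            "t_mm": self.t_mm.tolist(),
            "t_mi": self.t_mi.tolist(),
            "t_md": self.t_md.tolist(),
            "t_im": self.t_im.tolist(),
            "t_ii": self.t_ii.tolist(),
            "t_dm": self.t_dm.tolist(),
            "t_dd": self.t_dd.tolist(),
            "p_nn": self.p_nn,
            "p_cc": self.p_cc,
        }
        if self.calibration is not None:
            d["calibration"] = {
                "mu": self.calibration.mu,
                "lambda": self.calibration.lam,
                "n_samples": self.calibration.n_samples,
                "sample_length": self.calibration.sample_length,
                "seed": self.calibration.seed,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHMM":
        calib = None
        if "calibration" in d:
            c = d["calibration"]
            calib = CalibrationParams(
                mu=c["mu"], lam=c["lambda"], n_samples=c["n_samples"],
                sample_length=c["sample_length"], seed=c["seed"],
            )
        return cls(
            cluster_id=d["cluster_id"],
            match_emissions=np.array(d["match_emissions"]),
            insert_emissions=np.array(d["insert_emissions"]),
            background=np.array(d["background"]),
            entry=np.array(d["entry"]),
            exit_=np.array(d["exit"]),
            t_mm=np.array(d["t_mm"]),
            t_mi=np.array(d["t_mi"]),
            t_md=np.array(d["t_md"]),
            t_im=np.array(d["t_im"]),
            t_ii=np.array(d["t_ii"]),
            t_dm=np.array(d["t_dm"]),
            t_dd=np.array(d["t_dd"]),
            p_nn=d["p_nn"],
            p_cc=d["p_cc"],
            calibration=calib,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHMM":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# model construction


def _henikoff_weights(rows: list[str], keep: np.ndarray) -> np.ndarray:
    """Position-based sequence weights over retained columns."""
    n = len(rows)
    w = np.zeros(n)
    for j in np.flatnonzero(keep):
        col = [r[j] for r in rows]
        residues = [c for c in col if c != GAP]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for i, c in enumerate(col):
            if c != GAP:
                w[i] += 1.0 / (r * counts[c])
    if w.sum() <= 0:
        w[:] = 1.0
    return w * (n / w.sum())


def build_profile_hmm(
    aln: Alignment,
    pseudocount_weight: float = 1.0,
    cluster_id: str = "",
    config: PhmmConfig | None = None,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Compile a pruned alignment into a profile HMM.

    Match states are the retained columns. Emissions are Henikoff-weighted
    residue counts mixed with ``pseudocount_weight`` parts background;
    transitions come from the observed gap structure with Laplace
    pseudocounts. Residues in removed columns count as insertions between
    the flanking match states; residues outside the first/last retained
    column belong to the N/C flanks and are not counted.
    """
    cfg = config or PhmmConfig()
    if config is not None:
        pseudocount_weight = config.pseudocount_weight
    bg = BACKGROUND if background is None else np.asarray(background, dtype=float)
    keep = np.asarray(aln.column_mask, dtype=bool)
    match_cols = np.flatnonzero(keep)
    L = match_cols.size
    if L == 0:
        raise ValueError("alignment has zero retained columns")

    rows = aln.rows
    weights = _henikoff_weights(rows, keep)

    counts = np.zeros((L, 20))
    for k, j in enumerate(match_cols):
        for i, row in enumerate(rows):
            c = row[j]
            if c == GAP:
                continue
            code = encode(c)[0]
            if code < 20:
                counts[k, code] += weights[i]
            else:  # X spreads over the background
                counts[k] += weights[i] * bg
    emis = counts + pseudocount_weight * bg
    emis /= emis.sum(axis=1, keepdims=True)

    # transition counts between consecutive match nodes
    c_mm = np.zeros(L); c_mi = np.zeros(L); c_md = np.zeros(L)
    c_im = np.zeros(L); c_ii = np.zeros(L)
    c_dm = np.zeros(L); c_dd = np.zeros(L)
    col_to_node = {j: k for k, j in enumerate(match_cols)}
    first_col, last_col = match_cols[0], match_cols[-1]
    for i, row in enumerate(rows):
        wgt = weights[i]
        path: list[tuple[str, int]] = []
        for j in range(first_col, last_col + 1):
            c = row[j]
            if j in col_to_node:
                path.append(("M" if c != GAP else "D", col_to_node[j]))
            elif c != GAP:
                path.append(("I", col_to_node_before(col_to_node, match_cols, j)))
        # local entry/exit: trim leading and trailing deletions
        while path and path[0][0] == "D":
            path.pop(0)
        while path and path[-1][0] == "D":
            path.pop()
        # I->D and D->I are not representable in the architecture and are
        # dropped; Laplace pseudocounts keep every legal transition live.
        tables = {
            "M": {"M": c_mm, "I": c_mi, "D": c_md},
            "I": {"M": c_im, "I": c_ii},
            "D": {"M": c_dm, "D": c_dd},
        }
        for (s1, k1), (s2, _k2) in zip(path, path[1:]):
            table = tables[s1].get(s2)
            if table is not None:
                table[k1] += wgt

    eps = cfg.exit_prob if L > 1 else 0.0
    t_mm = np.zeros(L); t_mi = np.zeros(L); t_md = np.zeros(L)
    exit_ = np.zeros(L)
    for k in range(L - 1):
        tot = (c_mm[k] + 1) + (c_mi[k] + 1) + (c_md[k] + 1)
        t_mm[k] = (1 - eps) * (c_mm[k] + 1) / tot
        t_mi[k] = (1 - eps) * (c_mi[k] + 1) / tot
        t_md[k] = (1 - eps) * (c_md[k] + 1) / tot
        exit_[k] = eps
    exit_[L - 1] = 1.0

    t_im = np.zeros(L); t_ii = np.zeros(L)
    t_dm = np.zeros(L); t_dd = np.zeros(L)
    for k in range(L - 1):
        tot = (c_im[k] + 1) + (c_ii[k] + 1)
        t_im[k] = (c_im[k] + 1) / tot
        t_ii[k] = (c_ii[k] + 1) / tot
        tot = (c_dm[k] + 1) + (c_dd[k] + 1)
        t_dm[k] = (c_dm[k] + 1) / tot
        t_dd[k] = (c_dd[k] + 1) / tot

    hmm = ProfileHMM(
        cluster_id=cluster_id or "-",
        match_emissions=emis,
        insert_emissions=bg.copy(),
        background=bg.copy(),
        entry=np.full(L, 1.0 / L),
        exit_=exit_,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
        p_nn=cfg.p_loop, p_cc=cfg.p_loop,
    )
    hmm.validate()
    return hmm


def col_to_node_before(col_to_node, match_cols, j) -> int:
    """Match node index whose insert state hosts residues at column j."""
    idx = int(np.searchsorted(match_cols, j) - 1)
    return max(idx, 0)


# ---------------------------------------------------------------------------
# scoring (batched Forward/Viterbi over equal-length sequences)


def _log(x: np.ndarray | float) -> np.ndarray | float:
    """Elementwise log with zeros mapped to the finite NEG sentinel."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(x > 0, np.log(np.maximum(x, 1e-320)), NEG)
    return out if out.ndim else float(out)


def _null_logprob(hmm: ProfileHMM, X: np.ndarray) -> np.ndarray:
    """Background null with the same geometric length model as the flanks."""
    n = X.shape[1]
    lf = np.append(_log(hmm.background), 0.0)
    return lf[X].sum(axis=1) + n * _log(hmm.p_nn) + _log(1.0 - hmm.p_nn)


def _logprob_batch(hmm: ProfileHMM, X: np.ndarray, forward: bool) -> np.ndarray:
    """Model log-probability for a (n_seqs, seq_len) integer code batch.

    Forward sums over all state paths; Viterbi returns the best path's
    log-probability. Code 20 (X) emits with log-probability 0 on both the
    model and the null side, so it cancels from any log-odds score.
    """
    ns, n = X.shape
    L = hmm.length
    lf = np.append(_log(hmm.background), 0.0)  # X: cancels against null
    lem = np.concatenate(
        [_log(hmm.match_emissions), np.zeros((L, 1))], axis=1
    )
    lem[:, 20] = lf[20]  # X emits "background" on both sides
    # insert emission = background by construction -> same lf table
    l_entry = _log(hmm.entry)
    l_exit = _log(hmm.exit_)
    l_mm = _log(hmm.t_mm); l_mi = _log(hmm.t_mi); l_md = _log(hmm.t_md)
    l_im = _log(hmm.t_im); l_ii = _log(hmm.t_ii)
    l_dm = _log(hmm.t_dm); l_dd = _log(hmm.t_dd)
    l_pnn = _log(hmm.p_nn) if hmm.p_nn > 0 else NEG
    l_pcc = _log(hmm.p_cc) if hmm.p_cc > 0 else NEG
    l_qnn = _log(1.0 - hmm.p_nn)
    l_qcc = _log(1.0 - hmm.p_cc)

    comb = np.logaddexp if forward else np.maximum

    def chain(a, off):
        # silent delete chain within one position: D_k from M_{k-1}, D_{k-1}
        out = np.empty_like(a)
        out[:, 0] = a[:, 0]
        for k in range(1, a.shape[1]):
            out[:, k] = comb(a[:, k], out[:, k - 1] + off[k - 1])
        return out

    M = np.full((ns, L), NEG)
    I = np.full((ns, L), NEG)
    D = np.full((ns, L), NEG)
    logN = np.zeros(ns)
    logC = np.full(ns, NEG)
    lf_x = lf[X]  # (ns, n) flank/insert emission log-probs

    for i in range(n):
        xi = X[:, i]
        logB = logN + l_qnn
        # match: from B, M_{k-1}, I_{k-1}, D_{k-1}
        prev_m = np.concatenate([np.full((ns, 1), NEG), M[:, :-1] + l_mm[:-1]], axis=1)
        prev_i = np.concatenate([np.full((ns, 1), NEG), I[:, :-1] + l_im[:-1]], axis=1)
        prev_d = np.concatenate([np.full((ns, 1), NEG), D[:, :-1] + l_dm[:-1]], axis=1)
        new_m = comb(comb(logB[:, None] + l_entry[None, :], prev_m),
                     comb(prev_i, prev_d))
        new_m = new_m + lem[:, xi].T
        new_i = comb(M + l_mi[None, :], I + l_ii[None, :]) + lf_x[:, i][:, None]
        # delete chain (same position, silent): D_k from M_{k-1}, D_{k-1}
        a = np.concatenate([np.full((ns, 1), NEG), new_m[:, :-1] + l_md[:-1]], axis=1)
        new_d = chain(a, l_dd)
        logE = comb(
            _reduce(comb, new_m + l_exit[None, :]),
            new_d[:, L - 1],
        )
        logC = comb(logC + l_pcc + lf_x[:, i], logE)
        logN = logN + l_pnn + lf_x[:, i]
        M, I, D = new_m, new_i, new_d

    return logC + l_qcc


def _score_batch(hmm: ProfileHMM, X: np.ndarray, forward: bool) -> np.ndarray:
    """Log-odds bits against the background null for a code batch."""
    return (_logprob_batch(hmm, X, forward) - _null_logprob(hmm, X)) / LOG2


def _reduce(comb, arr):
    if comb is np.logaddexp:
        from scipy.special import logsumexp
        return logsumexp(arr, axis=1)
    return arr.max(axis=1)


def _scores(hmm: ProfileHMM, seq: str, forward: bool) -> float:
    if not seq:
        raise ValueError("sequence must be non-empty")
    codes = encode(seq)
    return float(_score_batch(hmm, codes[None, :], forward=forward)[0])


def forward_score(hmm: ProfileHMM, seq: str) -> float:
    """log2 P(seq|hmm) / P(seq|null), summed over all alignments."""
    return _scores(hmm, seq, forward=True)


def viterbi_score(hmm: ProfileHMM, seq: str) -> float:
    """log2 odds of the single best alignment; always <= forward_score."""
    return _scores(hmm, seq, forward=False)


def log_probability(hmm: ProfileHMM, seq: str) -> float:
    """Natural-log joint probability P(seq | hmm) (forward algorithm)."""
    codes = encode(seq)
    return float(_logprob_batch(hmm, codes[None, :], forward=True)[0])


# ---------------------------------------------------------------------------
# calibration and search


def calibrate_hmm(
    hmm: ProfileHMM,
    n_samples: int = 1000,
    sample_length: int = 350,
    seed: int = 0,
    use_forward: bool = False,
    config: PhmmConfig | None = None,
) -> CalibrationParams:
    """Fit a Gumbel to scores of random background sequences.

    The fitted parameters are stored on the model (``hmm.calibration``)
    and returned. Deterministic given the seed.
    """
    if config is not None:
        n_samples = config.calib_samples
        sample_length = config.calib_length
        use_forward = config.use_forward
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = np.random.default_rng(seed)
    X = rng.choice(20, size=(n_samples, sample_length), p=hmm.background)
    scores = _score_batch(hmm, X, forward=use_forward)
    evd = fit_gumbel(scores, n_samples=n_samples, seed=seed)
    params = CalibrationParams(mu=evd.mu, lam=evd.lam, n_samples=n_samples,
                               sample_length=sample_length, seed=seed)
    hmm.calibration = params
    return params


def hmm_evalue(hmm: ProfileHMM, score: float, n_targets: int) -> float:
    if hmm.calibration is None:
        raise ValueError(f"HMM {hmm.cluster_id!r} is not calibrated")
    evd = EVDParams(mu=hmm.calibration.mu, lam=hmm.calibration.lam)
    return evalue_from_score(score, evd, n_targets)


def hmm_search(
    hmms: Sequence[ProfileHMM],
    seqs: Sequence[ProteinRecord],
    evalue_cutoff: float = 0.01,
    use_forward: bool = False,
) -> list[ProfileHit]:
    """Score every sequence against every calibrated profile.

    E-values use ``n = len(seqs)`` (the database size of the search).
    Hits with E <= cutoff are returned sorted by E, ties broken by
    (sequence_id, cluster_id).
    """
    for h in hmms:
        if h.calibration is None:
            raise ValueError(f"HMM {h.cluster_id!r} is not calibrated")
    if not seqs:
        return []
    n = len(seqs)
    # batch sequences of equal length through the vectorized DP
    by_len: dict[int, list[ProteinRecord]] = {}
    for rec in seqs:
        by_len.setdefault(rec.length, []).append(rec)
    hits: list[ProfileHit] = []
    for h in hmms:
        for _length, group in by_len.items():
            X = np.stack([encode(r.sequence) for r in group])
            scores = _score_batch(h, X, forward=use_forward)
            for rec, s in zip(group, scores):
                e = hmm_evalue(h, float(s), n)
                if e <= evalue_cutoff:
                    hits.append(ProfileHit(sequence_id=rec.id,
                                           cluster_id=h.cluster_id,
                                           log_odds_score=float(s), evalue=e))
    hits.sort(key=lambda t: (t.evalue, t.sequence_id, t.cluster_id))
    return hits


# ---------------------------------------------------------------------------
# profile-profile comparison


def _coemission_matrix(h1: ProfileHMM, h2: ProfileHMM) -> np.ndarray:
    inv_f = 1.0 / h1.background
    co = h1.match_emissions @ (h2.match_emissions * inv_f[None, :]).T
    with np.errstate(divide="ignore"):
        return np.where(co > 0, np.log2(np.maximum(co, 1e-320)), NEG)


def profile_profile_score(
    h1: ProfileHMM,
    h2: ProfileHMM,
    gap_open: float = 4.0,
    gap_extend: float = 0.5,
    config: PhmmConfig | None = None,
    with_pairs: bool = False,
):
    """Local profile-profile alignment score over co-emission columns.

    Exactly symmetric: the operand order is canonicalized internally
    before the dynamic program runs. Returns the score (floored at 0), or
    ``(score, aligned match-state pairs)`` with ``with_pairs``.
    """
    if config is not None:
        gap_open = config.pp_gap_open
        gap_extend = config.pp_gap_extend
    swapped = (h2.length, h2.cluster_id) < (h1.length, h1.cluster_id)
    a, b = (h2, h1) if swapped else (h1, h2)
    s = _coemission_matrix(a, b)
    la, lb = s.shape
    H = np.zeros((la + 1, lb + 1))
    E = np.full((la + 1, lb + 1), -np.inf)  # gap in b
    F = np.full((la + 1, lb + 1), -np.inf)  # gap in a
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 stop 1 diag 2 up 3 left
    best = 0.0
    best_ij = (0, 0)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i, j] = max(H[i - 1, j] - gap_open, E[i - 1, j] - gap_extend)
            F[i, j] = max(H[i, j - 1] - gap_open, F[i, j - 1] - gap_extend)
            diag = H[i - 1, j - 1] + s[i - 1, j - 1]
            h = max(0.0, diag, E[i, j], F[i, j])
            H[i, j] = h
            if h <= 0:
                ptr[i, j] = 0
            elif h == diag:
                ptr[i, j] = 1
            elif h == E[i, j]:
                ptr[i, j] = 2
            else:
                ptr[i, j] = 3
            if h > best:
                best = h
                best_ij = (i, j)
    if not with_pairs:
        return float(best)
    pairs: list[tuple[int, int]] = []
    i, j = best_ij
    while i > 0 and j > 0 and ptr[i, j] != 0:
        if ptr[i, j] == 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif ptr[i, j] == 2:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    if swapped:
        pairs = [(q, p) for p, q in pairs]
    return float(best), pairs


def shuffle_profile(hmm: ProfileHMM, rng: np.random.Generator) -> ProfileHMM:
    """Decoy profile: match columns permuted, everything else untouched."""
    perm = rng.permutation(hmm.length)
    return ProfileHMM(
        cluster_id=hmm.cluster_id + ":shuffled",
        match_emissions=hmm.match_emissions[perm].copy(),
        insert_emissions=hmm.insert_emissions.copy(),
        background=hmm.background.copy(),
        entry=hmm.entry.copy(), exit_=hmm.exit_.copy(),
        t_mm=hmm.t_mm.copy(), t_mi=hmm.t_mi.copy(), t_md=hmm.t_md.copy(),
        t_im=hmm.t_im.copy(), t_ii=hmm.t_ii.copy(),
        t_dm=hmm.t_dm.copy(), t_dd=hmm.t_dd.copy(),
        p_nn=hmm.p_nn, p_cc=hmm.p_cc,
    )


def calibrate_profile_scores(
    hmms: Sequence[ProfileHMM],
    n_decoys: int = 200,
    seed: int = 0,
    config: PhmmConfig | None = None,
) -> EVDParams:
    """Gumbel null for profile-profile scores from column-shuffled decoys.

    Each decoy comparison scores one real profile against a
    column-shuffled copy of a different (or, with one profile, the same)
    profile, destroying column order while preserving composition.
    """
    cfg = config or PhmmConfig()
    if config is not None:
        n_decoys = config.pp_decoys
    if not hmms:
        raise ValueError("need at least one profile")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    for k in range(n_decoys):
        i = int(rng.integers(len(hmms)))
        j = int(rng.integers(len(hmms)))
        scores[k] = profile_profile_score(hmms[i], shuffle_profile(hmms[j], rng),
                                          config=cfg)
    if np.ptp(scores) == 0:
        raise ValueError("degenerate profile-score null; increase n_decoys")
    return fit_gumbel(scores, n_samples=n_decoys, seed=seed)
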