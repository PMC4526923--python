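"""End-to-end orchestration: clusters -> HMMs -> families -> screening.

The discovery pipeline mirrors the published protocol:

1. keep proteins < 200 aa with a predicted signal peptide;
2. all-vs-all local alignment of the last 50 residues (BLOSUM50),
   E-values by Gumbel calibration, similarity graph at E <= 1e-3;
3. Markov clustering (inflation 1.5) into first-level clusters;
4. per cluster: progressive alignment, BLOSUM62 column pruning, profile
   HMM build + calibration;
5. iterative singleton recruitment: unclustered sequences are searched
   against all cluster HMMs, the best hits join their cluster, affected
   models are rebuilt, until a round recruits nobody;
6. profile-profile comparison of all cluster HMMs, second Markov
   clustering of the resulting E-value graph: linked clusters form
   families;
7. arbitrary (pre-filtered) proteomes are screened against each family's
   representative HMM at E <= 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import mcl as mcl_mod
from . import msa as msa_mod
from . import pairwise as pw_mod
from . import phmm as phmm_mod
from .config import PipelineConfig
from .evd import evalue_from_score
from .msa import Alignment, NoConservedRegionError
from .seqio import CTerminalSegment, ProteinRecord, extract_cterm_all, filter_by_length
from .sigpep import predict_signal

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    """A first-level cluster (c#) with its alignment and profile HMM."""

    id: str
    member_ids: list[str]
    alignment: Alignment | None = None
    hmm: phmm_mod.ProfileHMM | None = None
    history: list[tuple[int, list[str]]] = field(default_factory=list)
    flagged: str | None = None  # e.g. "no conserved region"

    @property
    def numeric_id(self) -> int:
        return int(self.id.lstrip("c"))


@dataclass
class Family:
    """A second-level family (f#): clusters linked by profile comparison."""

    id: str
    cluster_ids: list[str]
    representative_cluster: str
    consensus: str
    information_content: np.ndarray = field(repr=False, default=None)
    member_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class PipelineResult:
    clusters: list[Cluster]
    singletons: list[str]
    families: list[Family]
    n_input: int = 0
    n_short: int = 0
    n_signal: int = 0
    recruitment_rounds: int = 0

    def family_labels(self) -> dict[str, str]:
        """protein id -> family id, or "singleton"."""
        by_cluster = {c.id: c for c in self.clusters}
        out = {s: "singleton" for s in self.singletons}
        assigned = set()
        for fam in self.families:
            for cid in fam.cluster_ids:
                for mid in by_cluster[cid].member_ids:
                    out[mid] = fam.id
                    assigned.add(cid)
        for c in self.clusters:  # clusters excluded from family assembly
            if c.id not in assigned:
                for mid in c.member_ids:
                    out[mid] = f"unassembled:{c.id}"
        return out


# ---------------------------------------------------------------------------
# cluster model building


def _build_cluster_model(
    cluster: Cluster,
    segments_by_id: Mapping[str, CTerminalSegment],
    config: PipelineConfig,
    seed: int,
) -> None:
    """Align, prune, build and calibrate one cluster's HMM (in place)."""
    segs = [segments_by_id[m] for m in cluster.member_ids]
    tree = msa_mod.upgma_guide_tree(segs, config.msa)
    aln = msa_mod.progressive_align(segs, tree, config.msa)
    try:
        aln = msa_mod.prune_columns(aln, config=config.msa)
    except NoConservedRegionError:
        cluster.alignment = aln
        cluster.hmm = None
        cluster.flagged = "no conserved region"
        logger.warning("cluster %s flagged: no conserved region", cluster.id)
        return
    cluster.alignment = aln
    cluster.flagged = None
    hmm = phmm_mod.build_profile_hmm(aln, cluster_id=cluster.id, config=config.phmm)
    phmm_mod.calibrate_hmm(
        hmm,
        n_samples=config.phmm.calib_samples,
        sample_length=config.phmm.calib_length,
        seed=(seed + 7919 * cluster.numeric_id) % (2**31 - 1),
        use_forward=config.phmm.use_forward,
    )
    cluster.hmm = hmm


def build_clusters(
    clustering: mcl_mod.Clustering,
    segments: Sequence[CTerminalSegment],
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[list[Cluster], list[str]]:
    """Materialize MCL clusters into aligned, calibrated Cluster objects."""
    cfg = config or PipelineConfig()
    by_id = {s.parent_id: s for s in segments}
    clusters = []
    for k, members in enumerate(clustering.clusters, start=1):
        c = Cluster(id=f"c{k}", member_ids=sorted(members),
                    history=[(0, sorted(members))])
        _build_cluster_model(c, by_id, cfg, seed)
        clusters.append(c)
    return clusters, sorted(clustering.singletons)


# ---------------------------------------------------------------------------
# singleton recruitment


def recruit_singletons(
    clusters: list[Cluster],
    singletons: Sequence[str],
    segments: Sequence[CTerminalSegment],
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[list[Cluster], list[str], int]:
    """Iteratively recruit singletons into the cluster that scores them best.

    Each round searches all remaining singletons against all cluster HMMs;
    a singleton with a hit at E <= the recruitment cutoff joins its
    best-E cluster (ties -> lower cluster id). Affected clusters are
    realigned, re-pruned, rebuilt and recalibrated before the next round.
    Stops when a round recruits nobody or after ``recruit_max_rounds``
    (with a warning). Cluster membership only ever grows.
    """
    cfg = config or PipelineConfig()
    by_id = {s.parent_id: s for s in segments}
    remaining = sorted(singletons)
    rounds = 0
    while remaining and rounds < cfg.pipeline.recruit_max_rounds:
        live = [c for c in clusters if c.hmm is not None]
        if not live:
            break
        records = [ProteinRecord(id=r, sequence=by_id[r].sequence) for r in remaining]
        hits = phmm_mod.hmm_search(
            [c.hmm for c in live], records,
            evalue_cutoff=cfg.pipeline.recruit_evalue,
            use_forward=cfg.phmm.use_forward,
        )
        best: dict[str, tuple[float, int, str]] = {}
        cluster_rank = {c.id: c.numeric_id for c in live}
        for h in hits:
            key = (h.evalue, cluster_rank[h.cluster_id], h.cluster_id)
            if h.sequence_id not in best or key < best[h.sequence_id]:
                best[h.sequence_id] = key
        if not best:
            break
        rounds += 1
        recruits_by_cluster: dict[str, list[str]] = {}
        for sid, (_e, _rank, cid) in sorted(best.items()):
            recruits_by_cluster.setdefault(cid, []).append(sid)
        for c in clusters:
            added = recruits_by_cluster.get(c.id)
            if not added:
                continue
            c.member_ids = sorted(set(c.member_ids) | set(added))
            c.history.append((rounds, sorted(added)))
            _build_cluster_model(c, by_id, cfg, seed)
        recruited = set(best)
        remaining = [r for r in remaining if r not in recruited]
        logger.info("recruitment round %d: %d sequences joined", rounds, len(recruited))
    if remaining and rounds >= cfg.pipeline.recruit_max_rounds:
        logger.warning("recruitment stopped at max_rounds=%d with candidates left",
                       rounds)
    return clusters, remaining, rounds


# ---------------------------------------------------------------------------
# family assembly (profile-level MCL)


def assemble_families(
    clusters: Sequence[Cluster],
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> list[Family]:
    """Aggregate clusters into families via profile-profile comparison.

    All cluster HMM pairs are scored with the co-emission local alignment;
    E-values come from a Gumbel fit on column-shuffled decoy profiles with
    ``n = number of pairs``. Pairs at E <= the link cutoff become edges
    (weight -log10 E) of a graph that is Markov-clustered at the family
    inflation; every resulting group — and every unlinked cluster — is one
    family, labelled f1, f2, ... by decreasing member count.
    """
    cfg = config or PipelineConfig()
    live = [c for c in clusters if c.hmm is not None]
    if not live:
        raise ValueError("no clusters with profile HMMs to assemble")
    hmms = {c.id: c.hmm for c in live}
    ids = sorted(hmms, key=lambda cid: int(cid.lstrip("c")))
    n = len(ids)
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    if n > 1:
        evd = phmm_mod.calibrate_profile_scores(
            [hmms[i] for i in ids], n_decoys=cfg.phmm.pp_decoys, seed=seed,
            config=cfg.phmm,
        )
        n_pairs = n * (n - 1) // 2
        for a in range(n):
            for b in range(a + 1, n):
                s = phmm_mod.profile_profile_score(
                    hmms[ids[a]], hmms[ids[b]], config=cfg.phmm
                )
                e = evalue_from_score(s, evd, n_pairs)
                if e <= cfg.pipeline.prc_evalue:
                    w = min(200.0, -np.log10(e))
                    graph.add_edge(ids[a], ids[b], weight=w)
    clustering = mcl_mod.mcl_cluster(
        graph,
        inflation=cfg.pipeline.family_inflation,
        expansion=cfg.mcl.expansion,
        prune_below=cfg.mcl.prune_below,
        max_iter=cfg.mcl.max_iter,
        tol=cfg.mcl.tol,
    )
    groups = [list(g) for g in clustering.clusters]
    groups += [[s] for s in clustering.singletons]

    by_id = {c.id: c for c in live}
    built = []
    for grp in groups:
        members: list[str] = []
        for cid in grp:
            members.extend(by_id[cid].member_ids)
        rep = max(grp, key=lambda cid: (len(by_id[cid].member_ids),
                                        -int(cid.lstrip("c"))))
        built.append((sorted(grp, key=lambda c: int(c.lstrip("c"))), rep,
                      sorted(members)))
    built.sort(key=lambda t: (-len(t[2]), int(t[1].lstrip("c"))))
    families = []
    for k, (grp, rep, members) in enumerate(built, start=1):
        consensus, info = consensus_motif_from_hmm(by_id[rep].hmm)
        families.append(Family(
            id=f"f{k}", cluster_ids=grp, representative_cluster=rep,
            consensus=consensus, information_content=info, member_ids=members,
        ))
    return families


def consensus_motif_from_hmm(hmm: phmm_mod.ProfileHMM) -> tuple[str, np.ndarray]:
    """Consensus string + per-position information content (bits).

    Per match state, the consensus residue is the emission argmax;
    information content is log2(20) - H(emissions), and the letter is
    uppercase iff the position carries >= 1 bit.
    """
    from .alphabet import AA

    emis = hmm.match_emissions
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(emis > 0, emis * np.log2(emis), 0.0)
    info = np.log2(20.0) + plogp.sum(axis=1)
    info = np.clip(info, 0.0, np.log2(20.0))
    letters = []
    for k in range(hmm.length):
        c = AA[int(np.argmax(emis[k]))]
        letters.append(c if info[k] >= 1.0 else c.lower())
    return "".join(letters), info


def consensus_motif(family: Family, clusters: Sequence[Cluster]) -> tuple[str, np.ndarray]:
    by_id = {c.id: c for c in clusters}
    rep = by_id[family.representative_cluster]
    if rep.hmm is None:
        raise ValueError(f"representative cluster {rep.id} has no HMM")
    return consensus_motif_from_hmm(rep.hmm)


# ---------------------------------------------------------------------------
# screening arbitrary proteomes


@dataclass
class ScreenResult:
    assignments: pd.DataFrame  # id, species, family, score, evalue
    matrix: pd.DataFrame  # species x family counts
    n_unassigned: int


def screen_proteomes(
    families: Sequence[Family],
    clusters: Sequence[Cluster],
    proteomes: Sequence[ProteinRecord],
    evalue_cutoff: float = 0.05,
    config: PipelineConfig | None = None,
) -> ScreenResult:
    """Assign each (pre-filtered) protein to its best-scoring family.

    Each protein is scored against every family's representative HMM;
    it is assigned to the best family iff that E-value (n = number of
    proteins screened) passes the cutoff. The species x family matrix
    tallies assigned proteins only; each protein counts at most once.
    """
    cfg = config or PipelineConfig()
    if config is not None:
        evalue_cutoff = cfg.pipeline.screen_evalue
    if not families:
        raise ValueError("empty family library")
    by_id = {c.id: c for c in clusters}
    reps = {}
    for fam in families:
        hmm = by_id[fam.representative_cluster].hmm
        if hmm is None or hmm.calibration is None:
            raise ValueError(f"family {fam.id} lacks a calibrated representative HMM")
        reps[fam.id] = hmm
    n = len(proteomes)
    rows = []
    n_unassigned = 0
    species_seen = []
    for rec in proteomes:
        if rec.species not in species_seen:
            species_seen.append(rec.species)
        best = None
        for fid in sorted(reps, key=lambda f: int(f.lstrip("f"))):
            hmm = reps[fid]
            s = (phmm_mod.forward_score(hmm, rec.sequence)
                 if cfg.phmm.use_forward else phmm_mod.viterbi_score(hmm, rec.sequence))
            e = phmm_mod.hmm_evalue(hmm, s, max(n, 1))
            if best is None or (e, fid) < (best[2], best[0]):
                best = (fid, s, e)
        fid, s, e = best
        if e <= evalue_cutoff:
            rows.append({"id": rec.id, "species": rec.species, "family": fid,
                         "score": s, "evalue": e})
        else:
            n_unassigned += 1
            rows.append({"id": rec.id, "species": rec.species, "family": "",
                         "score": s, "evalue": e})
    assignments = pd.DataFrame(
        rows, columns=["id", "species", "family", "score", "evalue"]
    )
    fam_ids = [f.id for f in families]
    matrix = pd.DataFrame(0, index=sorted(set(species_seen)), columns=fam_ids)
    assigned = assignments[assignments["family"] != ""]
    for (sp, fid), grp in assigned.groupby(["species", "family"]):
        matrix.loc[sp, fid] = len(grp)
    return ScreenResult(assignments=assignments, matrix=matrix,
                        n_unassigned=n_unassigned)


# ---------------------------------------------------------------------------
# evaluation


def _pair_sets(labels: Mapping[str, str]) -> set[frozenset]:
    by_label: dict[str, list[str]] = {}
    for k, v in labels.items():
        by_label.setdefault(v, []).append(k)
    pairs = set()
    for members in by_label.values():
        members = sorted(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add(frozenset((members[i], members[j])))
    return pairs


def expand_singleton_labels(labels: Mapping[str, str],
                            singleton_markers=("singleton", "decoy")) -> dict[str, str]:
    """Give every marker-labelled id its own unique class."""
    out = {}
    for k, v in labels.items():
        out[k] = f"_single:{k}" if v in singleton_markers else v
    return out


def evaluate_clustering(
    predicted: Mapping[str, str], truth: Mapping[str, str]
) -> dict[str, float]:
    """ARI + pairwise precision/recall of a predicted partition vs truth.

    "singleton" (predicted) and "decoy" (truth) labels are expanded to
    per-id classes first: a decoy correctly left alone is an agreement,
    not a cluster of decoys.
    """
    if set(predicted) != set(truth):
        raise ValueError("predicted and truth must label the same ids")
    pred = expand_singleton_labels(predicted)
    true = expand_singleton_labels(truth)
    ids = sorted(pred)
    ari = float(adjusted_rand_score([true[i] for i in ids], [pred[i] for i in ids]))
    p_pairs = _pair_sets(pred)
    t_pairs = _pair_sets(true)
    tp = len(p_pairs & t_pairs)
    precision = tp / len(p_pairs) if p_pairs else 0.0
    recall = tp / len(t_pairs) if t_pairs else 0.0
    return {"ARI": ari, "pair_precision": precision, "pair_recall": recall}


# ---------------------------------------------------------------------------
# end-to-end


def save_library(result: PipelineResult, outdir) -> None:
    """Write the discovery state as text: clusters TSV, Stockholm
    alignments, JSON profiles, and a families JSON."""
    import json
    from pathlib import Path

    out = Path(outdir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    (out / "profiles").mkdir(parents=True, exist_ok=True)
    rows = []
    for c in result.clusters:
        for m in c.member_ids:
            rows.append({"node_id": m, "cluster_id": c.id})
        if c.alignment is not None:
            msa_mod.write_stockholm(c.alignment, out / "alignments" / f"{c.id}.sto",
                                    name=c.id)
        if c.hmm is not None:
            c.hmm.to_json(out / "profiles" / f"{c.id}.json")
    for s in result.singletons:
        rows.append({"node_id": s, "cluster_id": "singleton"})
    pd.DataFrame(rows, columns=["node_id", "cluster_id"]).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    fams = {
        f.id: {
            "clusters": f.cluster_ids,
            "representative": f.representative_cluster,
            "consensus": f.consensus,
            "information_content": [round(float(x), 6)
                                    for x in f.information_content],
            "members": f.member_ids,
        }
        for f in result.families
    }
    (out / "families.json").write_text(json.dumps(fams, indent=1))


def load_library(libdir) -> tuple[list[Cluster], list[Family]]:
    """Load clusters (with profiles) and families written by save_library."""
    import json
    from pathlib import Path

    lib = Path(libdir)
    df = pd.read_csv(lib / "clusters.tsv", sep="\t")
    members: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        if row.cluster_id != "singleton":
            members.setdefault(str(row.cluster_id), []).append(str(row.node_id))
    clusters = []
    for cid in sorted(members, key=lambda c: int(c.lstrip("c"))):
        c = Cluster(id=cid, member_ids=sorted(members[cid]))
        sto = lib / "alignments" / f"{cid}.sto"
        if sto.exists():
            c.alignment = msa_mod.read_stockholm(sto)
        pj = lib / "profiles" / f"{cid}.json"
        if pj.exists():
            c.hmm = phmm_mod.ProfileHMM.from_json(pj)
        clusters.append(c)
    families = []
    fams_path = lib / "families.json"
    if fams_path.exists():
        fams = json.loads(fams_path.read_text())
        for fid in sorted(fams, key=lambda f: int(f.lstrip("f"))):
            d = fams[fid]
            families.append(Family(
                id=fid, cluster_ids=list(d["clusters"]),
                representative_cluster=d["representative"],
                consensus=d["consensus"],
                information_content=np.array(d["information_content"]),
                member_ids=list(d["members"]),
            ))
    return clusters, families


def run_pipeline(
    records: Sequence[ProteinRecord],
    config: PipelineConfig | None = None,
    seed: int = 0,
    require_signal: bool = True,
) -> PipelineResult:
    """Run discovery end-to-end on a set of protein records."""
    cfg = config or PipelineConfig()
    n_input = len(records)
    short = filter_by_length(records, cfg.seqio.max_len).kept
    if require_signal:
        secretory = [r for r in short if predict_signal(r, cfg.sigpep).has_signal]
    else:
        secretory = list(short)
    if len(secretory) < 2:
        raise ValueError("fewer than 2 candidate secretory proteins after filtering")
    segments = extract_cterm_all(secretory, cfg.seqio.cterm_window)
    hits = pw_mod.all_vs_all(segments, seed=seed, config=cfg.pairwise)
    graph = pw_mod.build_graph(
        hits, evalue_cutoff=cfg.pairwise.evalue_cutoff,
        weight_cap=cfg.pairwise.weight_cap,
        nodes=[s.parent_id for s in segments],
    )
    clustering = mcl_mod.mcl_cluster(graph, config=cfg.mcl)
    clusters, singletons = build_clusters(clustering, segments, cfg, seed)
    clusters, singletons, rounds = recruit_singletons(
        clusters, singletons, segments, cfg, seed
    )
    families = assemble_families(clusters, cfg, seed)
    return PipelineResult(
        clusters=clusters,
        singletons=singletons,
        families=families,
        n_input=n_input,
        n_short=len(short),
        n_signal=len(secretory),
        recruitment_rounds=rounds,
    )
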