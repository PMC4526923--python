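# sspfam

De novo discovery of **small secretory peptide (SSP) families** from
predicted proteomes.

Plant signalling peptides (CLE, GLV/RGF/CLEL, IDA, PSK, ...) are translated
as short preproproteins with a cleavable N-terminal signal peptide and a
conserved — usually C-terminal — bioactive motif. Because the mature
peptides are tiny and only weakly conserved, ordinary homology searches
miss most of them. `sspfam` implements a motif-centric discovery pipeline
for this problem, aimed at researchers who want to build a family library
from a set of reference proteomes and then screen other proteomes against
it.

## Method

1. **Preselection** — keep proteins strictly shorter than 200 aa whose
   N-terminus looks like a cleavable signal peptide. Signal detection is a
   transparent von-Heijne-style heuristic (hydrophobic h-region core,
   non-negative n-region charge, small residues at the −3/−1 positions of
   a cleavage site); externally computed predictions can be imported and
   take precedence.
2. **All-vs-all comparison** — the last 50 residues of every candidate are
   aligned against every other with exact affine-gap Smith–Waterman under
   BLOSUM50 (chosen to pick up mildly related sequences). Raw scores are
   converted to E-values with an empirical Gumbel null fitted to
   shuffled-sequence decoys:
   `E(S) = N · (1 − exp(−exp(−λ(S − μ))))`, and pairs with `E ≤ 10⁻³`
   become edges (weight `−log₁₀E`) of a similarity graph.
3. **Markov clustering (MCL)** — random-walk expansion alternating with
   inflation (entrywise power 1.5) fragments the graph into first-level
   clusters; unattached sequences stay singletons.
4. **Profile HMMs** — each cluster is aligned progressively (UPGMA guide
   tree, sum-of-pairs BLOSUM62 profiles), gappy/non-conserved columns are
   pruned, and the conserved core is compiled into a local-alignment
   profile HMM (Henikoff weighting, background pseudocounts) calibrated
   against random sequences, again via the Gumbel.
5. **Singleton recruitment** — remaining singletons are searched against
   all cluster HMMs; good hits (`E ≤ 0.01`) join their best cluster, the
   affected models are rebuilt, and the search repeats until a fixpoint.
6. **Family assembly** — cluster HMMs are compared all-vs-all with a
   profile–profile co-emission score
   `s(i,j) = log₂ Σₐ pᵢ(a)qⱼ(a)/f(a)`; linked profiles (`E ≤ 0.05`
   against column-shuffled decoy profiles) are Markov-clustered once more.
   Each resulting group of clusters is one family with a consensus motif
   and per-position information content.
7. **Screening** — arbitrary pre-filtered proteomes are scored against
   each family's representative HMM and assigned to their best family at
   `E ≤ 0.05`, yielding a species × family count matrix.

A seeded synthetic-data generator builds preproprotein datasets with
planted motif families and ground truth, so the whole pipeline is testable
without downloads.

## Worked example

```bash
sspfam --seed 42 simulate --out toy.fasta --truth truth.tsv \
       --families 3 --members 6 --decoys 12
# wrote 30 records to toy.fasta

sspfam --seed 42 run toy.fasta --outdir library
# 3 clusters, 3 families, 12 singletons (1 recruitment rounds) -> library

sspfam screen toy.fasta --library library --out assignments.tsv --matrix matrix.tsv
# assigned 18 of 30 proteins
```

The run discovers the three planted families (`library/families.json`),
e.g.

```
f1 ['c1'] TEAEDGICSQKKVCQFCMYRSSS 6
f2 ['c2'] GKCRVALAYTMKLFCNVCVTGPESV 6
f3 ['c3'] GLTIYSFIRLRSMDTLMIEWSPKTT 6
```

— family id, member clusters, consensus motif (uppercase letters carry
≥ 1 bit of information), member count. All 18 planted members and none of
the 12 motif-free decoys pass the screening cutoff; the species × family
matrix shows 6 proteins per family:

```
	f1	f2	f3
synth	6	6	6
```

Each stage is also available separately (`sspfam filter / pairs / cluster /
build / recruit / families / eval`); `sspfam write-config` emits the full
default configuration (every threshold above) as YAML for editing, and
`--config my.yaml` applies it.

## Layout

- `src/sspfam/seqio.py` — FASTA IO, length filter, C-terminal windows
- `src/sspfam/sigpep.py` — signal-peptide heuristic + external imports
- `src/sspfam/pairwise.py` — Smith–Waterman all-vs-all, Gumbel E-values,
  similarity graph
- `src/sspfam/mcl.py` — Markov Cluster Algorithm
- `src/sspfam/msa.py` — progressive alignment and column pruning
- `src/sspfam/phmm.py` — profile HMMs: build, calibrate, search,
  profile–profile comparison
- `src/sspfam/pipeline.py` — orchestration, recruitment, families,
  screening, evaluation
- `src/sspfam/synthetic.py` — planted-family dataset generator
- `docs/methods.md` — model details, parameter rationale, limitations
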