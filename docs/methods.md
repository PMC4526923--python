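# Methods

This note documents the models and numerical choices behind `sspfam`, the
defaults that matter, what the synthetic benchmark does and does not show,
and the known limitations.

## Problem setting

Small secretory peptides (SSPs) are translated as preproproteins of
roughly 60–200 residues: an N-terminal signal peptide (~15–30 aa), a
variable pro-region, and a short bioactive motif that typically sits at or
very near the C-terminus. Family membership is carried almost entirely by
that motif; the rest of the precursor diverges quickly. The pipeline
therefore compares only the C-terminal window (default 50 aa), clusters on
weak local similarity, and represents each cluster by a probabilistic
motif model.

## Preselection

*Length.* Proteins of length `< 200` (strict) are kept. The cutoff is
deliberately generous — known precursors average ~100 aa — so that the
length filter removes almost no genuine SSPs.

*Signal peptide.* The detector is a transparent three-rule heuristic in
the von Heijne tradition, not a reimplementation of any neural-network or
HMM predictor:

1. an h-region: some 8-residue window fully inside the first 40 residues
   with mean Kyte–Doolittle hydropathy ≥ 2.2;
2. a non-negative net charge (K/R = +1, D/E = −1) of the region before
   that window (n-regions are typically positively charged);
3. a cleavage site at position 10–45, strictly after the h-region, whose
   −1 and −3 residues are small/neutral ({A,G,S,C,T}), with at least one
   mature residue following.

The hydropathy threshold of 2.2 was fixed by a one-off calibration against
the package's own synthetic benchmark: genuine h-region cores average
KD ≈ 3, background composition ≈ −0.5, and 2.2 yields sensitivity 1.00 /
specificity ≈ 0.93 on independent calibration draws. All three thresholds
are config keys; externally computed predictions (TSV) override the
heuristic per protein, so users with access to a dedicated predictor lose
nothing.

## All-vs-all comparison and E-values

The C-terminal windows are compared with exact affine-gap Smith–Waterman
(BLOSUM50; gap open 10 including the first extension, extend 2; `X`
scores 0 against everything). Exactness is affordable at the scale of
50-residue segments, so no heuristic seeding layer exists.

Statistical significance uses an *empirical* extreme-value null rather
than precomputed Karlin–Altschul constants: `n_decoys` (default 1000)
pairs of segments are drawn, each sequence independently shuffled
(destroying motifs, preserving length and composition), scored, and a
Gumbel is fitted by maximum likelihood. Then

    E(S) = N · (1 − exp(−exp(−λ(S − μ)))),   λ = 1/β,

with `N` the number of pairs actually compared. This is correct by
construction for whatever matrix and penalties are configured. Segments
are nearly uniform in length (capped at the window), so a single global
fit replaces per-length calibration. E-values are floored at 1e-200 and
edge weights `−log₁₀E` capped at 200 so the clustering matrix stays
finite (the TribeMCL convention).

At the default cutoff `E ≤ 10⁻³` only strongly similar segment pairs
form edges — at the benchmark's divergence roughly the closest 15% of
within-family pairs. This is intentional and mirrors the two-stage logic
of the protocol: the graph stage seeds conservative clusters and the far
more sensitive HMM stage recruits the rest.

## Markov clustering

MCL runs on the dense column-stochastic matrix: self-loops set to each
node's maximum incident weight (1 for isolated nodes), expansion = matrix
squaring, inflation = entrywise power 1.5 followed by column
renormalization, pruning of entries below 1e-5, iterated to a 1e-8
fixpoint (max 200 rounds, non-convergence is reported in diagnostics but
interpreted anyway). Clusters are read off the attractor structure;
nodes attracted to several attractor systems join the one containing the
smallest member id, which makes the labelling (`c1, c2, ...` by
decreasing size, ties by smallest member) fully deterministic. Inflation
1.5 is used at both the sequence and the profile level — low granularity,
because SSP families cohere through weak similarity.

## Per-cluster alignment and pruning

Clusters are aligned progressively: a UPGMA guide tree over the distance
`d(a,b) = 1 − S(a,b)/min(S(a,a), S(b,b))` (S = Smith–Waterman raw score),
then profile–profile global alignment up the tree with sum-of-pairs
BLOSUM62 column scores (gap-vs-residue pairs score 0) and affine gaps
(11/1, scaled by the product of profile depths). Traceback prefers
diagonal over up over left, and ties in the guide tree join the
lexicographically smallest id pair, so the alignment is a pure function
of its input. Iterative refinement is deliberately omitted: clusters are
small and short, and determinism is worth more here than the marginal
accuracy of refinement passes.

A column is *retained* iff its gap fraction is ≤ 0.5, it has ≥ 2
residues, and its mean pairwise BLOSUM62 score is > 0. Pruning only masks
columns (rows are never altered) and is recomputed from the rows, hence
idempotent. A cluster whose every column fails is flagged
"no conserved region" and excluded from the HMM stages but reported.
Pruning runs immediately before every HMM build, including rebuilds
during recruitment.

## Profile HMMs

One match state per retained column. Emissions are Henikoff
position-based weighted counts mixed with `pseudocount_weight` (default
1.0) parts background (Robinson–Robinson frequencies, config-overridable);
transitions come from the observed gap structure with Laplace
pseudocounts (I→D and D→I, absent from the architecture, are dropped
during counting). The architecture is single-hit local:

- uniform begin-entry over match states;
- a small exit mass (default 0.05) from every internal match state, full
  exit from the last;
- free N/C flank states that self-loop with probability 350/351 and emit
  background.

The null model is the same background with the same geometric length
distribution, so flank emissions cancel and scores
(`log₂ P(seq|model)/P(seq|null)`, bits) are driven by the motif alone.
A single-hit design reflects the biology: one bioactive motif per
preproprotein. Forward and Viterbi are implemented in log space over a
batched DP (the delete chain is a per-position scan); "log zero" is the
finite sentinel −1e30, which exponentiates to exactly 0 and avoids NaN
from ∞−∞. Viterbi is used for calibration and search (a config flag
switches to Forward), matching classic practice.

Calibration draws `n_samples` (default 1000) background sequences of
length 350, scores them, and fits a Gumbel by maximum likelihood;
`E = n_targets · tail` as above. Scores of ~30–40 bits against
calibrated nulls of μ ≈ −6, β ≈ 1.5 make recruitment and screening
E-values effectively unambiguous at the benchmark scale.

## Recruitment, families, screening

*Recruitment* (cutoff `E ≤ 0.01`, max 20 rounds): per round, all
remaining singletons are searched against all cluster HMMs; each with a
qualifying hit joins its best-E cluster (ties → lower cluster id);
affected clusters are realigned, re-pruned, rebuilt and recalibrated.
Membership only grows, and each continuing round recruits at least one
sequence, so the procedure terminates within the initial singleton count.
Families are assembled once, after recruitment has converged.

*Family assembly*: all cluster-HMM pairs are scored with a local
profile–profile DP over the co-emission score
`s(i,j) = log₂ Σₐ pᵢ(a)qⱼ(a)/f(a)` with affine gaps in bits (defaults
4.0/0.5), floored at 0 and canonicalized so symmetry is exact. The null
comes from column-shuffled decoy profiles — shuffling preserves the
column repertoire but destroys the colinear chains that genuine
homology produces. Links at `E ≤ 0.05` feed a second MCL; each resulting
group (plus each unlinked cluster) is a family. The family's
representative HMM is its largest cluster's (ties → lowest c#); the
consensus string takes each match state's argmax residue, uppercase
where information content `log₂20 − H(emissions)` is ≥ 1 bit.

*Screening* scores every pre-filtered protein of a target proteome
against every family representative and assigns it to the best family iff
`E ≤ 0.05` (E against the number of proteins screened). Each protein
counts at most once, so the species × family matrix rows sum to the
number of assigned proteins.

## Synthetic benchmark

The generator emulates preproprotein architecture: a signal peptide
constructed to satisfy the detector's rules (M + 1–2 positively
charged/polar residues + 9–12 hydrophobic residues + a small-residue
cleavage box landing at position ~15–22), a linker drawn from background
composition, and — for family members — a planted motif ending within 5
residues of the C-terminus. Mature length is Normal(75, 15) (protein
totals ≈ 95–100 aa, matching the ~100-aa average of known precursors).
Family divergence substitutes each motif residue with probability `d`,
resampling uniformly over all 20 residues, so expected identity to the
ancestor is analytic: `1 − 19d/20`. Decoys share the full architecture
minus the motif, which makes them a test of the E-value machinery rather
than of composition filtering.

Default study conditions: 5 families × 8 members, motif length 14,
divergence 0.10, 40 decoys. Two scenario generators probe the two-level
behaviour: *two-subfamily* (one ancestor, two consensuses at 0.15
divergence each — ≈ 74% inter-subfamily identity, the conserved-box
regime — members at 0.05) must yield two first-level clusters that merge
into one family; *two-motif* (independent ancestors) must stay two
families.

What passing these benchmarks does **not** show: real preproproteins have
indels in their motifs, family sizes are heavy-tailed, signal peptides
vary far more than the generator's, proteomes contain transmembrane
proteins that fool hydropathy-based detection, and real divergence is not
i.i.d. uniform substitution. The benchmarks validate the machinery —
exactness, calibration, convergence, two-level clustering logic — not
field performance on any particular genome release.

## Numerical and degenerate-input choices

- Gumbel fits reject constant score samples (no scale information).
- MCL validates symmetry and non-negativity; single-node components are
  singletons by definition.
- `hmm_search` with an empty target list returns no hits; screening an
  empty proteome returns an empty assignment table and zero matrix.
- Proteins shorter than the C-terminal window contribute their whole
  sequence; records shorter than 15 residues are signal-negative without
  error.
- Ambiguity codes (B, Z, J, U, O) are folded into X on input; X scores 0
  in substitution matrices and emits background in HMMs, so it is
  score-neutral everywhere.
- End-to-end determinism: every stochastic step (decoy shuffling, HMM
  calibration, profile decoys) derives its seed from the pipeline seed;
  per-cluster calibration seeds are offset by the cluster's numeric id so
  rebuilds are reproducible independent of rebuild order.

## Problem sizes

The shipped tests and the acceptance script run at desk scale: ≤ ~80
sequences per dataset, 200-pair alignment-oracle checks, 5000-sample
calibration recovery, 1000 decoys per Gumbel fit, 1000×350 calibration
batches per HMM. A full multi-genome run (10⁵ proteins) would want the
all-vs-all stage parallelized or banded and MCL sparsified; neither
changes the statistics, only the engineering.

## Known limitations

- The signal-peptide heuristic trades accuracy for transparency; use
  imported predictions for serious genome-scale work.
- Profile–profile comparison scores match-state co-emission only (no
  insert-state co-emission), which suffices for linking related clusters
  but underestimates similarity between profiles with long inserts.
- The first-level graph stage needs at least one within-family pair at
  `E ≤ 10⁻³` to seed a cluster; families whose members are uniformly
  very diverged can remain singletons (recruitment has nothing to grow
  from). This mirrors the conservative seeding of the original protocol.
- MCL is dense (O(n²) memory): fine for thousands of nodes, not millions.
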