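"""Seeded generator of preproprotein datasets with planted SSP families.

Generated records emulate the architecture of small secretory peptide
precursors: an N-terminal signal peptide (positively charged n-region,
hydrophobic h-region, c-region obeying the (-3,-1) small-residue rule),
a variable linker drawn from background composition, and — for family
members — a conserved C-terminal bioactive motif that ends at or within a
few residues of the C-terminus. Decoys share the architecture but carry
no planted motif, so they stress the E-value machinery rather than any
composition filter. Every dataset comes with a ground-truth table, making
each pipeline stage testable without downloads.

Substitutions during family divergence resample uniformly over the 20
residues (and may silently restore the original), so the expected
within-family motif identity stays analytic:
``1 - divergence * 19/20`` per residue relative to the ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import AA, BACKGROUND
from .seqio import ProteinRecord

HYDROPHOBIC = "LIVAF"
N_REGION = "KRNQST"
SMALL = "AGST"  # used at the -1/-3 cleavage positions


@dataclass
class SyntheticSpec:
    """Study conditions for one planted-family dataset."""

    n_families: int = 5
    members_per_family: int = 8
    motif_length: int = 14
    motif_divergence: float = 0.10  # per-residue substitution probability
    n_decoys: int = 40
    mature_length_mean: float = 75.0
    mature_length_sd: float = 15.0
    include_signal: bool = True
    species: Sequence[str] = ("synth",)
    seed: int = 42
    max_protein_length: int = 200
    allow_overlength: bool = False
    family_ancestors: Sequence[str] | None = None  # optional fixed motifs

    def __post_init__(self):
        if not 8 <= self.motif_length <= 20:
            raise ValueError("motif_length must be in [8, 20]")
        if not 0.0 <= self.motif_divergence <= 1.0:
            raise ValueError("motif_divergence must be a probability")
        if self.mature_length_mean <= 0 or self.mature_length_sd < 0:
            raise ValueError("mature length distribution must be positive")
        if self.n_families < 0 or self.members_per_family < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SyntheticDataset:
    records: list[ProteinRecord]
    truth: pd.DataFrame  # columns: id, family, species
    spec: SyntheticSpec = field(repr=False, default=None)

    def truth_labels(self) -> dict[str, str]:
        return dict(zip(self.truth["id"], self.truth["family"]))


def _background_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(np.array(list(AA))[rng.choice(20, size=n, p=BACKGROUND)])


def _signal_peptide(rng: np.random.Generator) -> str:
    """A signal peptide built to satisfy the package's detection rules.

    M + short positive n-region + 9-12 aa hydrophobic h-region + c-region
    ending in small residues at the -3 and -1 positions; the cleavage site
    lands between positions 15 and ~22.
    """
    n_len = int(rng.integers(1, 3))
    n_region = "M" + "".join(rng.choice(list(N_REGION), size=n_len))
    h_len = int(rng.integers(9, 13))
    h_region = "".join(rng.choice(list(HYDROPHOBIC), size=h_len, p=[0.5, 0.15, 0.15, 0.15, 0.05]))
    middle = rng.choice(list("QNPH"))
    c_region = rng.choice(list(SMALL)) + middle + rng.choice(list(SMALL))
    sig = n_region + h_region + c_region
    if len(sig) < 15:  # pad the h-region so the cleavage site is >= 15
        sig = n_region + h_region + "L" * (15 - len(sig)) + c_region
    return sig


def mutate_motif(motif: str, divergence: float, rng: np.random.Generator) -> str:
    out = []
    for c in motif:
        if rng.random() < divergence:
            out.append(AA[int(rng.integers(20))])
        else:
            out.append(c)
    return "".join(out)


def _one_record(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    motif: str | None,
) -> str:
    """Assemble signal + linker + (motif + short tail | background)."""
    mature_len = max(
        spec.motif_length + 1,
        int(round(rng.normal(spec.mature_length_mean, spec.mature_length_sd))),
    )
    prefix = (
        _signal_peptide(rng)
        if spec.include_signal
        else _background_seq(rng, int(rng.integers(18, 26)))
    )
    if motif is not None:
        tail_len = int(rng.integers(0, 6))  # motif ends within 5 aa of the C-terminus
        linker_len = max(0, mature_len - len(motif) - tail_len)
        body = _background_seq(rng, linker_len) + motif + _background_seq(rng, tail_len)
    else:
        body = _background_seq(rng, mature_len)
    return prefix + body


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a planted-family proteome with ground truth, reproducibly.

    Raises ``ValueError`` if a generated protein reaches the 200-aa
    length cutoff and ``allow_overlength`` is not set: such a record would
    silently vanish from the pipeline's input.
    """
    rng = np.random.default_rng(spec.seed)
    species = list(spec.species) or ["synth"]
    records: list[ProteinRecord] = []
    rows: list[dict] = []

    ancestors: list[str] = []
    if spec.family_ancestors is not None:
        if len(spec.family_ancestors) != spec.n_families:
            raise ValueError("family_ancestors must match n_families")
        ancestors = [m.upper() for m in spec.family_ancestors]
    else:
        for _ in range(spec.n_families):
            ancestors.append(
                "".join(np.array(list(AA))[rng.integers(0, 20, spec.motif_length)])
            )

    idx = 0
    for k, ancestor in enumerate(ancestors):
        label = f"fam{k + 1}"
        for _ in range(spec.members_per_family):
            motif = mutate_motif(ancestor, spec.motif_divergence, rng)
            seq = _one_record(rng, spec, motif)
            sp = species[idx % len(species)]
            rid = f"{label}_m{idx:03d}"
            _check_length(seq, rid, spec)
            records.append(ProteinRecord(id=rid, sequence=seq, species=sp))
            rows.append({"id": rid, "family": label, "species": sp})
            idx += 1
    for d in range(spec.n_decoys):
        seq = _one_record(rng, spec, None)
        sp = species[idx % len(species)]
        rid = f"decoy_{d:03d}"
        _check_length(seq, rid, spec)
        records.append(ProteinRecord(id=rid, sequence=seq, species=sp))
        rows.append({"id": rid, "family": "decoy", "species": sp})
        idx += 1

    truth = pd.DataFrame(rows, columns=["id", "family", "species"])
    return SyntheticDataset(records=records, truth=truth, spec=spec)


def _check_length(seq: str, rid: str, spec: SyntheticSpec) -> None:
    if len(seq) >= spec.max_protein_length and not spec.allow_overlength:
        raise ValueError(
            f"generated record {rid} has length {len(seq)} >= "
            f"{spec.max_protein_length}; shrink the mature length "
            "distribution or set allow_overlength"
        )


# ---------------------------------------------------------------------------
# benchmark scenarios mirroring known signalling-peptide families


def two_subfamily_dataset(
    seed: int = 42,
    subfamily_divergence: float = 0.15,
    within_divergence: float = 0.05,
    members_per_subfamily: int = 8,
    motif_length: int = 14,
    n_decoys: int = 10,
) -> SyntheticDataset:
    """One ancestral motif, two diverged subfamilies (a GLV/RGF-like case).

    The subfamily consensus motifs each differ by ``subfamily_divergence``
    from a shared ancestor (default 0.15, i.e. ~74% consensus identity
    between the subfamilies — the regime of signalling-peptide subgroups
    that share a conserved box); members are tight around their subfamily
    consensus. First-level clustering is expected to separate the
    subfamilies and profile-profile comparison to reunite them into a
    single family. Truth labels carry the shared family (``fam1``) for
    both subfamilies.
    """
    rng = np.random.default_rng(seed)
    ancestor = "".join(np.array(list(AA))[rng.integers(0, 20, motif_length)])
    sub1 = mutate_motif(ancestor, subfamily_divergence, rng)
    sub2 = mutate_motif(ancestor, subfamily_divergence, rng)
    spec = SyntheticSpec(
        n_families=2,
        members_per_family=members_per_subfamily,
        motif_length=motif_length,
        motif_divergence=within_divergence,
        n_decoys=n_decoys,
        seed=seed + 1,
        family_ancestors=[sub1, sub2],
    )
    ds = generate_dataset(spec)
    # both subfamilies are truly the same family
    ds.truth.loc[ds.truth["family"].isin(["fam1", "fam2"]), "family"] = "fam1"
    return ds


def two_family_dataset(
    seed: int = 42,
    within_divergence: float = 0.05,
    members_per_family: int = 8,
    motif_length: int = 14,
    n_decoys: int = 10,
) -> SyntheticDataset:
    """Two unrelated planted motifs (a CLE-like two-family case)."""
    spec = SyntheticSpec(
        n_families=2,
        members_per_family=members_per_family,
        motif_length=motif_length,
        motif_divergence=within_divergence,
        n_decoys=n_decoys,
        seed=seed,
    )
    return generate_dataset(spec)
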