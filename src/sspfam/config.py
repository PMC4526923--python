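"""Pipeline configuration: every threshold in one serializable tree.

Defaults follow the published protocol where it states a value (length
cutoff 200, C-terminal window 50, BLOSUM50 all-vs-all with E <= 1e-3, MCL
inflation 1.5 at both levels, screening E <= 0.05) and documented package
choices elsewhere (gap penalties, signal-peptide heuristic thresholds,
HMM pseudocounts, recruitment cutoff).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SeqioConfig:
    max_len: int = 200          # keep proteins strictly shorter than this
    cterm_window: int = 50      # C-terminal search window (aa)


@dataclass
class SigpepConfig:
    window: int = 8             # h-region window length (aa)
    # mean Kyte-Doolittle over the window; genuine h-region cores sit near
    # 3, background composition near -0.5, so 2.2 separates them cleanly
    min_hydropathy: float = 2.2
    nterm_span: int = 40        # h-region must lie within the first N residues
    cleavage_min: int = 10      # 1-based position of last signal residue
    cleavage_max: int = 45


@dataclass
class PairwiseConfig:
    matrix: str = "BLOSUM50"
    gap_open: int = 10          # open cost includes the first extension
    gap_extend: int = 2
    evalue_cutoff: float = 1e-3
    n_decoys: int = 1000        # shuffled pairs for Gumbel calibration
    weight_cap: float = 200.0   # cap on -log10(E) edge weights


@dataclass
class MclConfig:
    inflation: float = 1.5
    expansion: int = 2
    prune_below: float = 1e-5
    max_iter: int = 200
    tol: float = 1e-8


@dataclass
class MsaConfig:
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    max_gap_frac: float = 0.5   # column removed above this gap fraction
    min_col_score: float = 0.0  # mean pairwise BLOSUM62 must exceed this


@dataclass
class PhmmConfig:
    pseudocount_weight: float = 1.0
    p_loop: float = 350.0 / 351.0   # N/C flank + null-model length geometry
    exit_prob: float = 0.05         # local exit mass per internal match state
    calib_samples: int = 1000
    calib_length: int = 350
    use_forward: bool = False       # score with Viterbi by default
    pp_gap_open: float = 4.0        # profile-profile gap penalties (bits)
    pp_gap_extend: float = 0.5
    pp_decoys: int = 200            # column-shuffled decoy profile pairs


@dataclass
class PipelineStageConfig:
    recruit_evalue: float = 0.01
    recruit_max_rounds: int = 20
    family_inflation: float = 1.5
    prc_evalue: float = 0.05        # profile-profile link cutoff
    screen_evalue: float = 0.05


@dataclass
class PipelineConfig:
    seqio: SeqioConfig = field(default_factory=SeqioConfig)
    sigpep: SigpepConfig = field(default_factory=SigpepConfig)
    pairwise: PairwiseConfig = field(default_factory=PairwiseConfig)
    mcl: MclConfig = field(default_factory=MclConfig)
    msa: MsaConfig = field(default_factory=MsaConfig)
    phmm: PhmmConfig = field(default_factory=PhmmConfig)
    pipeline: PipelineStageConfig = field(default_factory=PipelineStageConfig)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        for section_field in dataclasses.fields(cls):
            section = data.get(section_field.name)
            if section is None:
                continue
            target = getattr(cfg, section_field.name)
            valid = {f.name for f in dataclasses.fields(target)}
            unknown = set(section) - valid
            if unknown:
                raise ValueError(
                    f"unknown config keys in [{section_field.name}]: {sorted(unknown)}"
                )
            for key, value in section.items():
                setattr(target, key, value)
        return cfg


DEFAULT_CONFIG = PipelineConfig()
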