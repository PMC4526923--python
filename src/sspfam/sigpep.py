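"""Signal-peptide detection for short proteins.

Secretory preproproteins start with a cleavable N-terminal signal peptide:
a short, often positively charged n-region, a hydrophobic h-region, and a
c-region whose last residues obey von Heijne's (-3,-1) rule (small,
neutral residues at the -1 and -3 positions relative to the cleavage
site). This module implements a transparent heuristic in that spirit —
it does not attempt to reproduce any particular neural-network or HMM
predictor — and can import externally computed prediction tables, which
take precedence when present.

Heuristic (all thresholds config-exposed):

1. h-region: an 8-residue window, fully inside the first 40 residues,
   whose mean Kyte-Doolittle hydropathy reaches the configured threshold
   (default 2.2: genuine h-region cores average near 3, background
   composition near -0.5).
2. n-region: the residues before the h-region have net charge >= 0
   (K/R = +1, D/E = -1).
3. cleavage site: a 1-based position c in [10, 45], strictly after the
   h-region, with residues at c (-1) and c-2 (-3) in {A, G, S, C, T},
   and at least one mature residue after it.

The reported score is min(1, mean h-region hydropathy / 4); 0 when no
signal is called.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .config import SigpepConfig
from .seqio import ProteinRecord
from .alphabet import KYTE_DOOLITTLE

SMALL_NEUTRAL = set("AGSCT")  # allowed at the -1 / -3 positions
_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}


class PredictionSource(str, Enum):
    HEURISTIC = "heuristic"
    EXTERNAL = "external"


@dataclass(frozen=True)
class SignalPrediction:
    protein_id: str
    has_signal: bool
    cleavage_pos: int  # 1-based index of the last signal residue; 0 if none
    score: float
    source: PredictionSource = PredictionSource.HEURISTIC

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")
        if self.has_signal and self.cleavage_pos <= 0:
            raise ValueError("has_signal requires a positive cleavage_pos")


def _window_hydropathy(seq: str, start: int, width: int) -> float:
    return sum(KYTE_DOOLITTLE.get(c, 0.0) for c in seq[start:start + width]) / width


def predict_signal(
    record: ProteinRecord, config: SigpepConfig | None = None
) -> SignalPrediction:
    """Apply the h-region + (-3,-1) heuristic to one protein.

    Deterministic; records shorter than 15 residues are reported as
    signal-free with score 0 (no error). Windows are scanned left to
    right and the first (h-region, cleavage site) combination satisfying
    all three rules is reported.
    """
    cfg = config or SigpepConfig()
    seq = record.sequence
    negative = SignalPrediction(record.id, False, 0, 0.0)
    if record.length < 15:
        return negative

    w = cfg.window
    last_start = min(cfg.nterm_span, record.length) - w
    for h0 in range(0, last_start + 1):
        hyd = _window_hydropathy(seq, h0, w)
        if hyd < cfg.min_hydropathy:
            continue
        if sum(_CHARGE.get(c, 0) for c in seq[:h0]) < 0:
            continue
        # first qualifying cleavage site strictly after the h-region
        c_lo = max(cfg.cleavage_min, h0 + w + 1)
        c_hi = min(cfg.cleavage_max, record.length - 1)  # need a mature region
        for c in range(c_lo, c_hi + 1):
            if c - 3 < 0:
                continue
            if seq[c - 1] in SMALL_NEUTRAL and seq[c - 3] in SMALL_NEUTRAL:
                return SignalPrediction(
                    record.id, True, c, min(1.0, hyd / 4.0)
                )
    return negative


def predict_signal_all(
    records, config: SigpepConfig | None = None
) -> dict[str, SignalPrediction]:
    return {r.id: predict_signal(r, config) for r in records}


def import_signal_predictions(path: str | Path) -> dict[str, SignalPrediction]:
    """Read an external prediction table (TSV: id, has_signal Y/N, cleavage_pos, score).

    Rows are marked ``source=external`` and override heuristic calls when
    both exist. IDs absent from the proteome are kept: screened proteomes
    may be supersets of the table.
    """
    path = Path(path)
    out: dict[str, SignalPrediction] = {}
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[:2] == ["id", "has_signal"]:
                continue  # optional header
            if len(row) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            pid, flag, pos, score = row[0], row[1].strip().upper(), row[2], row[3]
            if flag not in {"Y", "N"}:
                raise ValueError(f"{path}:{lineno}: has_signal must be Y or N, got {row[1]!r}")
            try:
                pos_i = int(pos)
                score_f = float(score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field: {exc}") from exc
            out[pid] = SignalPrediction(
                protein_id=pid,
                has_signal=flag == "Y",
                cleavage_pos=pos_i,
                score=score_f,
                source=PredictionSource.EXTERNAL,
            )
    return out


def merge_predictions(
    heuristic: dict[str, SignalPrediction],
    external: dict[str, SignalPrediction] | None,
) -> dict[str, SignalPrediction]:
    """External predictions override heuristic ones; unknown ids are kept."""
    merged = dict(heuristic)
    if external:
        merged.update(external)
    return merged
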