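"""Shared fixtures: small hand fixtures plus one session-scoped pipeline run.

The end-to-end planted-family run (5 families x 8 members, motif length
14, 10% per-residue divergence, 40 decoys, seed 42) is computed once per
session and shared by the tests that examine its clusters, recruitment
trace, families and screening behaviour.
"""

from __future__ import annotations

import numpy as np
import pytest

from sspfam.config import PipelineConfig
from sspfam.pipeline import run_pipeline
from sspfam.seqio import CTerminalSegment, ProteinRecord
from sspfam.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    return generate_dataset(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def planted_result(planted_dataset):
    return run_pipeline(planted_dataset.records, config=PipelineConfig(), seed=42)


@pytest.fixture()
def toy_segments():
    return [
        CTerminalSegment("a", "MKWVYQGKLLPRAAY", 0),
        CTerminalSegment("b", "MKWVYQGRLLPRAAY", 0),
        CTerminalSegment("c", "MKWVYGKLLPRAY", 0),
        CTerminalSegment("d", "AKWVYQGKLLPRAAY", 0),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_record(id: str, sequence: str, species: str = "") -> ProteinRecord:
    return ProteinRecord(id=id, sequence=sequence, species=species)
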