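"""Shared fixtures: small hand-built alignments and standard synthetic
family / dimer parameter sets."""

from __future__ import annotations

import numpy as np
import pytest

from cladeface import (
    Alignment,
    DimerParams,
    FamilyParams,
    SequenceRecord,
    default_planted_sites,
    generate_clade_family,
)


@pytest.fixture
def tiny_alignment() -> Alignment:
    return Alignment(
        [
            SequenceRecord("a", "MKTA-"),
            SequenceRecord("b", "MKTAR"),
            SequenceRecord("c", "MRTAR"),
            SequenceRecord("d", "M-TAR"),
        ]
    )


def make_family(seed: int, *, fixation: float = 1.0, leak: float = 0.0,
                gap_rate: float = 0.05, sites_per_clade: int = 5) -> tuple:
    """Standard study-condition family: 3 clades x 40 sequences x 300
    columns, 5 planted sites per clade."""
    clade_names = [f"clade{i + 1}" for i in range(3)]
    rng = np.random.default_rng(seed)
    planted = default_planted_sites(
        300, clade_names, sites_per_clade, rng,
        query_fixation=fixation, subject_leak=leak,
    )
    params = FamilyParams(
        n_clades=3,
        seqs_per_clade=40,
        n_columns=300,
        planted_sites=planted,
        gap_rate=gap_rate,
        seed=seed,
    )
    return generate_clade_family(params)


@pytest.fixture
def family():
    return make_family(seed=7)


@pytest.fixture
def five_pair_dimer_params() -> DimerParams:
    return DimerParams(
        n_residues_per_chain=10,
        contact_residue_pairs=((1, 2), (3, 4), (5, 6), (7, 8), (9, 10)),
        cutoff=6.0,
    )
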