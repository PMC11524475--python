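"""The relative amino-acid ratio statistic and unique-residue calling."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from cladeface import (
    Alignment,
    CladePartition,
    DivergenceParams,
    SequenceRecord,
    iterate_unique_calls,
    relative_aa_ratio,
)
from cladeface.divergence import INFINITE, NA, NO_CALL, OK, call_unique_residues
from cladeface.io_formats import AMINO_ACIDS
from conftest import make_family


def vec(**freqs: float) -> np.ndarray:
    out = np.zeros(20)
    for aa, f in freqs.items():
        out[AMINO_ACIDS.index(aa)] = f
    return out


def brute_force_calls(rows_by_group: dict[str, list[str]], freq_cutoff=0.8,
                      ratio_cutoff=50.0) -> list[dict]:
    """Independent oracle: explicit counting, no shared code with the
    implementation.  rows_by_group maps 'query'/'subject' to row strings."""
    n_cols = len(rows_by_group["query"][0])
    out = []
    for j in range(n_cols):
        qchars = [r[j] for r in rows_by_group["query"] if r[j] in AMINO_ACIDS]
        schars = [r[j] for r in rows_by_group["subject"] if r[j] in AMINO_ACIDS]
        if not qchars:
            out.append({"status": "NA", "unique": False})
            continue
        counts = Counter(qchars)
        # the single majority amino acid, alphabetical tie-break
        aa = min(counts, key=lambda a: (-counts[a], a))
        qf = counts[aa] / len(qchars)
        if not qf > freq_cutoff:
            out.append({"status": "no_call", "unique": False})
            continue
        sf = schars.count(aa) / len(schars) if schars else 0.0
        if sf == 0.0:
            out.append({"status": "INF", "unique": True, "aa": aa})
        else:
            ratio = qf / sf
            out.append(
                {"status": "ok", "unique": ratio > ratio_cutoff, "aa": aa,
                 "ratio": ratio}
            )
    return out


class TestSingleColumn:
    def test_query_fixed_residue_absent_from_subject_is_infinite(self):
        call = relative_aa_ratio(vec(R=1.0), vec(K=1.0), query_n_effective=10)
        assert call.status == INFINITE
        assert call.unique and math.isinf(call.ratio)

    def test_nine_fold_ratio_not_unique_at_fifty(self):
        call = relative_aa_ratio(
            vec(R=0.9, K=0.1), vec(R=0.1, K=0.9), query_n_effective=10
        )
        assert call.status == OK
        assert call.ratio == pytest.approx(9.0)
        assert not call.unique

    def test_all_gap_query_is_na(self):
        call = relative_aa_ratio(np.zeros(20), vec(K=1.0), query_n_effective=0)
        assert call.status == NA and not call.unique

    def test_frequency_cutoff_is_strict(self):
        call = relative_aa_ratio(
            vec(R=0.8, K=0.2), vec(K=1.0), query_n_effective=10
        )
        assert call.status == NO_CALL  # 0.8 is not more than 0.8

    def test_ratio_cutoff_is_strict(self):
        call = relative_aa_ratio(
            vec(R=1.0), vec(R=0.02, K=0.98), query_n_effective=10
        )
        assert call.ratio == pytest.approx(50.0)
        assert not call.unique  # exactly 50 is not more than 50

    def test_invariant_column_ratio_one(self):
        call = relative_aa_ratio(vec(K=1.0), vec(K=1.0), query_n_effective=10)
        assert call.ratio == pytest.approx(1.0)
        assert not call.unique


class TestCalling:
    def make_two_clade(self, query_rows: list[str], subject_rows: list[str]):
        records = [
            SequenceRecord(f"q{i}", row) for i, row in enumerate(query_rows)
        ] + [SequenceRecord(f"s{i}", row) for i, row in enumerate(subject_rows)]
        partition = CladePartition(
            clades={
                "Q": frozenset(f"q{i}" for i in range(len(query_rows))),
                "S": frozenset(f"s{i}" for i in range(len(subject_rows))),
            },
            unassigned=frozenset(),
        )
        return Alignment(records), partition

    def test_planted_family_recovers_exactly_the_planted_sites(self):
        aln, partition, _, truth = make_family(seed=40)
        params = DivergenceParams(clade_set=("clade1", "clade2", "clade3"))
        table = iterate_unique_calls(aln, partition, params)
        got = {(c, col) for c in table.calls for col in table.unique_columns(c)}
        assert got == {(c, col) for c, col, _ in truth.planted}

    def test_two_clade_iteration_runs_both_directions(self):
        aln, partition = self.make_two_clade(["RK", "RK"], ["KK", "KK"])
        params = DivergenceParams(clade_set=("Q", "S"))
        table = iterate_unique_calls(aln, partition, params)
        assert table.calls["Q"][0].status == INFINITE
        assert table.calls["S"][0].status == INFINITE  # K absent from Q at col 1
        assert table.calls["Q"][1].ratio == pytest.approx(1.0)

    def test_determinism(self):
        aln, partition, _, _ = make_family(seed=41)
        params = DivergenceParams(clade_set=("clade1", "clade2", "clade3"))
        t1 = iterate_unique_calls(aln, partition, params)
        t2 = iterate_unique_calls(aln, partition, params)
        assert t1.calls == t2.calls

    def test_monotonicity_in_cutoffs(self):
        aln, partition, _, _ = make_family(seed=42, fixation=0.9, leak=0.01)
        base = DivergenceParams(clade_set=("clade1", "clade2", "clade3"))
        stricter_ratio = DivergenceParams(
            clade_set=base.clade_set, ratio_cutoff=200.0
        )
        stricter_freq = DivergenceParams(
            clade_set=base.clade_set, freq_cutoff=0.95
        )
        t0 = iterate_unique_calls(aln, partition, base)
        t1 = iterate_unique_calls(aln, partition, stricter_ratio)
        t2 = iterate_unique_calls(aln, partition, stricter_freq)
        for clade in base.clade_set:
            assert set(t1.unique_columns(clade)) <= set(t0.unique_columns(clade))
            callable0 = {c.column for c in t0.calls[clade] if c.status != NO_CALL}
            callable2 = {c.column for c in t2.calls[clade] if c.status != NO_CALL}
            assert callable2 <= callable0

    def test_empty_query_or_subject_rejected(self):
        aln, partition = self.make_two_clade(["RK"], ["KK"])
        params = DivergenceParams(clade_set=("Q", "S"))
        bad = CladePartition(
            clades={"Q": frozenset(), "S": partition.clades["S"]},
            unassigned=partition.clades["Q"],
        )
        with pytest.raises(ValueError, match="non-empty"):
            call_unique_residues(aln, bad, "Q", params)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_on_random_small_alignments(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = np.array(list(AMINO_ACIDS + "--X"))
        n_cols = 10
        qrows = ["".join(rng.choice(alphabet, n_cols)) for _ in range(6)]
        srows = ["".join(rng.choice(alphabet, n_cols)) for _ in range(9)]
        aln, partition = self.make_two_clade(qrows, srows)
        params = DivergenceParams(clade_set=("Q", "S"))
        calls = call_unique_residues(aln, partition, "Q", params)
        expected = brute_force_calls({"query": qrows, "subject": srows})
        for call, exp in zip(calls, expected):
            assert call.status == exp["status"]
            assert call.unique == exp["unique"]
            if exp["status"] == "ok":
                assert call.major_aa == exp["aa"]
                assert call.ratio == pytest.approx(exp["ratio"], abs=1e-12)


class TestParameterRecovery:
    @pytest.mark.parametrize("seed", range(20))
    def test_full_fixation_no_leak_perfect_recovery(self, seed):
        """Sensitivity 1.0 and zero false calls at fixation 1.0, leak 0."""
        aln, partition, _, truth = make_family(seed=seed)
        params = DivergenceParams(clade_set=("clade1", "clade2", "clade3"))
        table = iterate_unique_calls(aln, partition, params)
        got = {(c, col) for c in table.calls for col in table.unique_columns(c)}
        want = {(c, col) for c, col, _ in truth.planted}
        assert got == want  # all planted found, nothing else called
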