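"""Clade-unique residue calling via the relative amino-acid ratio.

For a chosen *query* clade and a pooled *subject* group (the remaining
clades of the comparison set), each alignment column is scored as follows:

1. Compute amino-acid frequencies in query and subject separately, over
   non-gap, non-``X`` characters only.
2. A column is *callable* only if one amino acid exceeds the frequency
   cutoff (strictly more than 80% by default) within the query clade; at
   that cutoff at most one amino acid can qualify.
3. The relative amino-acid ratio is the query frequency of that majority
   amino acid divided by its frequency in the pooled subject group.  A
   ratio strictly above the ratio cutoff (50 by default) calls the column
   a clade-unique residue.
4. If the amino acid is absent from the subject group, the ratio is
   *infinite* (a distinct token, never a numeric sentinel) and the column
   is called unique.  If every query row is a gap at the column, the
   result is *NA*.

Iterating the computation with each clade as query in turn yields the
per-clade unique-residue table; intersected with the columns of the
dimerization stretches it gives the per-clade interface polymorphism
counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .curation import CladePartition
from .io_formats import AMINO_ACIDS, Alignment
from .msa import StretchAnnotation, column_frequencies

DEFAULT_FREQ_CUTOFF = 0.8
DEFAULT_RATIO_CUTOFF = 50.0

# status tokens used in RatioCall and TSV output
OK = "ok"  # finite ratio computed
INFINITE = "INF"  # majority amino acid absent from subject
NA = "NA"  # query all-gap at this column
NO_CALL = "no_call"  # no query amino acid above the frequency cutoff


@dataclass(frozen=True)
class DivergenceParams:
    """Cutoffs and the ordered clade set entering the comparison."""

    clade_set: tuple[str, ...]
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF

    def __post_init__(self) -> None:
        if not 0.0 < self.freq_cutoff <= 1.0:
            raise ValueError("freq_cutoff must be in (0, 1]")
        if self.ratio_cutoff <= 0:
            raise ValueError("ratio_cutoff must be positive")
        if len(self.clade_set) < 2:
            raise ValueError("clade_set needs at least two clades")
        if len(set(self.clade_set)) != len(self.clade_set):
            raise ValueError("clade_set has repeated names")


@dataclass(frozen=True)
class RatioCall:
    """Result of the ratio statistic at one column for one query clade.

    ``ratio`` is a finite positive float when ``status == "ok"``,
    ``math.inf`` for the infinite case, and NaN for NA / no-call columns.
    """

    column: int
    query_clade: str
    status: str
    major_aa: str | None
    query_freq: float
    subject_freq: float
    ratio: float
    unique: bool

    @property
    def ratio_token(self) -> str:
        if self.status == INFINITE:
            return INFINITE
        if self.status == NA:
            return NA
        if self.status == NO_CALL:
            return ""
        return f"{self.ratio:.6g}"


def relative_aa_ratio(
    query_freqs: Sequence[float] | np.ndarray,
    subject_freqs: Sequence[float] | np.ndarray,
    query_n_effective: int,
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF,
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
    column: int = 0,
    query_clade: str = "query",
) -> RatioCall:
    """Score a single column given query and subject frequency vectors.

    Both vectors are over the alphabet ``ACDEFGHIKLMNPQRSTVWY`` with
    gap-excluded denominators, as produced by
    :func:`cladeface.msa.column_frequencies`.  ``query_n_effective`` is the
    query's non-gap count at the column (0 means NA).
    """
    q = np.asarray(query_freqs, dtype=float)
    s = np.asarray(subject_freqs, dtype=float)
    if q.shape != (len(AMINO_ACIDS),) or s.shape != (len(AMINO_ACIDS),):
        raise ValueError("frequency vectors must cover the 20-letter alphabet")
    if query_n_effective == 0:
        return RatioCall(column, query_clade, NA, None, math.nan, math.nan,
                         math.nan, False)
    best = int(q.argmax())
    qf = float(q[best])
    if qf <= freq_cutoff:  # strict: the majority must exceed the cutoff
        return RatioCall(column, query_clade, NO_CALL, None, math.nan,
                         math.nan, math.nan, False)
    aa = AMINO_ACIDS[best]
    sf = float(s[best])
    if sf == 0.0:
        return RatioCall(column, query_clade, INFINITE, aa, qf, 0.0,
                         math.inf, True)
    ratio = qf / sf
    return RatioCall(column, query_clade, OK, aa, qf, sf, ratio,
                     ratio > ratio_cutoff)


def call_unique_residues(
    alignment: Alignment,
    partition: CladePartition,
    query_clade: str,
    params: DivergenceParams,
    columns: Sequence[int] | None = None,
) -> list[RatioCall]:
    """One :class:`RatioCall` per alignment column, query vs pooled subjects.

    The subject group pools the sequences of every clade in
    ``params.clade_set`` except the query (one pooled frequency vector, not
    an average of per-clade vectors).
    """
    if query_clade not in params.clade_set:
        raise ValueError(f"query {query_clade!r} not in clade_set")
    for name in params.clade_set:
        if name not in partition.clades:
            raise ValueError(f"clade {name!r} missing from partition")
    query_ids = partition.clades[query_clade]
    subject_ids: set[str] = set()
    for name in params.clade_set:
        if name != query_clade:
            subject_ids |= partition.clades[name]
    if not query_ids or not subject_ids:
        raise ValueError("query and subject groups must be non-empty")

    qt = column_frequencies(alignment, subset=query_ids, columns=columns)
    st = column_frequencies(alignment, subset=subject_ids, columns=columns)
    calls: list[RatioCall] = []
    for i in range(qt.n_columns):
        calls.append(
            relative_aa_ratio(
                qt.freqs[i],
                st.freqs[i],
                int(qt.n_effective[i]),
                freq_cutoff=params.freq_cutoff,
                ratio_cutoff=params.ratio_cutoff,
                column=int(qt.columns[i]),
                query_clade=query_clade,
            )
        )
    return calls


@dataclass
class UniqueResidueTable:
    """Per-clade ratio calls, with helpers to tabulate and intersect with
    mapped stretch columns."""

    calls: dict[str, list[RatioCall]]
    params: DivergenceParams

    def unique_columns(self, clade: str) -> list[int]:
        return [c.column for c in self.calls[clade] if c.unique]

    def unique_in_stretches(
        self, annotations: Sequence[StretchAnnotation]
    ) -> dict[str, list[int]]:
        """Per clade, the unique-residue columns lying in mapped stretches."""
        cols = {col for ann in annotations for col in ann.columns}
        return {
            clade: sorted(set(self.unique_columns(clade)) & cols)
            for clade in self.calls
        }

    def to_frame(
        self, annotations: Sequence[StretchAnnotation] | None = None
    ) -> pd.DataFrame:
        stretch_of: dict[int, str] = {}
        residue_of: dict[int, int] = {}
        if annotations:
            for ann in annotations:
                for offset, col in enumerate(ann.columns):
                    stretch_of[col] = ann.name
                    residue_of[col] = ann.reference_range[0] + offset
        rows = []
        for clade, calls in self.calls.items():
            for c in calls:
                rows.append(
                    {
                        "clade": clade,
                        "column": c.column,
                        "reference_residue": residue_of.get(c.column, ""),
                        "stretch": stretch_of.get(c.column, ""),
                        "major_aa": c.major_aa or "",
                        "query_freq": c.query_freq,
                        "subject_freq": c.subject_freq,
                        "ratio": c.ratio_token,
                        "unique": c.unique,
                    }
                )
        return pd.DataFrame(rows)


def iterate_unique_calls(
    alignment: Alignment,
    partition: CladePartition,
    params: DivergenceParams,
    columns: Sequence[int] | None = None,
) -> UniqueResidueTable:
    """Run the unique-residue caller with each clade of the set as query;
    subjects are always the pooled remainder of the clade set."""
    calls = {
        clade: call_unique_residues(alignment, partition, clade, params, columns)
        for clade in params.clade_set
    }
    return UniqueResidueTable(calls=calls, params=params)
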