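"""Alignment-level utilities.

Gappy-column trimming (ClipKIT gappy-mode semantics), mapping of
reference-numbered residue stretches onto alignment columns, per-subset
column amino-acid frequencies, and consensus/logo matrices.

Columns are numbered 1-based in all public outputs; the trimming map keeps
track of original column numbers so that downstream tables can always be
reported in both frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AMINO_ACIDS, GAP, Alignment, SequenceRecord

#: The eight residue stretches that compose the NbNRC2 homodimerization
#: interface, in NbNRC2 residue numbering (1-based, inclusive).  Stretches
#: 1a-1c lie in the NB domain and contact the partner LRR; 1d-1f lie in the
#: LRR and contact the partner NB; 2a-2b form the LRR-LRR stack.
DIMERIZATION_STRETCHES: dict[str, tuple[int, int]] = {
    "1a": (217, 220),
    "1b": (238, 244),
    "1c": (270, 274),
    "1d": (506, 513),
    "2a": (528, 532),
    "1e": (533, 536),
    "2b": (549, 554),
    "1f": (559, 563),
}

DEFAULT_GAP_THRESHOLD = 0.9

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class StretchAnnotation:
    """A named reference-numbered residue range mapped to alignment columns.

    ``columns`` holds the 1-based alignment column of each residue
    ``start..end`` of the reference sequence; a residue whose column was
    removed by trimming appears in ``missing`` as (residue number, original
    column) instead.
    """

    name: str
    reference_range: tuple[int, int]
    columns: list[int]
    missing: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.columns, self.columns[1:])):
            raise ValueError(f"stretch {self.name!r}: columns not increasing")


@dataclass
class FrequencyTable:
    """Per-column amino-acid frequencies for a sequence subset.

    ``freqs`` is an (n_columns, 20) array over the alphabet
    ``ACDEFGHIKLMNPQRSTVWY``; ``n_effective`` counts the non-gap, non-X
    characters used as denominator.  Columns with ``n_effective == 0`` have
    undefined frequencies (stored as zeros, flagged by the count).
    ``columns`` gives the 1-based column number of each row (original
    numbering when the table was built on a trimmed alignment with a map).
    """

    freqs: np.ndarray
    n_effective: np.ndarray
    columns: np.ndarray
    subset_size: int

    @property
    def n_columns(self) -> int:
        return self.freqs.shape[0]

    def frequency(self, column_index: int, amino_acid: str) -> float:
        """Frequency of ``amino_acid`` at 0-based row ``column_index``."""
        return float(self.freqs[column_index, _AA_INDEX[amino_acid]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freqs, columns=list(AMINO_ACIDS))
        df.insert(0, "column", self.columns)
        df.insert(1, "n_effective", self.n_effective)
        return df


def gap_fractions(alignment: Alignment) -> np.ndarray:
    arr = alignment.to_array()
    return (arr == GAP).mean(axis=0)


def trim_gappy_columns(
    alignment: Alignment, gap_threshold: float = DEFAULT_GAP_THRESHOLD
) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap fraction is >= ``gap_threshold``.

    Returns the trimmed alignment and a column index map: entry *i* is the
    1-based original column number of trimmed column *i+1*.  Raises if every
    column would be removed.
    """
    if not 0.0 < gap_threshold <= 1.0:
        raise ValueError("gap threshold must be in (0, 1]")
    frac = gap_fractions(alignment)
    keep = frac < gap_threshold
    if not keep.any():
        raise ValueError("all columns removed by gap trimming")
    arr = alignment.to_array()[:, keep]
    records = [
        SequenceRecord(id=rec.id, residues="".join(row))
        for rec, row in zip(alignment.records, arr)
    ]
    column_index_map = [int(i) + 1 for i in np.flatnonzero(keep)]
    return Alignment(records), column_index_map


def map_reference_ranges(
    alignment: Alignment,
    reference_id: str,
    named_ranges: Mapping[str, tuple[int, int]],
    column_index_map: Sequence[int] | None = None,
) -> list[StretchAnnotation]:
    """Map reference-numbered residue ranges to alignment columns.

    The reference row is walked left to right, skipping its gaps, so residue
    *k* of the ungapped reference lands on the column holding its *k*-th
    non-gap character.  Ranges are 1-based inclusive in reference residue
    numbering.

    When the ranges refer to the numbering of the reference *before*
    trimming, pass the ``column_index_map`` from :func:`trim_gappy_columns`
    together with the **untrimmed** alignment: columns are then reported in
    the trimmed frame and reference residues lost to trimming are listed in
    ``missing`` with their original column.
    """
    if reference_id not in alignment:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    row = alignment[reference_id].residues
    # residue number (1-based) -> 1-based column in this alignment
    residue_columns: list[int] = [
        col + 1 for col, ch in enumerate(row) if ch != GAP
    ]
    ref_length = len(residue_columns)
    if column_index_map is not None:
        original_to_trimmed = {
            orig: trimmed + 1 for trimmed, orig in enumerate(column_index_map)
        }
    annotations: list[StretchAnnotation] = []
    for name, (start, end) in named_ranges.items():
        if not (1 <= start <= end <= ref_length):
            raise ValueError(
                f"range {name!r} ({start}, {end}) exceeds reference length {ref_length}"
            )
        cols = residue_columns[start - 1 : end]
        if column_index_map is None:
            columns, missing = list(cols), []
        else:
            columns, missing = [], []
            for residue_number, orig_col in zip(range(start, end + 1), cols):
                trimmed_col = original_to_trimmed.get(orig_col)
                if trimmed_col is None:
                    missing.append((residue_number, orig_col))
                else:
                    columns.append(trimmed_col)
        annotations.append(
            StretchAnnotation(
                name=name,
                reference_range=(start, end),
                columns=columns,
                missing=missing,
            )
        )
    return annotations


def stretch_columns(annotations: Iterable[StretchAnnotation]) -> list[int]:
    """The sorted union of all mapped columns across annotations."""
    cols: set[int] = set()
    for ann in annotations:
        cols.update(ann.columns)
    return sorted(cols)


def column_frequencies(
    alignment: Alignment,
    subset: Iterable[str] | None = None,
    columns: Sequence[int] | None = None,
) -> FrequencyTable:
    """Amino-acid frequencies per column among a row subset.

    Gaps and ``X`` are excluded from numerator and denominator.  A column in
    which every subset row is a gap/X gets ``n_effective`` 0 and an all-zero
    (undefined) frequency row.  ``columns`` optionally attaches 1-based
    original column numbers (defaults to 1..n).
    """
    sub = alignment if subset is None else alignment.subset(subset)
    if len(sub) == 0:
        raise ValueError("empty subset")
    arr = sub.to_array()
    counts = np.zeros((arr.shape[1], len(AMINO_ACIDS)), dtype=np.int64)
    for aa, idx in _AA_INDEX.items():
        counts[:, idx] = (arr == aa).sum(axis=0)
    n_eff = counts.sum(axis=1)
    freqs = np.zeros_like(counts, dtype=float)
    nz = n_eff > 0
    freqs[nz] = counts[nz] / n_eff[nz, None]
    if columns is None:
        columns = np.arange(1, arr.shape[1] + 1)
    else:
        columns = np.asarray(columns, dtype=int)
        if len(columns) != arr.shape[1]:
            raise ValueError("columns length must equal alignment width")
    return FrequencyTable(
        freqs=freqs,
        n_effective=n_eff,
        columns=np.asarray(columns),
        subset_size=len(sub),
    )


def consensus_pattern(table: FrequencyTable) -> tuple[str, pd.DataFrame]:
    """Per-column consensus and the full logo matrix.

    The consensus character is the most frequent amino acid, ties broken
    alphabetically (the alphabet is sorted, so argmax does this); columns
    with ``n_effective`` 0 emit ``-``.  The logo matrix is the frequency
    table plus the consensus column and a tie flag.
    """
    best = table.freqs.argmax(axis=1)
    consensus = np.array(list(AMINO_ACIDS))[best]
    consensus[table.n_effective == 0] = GAP
    maxima = table.freqs.max(axis=1)
    tie = ((table.freqs == maxima[:, None]).sum(axis=1) > 1) & (table.n_effective > 0)
    df = table.to_frame()
    df["consensus"] = consensus
    df["tie"] = tie
    return "".join(consensus), df
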