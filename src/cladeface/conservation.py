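"""Per-position Shannon entropy and variability classification.

The entropy of an alignment column is H = -sum p log2 p over the amino-acid
frequencies p at that column, in bits.  It ranges from 0 for a fully
conserved position to log2(20) ~ 4.32 bits when all twenty amino acids are
equally frequent.  Positions with H strictly above a threshold (1.5 bits by
default, a convention from NLR sequence-diversity studies) are classified
as highly variable.

Gaps and ``X`` are excluded from the frequency denominators, mirroring the
gap handling of the clade-unique residue statistic.  The estimator is the
plug-in (maximum-likelihood) entropy with no small-sample correction: the
quoted bounds 0 and 4.32 are plug-in values, and with clade sizes of a few
dozen sequences bias corrections are secondary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import Alignment, max_entropy_bits
from .msa import FrequencyTable, column_frequencies

DEFAULT_ENTROPY_THRESHOLD = 1.5

VARIABLE = "variable"
CONSERVED = "conserved"
UNDEFINED = "undefined"


@dataclass
class EntropyProfile:
    """Per-column Shannon entropy for one sequence subset.

    ``entropy`` is in bits, NaN where undefined (all-gap columns);
    ``classification`` is ``variable`` iff H > threshold (strict),
    ``conserved`` for defined H <= threshold, ``undefined`` otherwise.
    ``columns`` carries 1-based column numbers.
    """

    entropy: np.ndarray
    n_effective: np.ndarray
    columns: np.ndarray
    threshold: float
    subset_size: int

    @property
    def classification(self) -> np.ndarray:
        out = np.full(self.entropy.shape, CONSERVED, dtype=object)
        defined = ~np.isnan(self.entropy)
        out[defined & (self.entropy > self.threshold)] = VARIABLE
        out[~defined] = UNDEFINED
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": self.columns,
                "n_effective": self.n_effective,
                "H_bits": self.entropy,
                "class": self.classification,
            }
        )


def shannon_entropy(frequencies: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy in bits of one frequency vector.

    Frequencies must be non-negative and sum to 1 within 1e-9.  Zero entries
    contribute nothing (0 log 0 = 0).
    """
    p = np.asarray(frequencies, dtype=float)
    if (p < 0).any():
        raise ValueError("frequencies must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1 (got {total})")
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum()) + 0.0


def _profile_from_table(
    table: FrequencyTable, threshold: float
) -> EntropyProfile:
    p = table.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    entropy = -terms.sum(axis=1)
    entropy = np.where(table.n_effective > 0, entropy, np.nan)
    return EntropyProfile(
        entropy=entropy,
        n_effective=table.n_effective,
        columns=table.columns,
        threshold=threshold,
        subset_size=table.subset_size,
    )


def entropy_profile(
    alignment: Alignment,
    subset: Iterable[str] | None = None,
    threshold: float = DEFAULT_ENTROPY_THRESHOLD,
    columns: Sequence[int] | None = None,
) -> EntropyProfile:
    """Shannon entropy per column over a subset of alignment rows.

    Frequencies come from :func:`cladeface.msa.column_frequencies`
    (gap/X-excluded).  Columns where the subset is all gaps are undefined.
    """
    table = column_frequencies(alignment, subset=subset, columns=columns)
    return _profile_from_table(table, threshold)


def entropy_from_frequencies(
    table: FrequencyTable, threshold: float = DEFAULT_ENTROPY_THRESHOLD
) -> EntropyProfile:
    """Entropy profile from an existing frequency table."""
    return _profile_from_table(table, threshold)


def entropy_bounds() -> tuple[float, float]:
    """The attainable range of column entropy: (0, log2 20)."""
    return 0.0, max_entropy_bits()


# re-exported for convenience in reports
__all__ = [
    "DEFAULT_ENTROPY_THRESHOLD",
    "EntropyProfile",
    "shannon_entropy",
    "entropy_profile",
    "entropy_from_frequencies",
    "entropy_bounds",
    "VARIABLE",
    "CONSERVED",
    "UNDEFINED",
]
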