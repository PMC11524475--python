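"""Sequence-set curation: length filters, exact deduplication and
tree-guided clade assignment.

The curation stage mirrors how helper-NLR (NRC) family datasets are
assembled: full-length sequences are kept inside a plausible length window
(default 750-950 residues), NB-ARC domains inside 300-400 residues,
identical sequences are collapsed, and clades are read off a phylogenetic
tree as the well-supported branches that contain the reference sequences of
exactly one clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import SequenceRecord, Tree

FULL_LENGTH_MIN = 750
FULL_LENGTH_MAX = 950
NBARC_MIN = 300
NBARC_MAX = 400
DEFAULT_SUPPORT_THRESHOLD = 0.8


@dataclass(frozen=True)
class CurationParams:
    """Length windows (inclusive on both ends) and the support threshold
    that qualifies a branch as "well-supported" during clade extraction."""

    full_length_min: int = FULL_LENGTH_MIN
    full_length_max: int = FULL_LENGTH_MAX
    nbarc_min: int = NBARC_MIN
    nbarc_max: int = NBARC_MAX
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD

    def __post_init__(self) -> None:
        if self.full_length_min >= self.full_length_max:
            raise ValueError("full-length window: min must be < max")
        if self.nbarc_min >= self.nbarc_max:
            raise ValueError("domain window: min must be < max")
        if not 0.0 <= self.support_threshold <= 1.0:
            raise ValueError("support threshold must be in [0, 1]")


@dataclass
class CladePartition:
    """Assignment of sequence identifiers to named clades.

    Clade sets are pairwise disjoint; identifiers not claimed by any clade
    are in ``unassigned``.  ``errors`` carries human-readable reports about
    clades that could not be separated on the tree.
    """

    clades: dict[str, frozenset[str]]
    unassigned: frozenset[str]
    errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.clades.items():
            overlap = seen & members
            if overlap:
                raise ValueError(
                    f"clade {name!r} overlaps another clade: {sorted(overlap)[:5]}"
                )
            seen |= members
        if seen & self.unassigned:
            raise ValueError("unassigned overlaps clade members")

    @property
    def all_ids(self) -> frozenset[str]:
        out: set[str] = set(self.unassigned)
        for members in self.clades.values():
            out |= members
        return frozenset(out)

    def clade_of(self, seq_id: str) -> str | None:
        for name, members in self.clades.items():
            if seq_id in members:
                return name
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clade": name, "id": sid}
            for name, members in self.clades.items()
            for sid in sorted(members)
        ]
        rows += [{"clade": "", "id": sid} for sid in sorted(self.unassigned)]
        return pd.DataFrame(rows, columns=["clade", "id"])


def filter_full_length(
    records: Sequence[SequenceRecord],
    min_length: int = FULL_LENGTH_MIN,
    max_length: int = FULL_LENGTH_MAX,
) -> list[SequenceRecord]:
    """Keep records whose ungapped length is within [min, max], inclusive.

    Order is preserved; an empty result is allowed.
    """
    return [rec for rec in records if min_length <= rec.length <= max_length]


def filter_domain_length(
    records: Sequence[SequenceRecord],
    domain_ranges: Mapping[str, tuple[int, int]],
    min_length: int = NBARC_MIN,
    max_length: int = NBARC_MAX,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Keep records whose annotated domain span is within [min, max].

    ``domain_ranges`` maps id -> (start, end), 1-based inclusive in ungapped
    sequence coordinates.  Records lacking a range are dropped and listed in
    the returned report with reason ``no_domain_range``; out-of-window spans
    are listed with reason ``span_out_of_range``.
    """
    kept: list[SequenceRecord] = []
    dropped: list[dict[str, object]] = []
    for rec in records:
        rng = domain_ranges.get(rec.id)
        if rng is None:
            dropped.append({"id": rec.id, "reason": "no_domain_range", "span": ""})
            continue
        start, end = rng
        if not (1 <= start <= end <= rec.length):
            raise ValueError(
                f"domain range {rng} outside sequence bounds for {rec.id!r}"
            )
        span = end - start + 1
        if min_length <= span <= max_length:
            kept.append(rec)
        else:
            dropped.append(
                {"id": rec.id, "reason": "span_out_of_range", "span": span}
            )
    report = pd.DataFrame(dropped, columns=["id", "reason", "span"])
    return kept, report


def deduplicate(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """Collapse exact full-length duplicates.

    The representative is the first occurrence in input order; the returned
    map lists representative id -> ids of the collapsed members (excluding
    the representative itself).  Idempotent.  Only exact identity of the
    ungapped sequence counts: a sequence equal to a prefix of another is a
    distinct sequence and is kept.
    """
    survivors: list[SequenceRecord] = []
    by_seq: dict[str, str] = {}
    duplicate_map: dict[str, list[str]] = {}
    for rec in records:
        seq = rec.ungapped
        rep = by_seq.get(seq)
        if rep is None:
            by_seq[seq] = rec.id
            survivors.append(rec)
        else:
            duplicate_map.setdefault(rep, []).append(rec.id)
    return survivors, duplicate_map


def extract_clades(
    tree: Tree,
    reference_map: Mapping[str, Iterable[str]],
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
) -> CladePartition:
    """Assign tree leaves to clades by reference membership.

    For each clade name the assigned leaf set is the smallest internal
    branch that (a) contains all of that clade's reference leaves,
    (b) contains no reference of any other clade, and (c) carries a support
    value >= ``support_threshold``.  Branches without a support value do not
    qualify (missing support is missing, not zero).  Leaves covered by no
    qualifying branch go to ``unassigned``.
    Two clades whose references cannot be separated by any branch are
    reported and both left unassigned.
    """
    ref_sets = {name: frozenset(ids) for name, ids in reference_map.items()}
    all_refs: dict[str, str] = {}
    for name, ids in ref_sets.items():
        if not ids:
            raise ValueError(f"clade {name!r} has no reference leaves")
        missing = ids - tree.leaves
        if missing:
            raise ValueError(
                f"reference leaves of clade {name!r} not in tree: {sorted(missing)}"
            )
        for sid in ids:
            if sid in all_refs:
                raise ValueError(
                    f"leaf {sid!r} is a reference of both {all_refs[sid]!r} and {name!r}"
                )
            all_refs[sid] = name

    branches = tree.internal_branches()
    errors: list[str] = []
    assigned: dict[str, frozenset[str]] = {}
    for name, refs in ref_sets.items():
        foreign = frozenset(all_refs) - refs
        best: frozenset[str] | None = None
        for br in branches:
            if br.support is None or br.support < support_threshold:
                continue
            if not refs <= br.leaves:
                continue
            if br.leaves & foreign:
                continue
            if best is None or len(br.leaves) < len(best):
                best = br.leaves
        if best is None:
            errors.append(
                f"clade {name!r}: no well-supported branch separates its "
                f"references from other clades"
            )
        else:
            assigned[name] = best

    # Branches of different clades may overlap only if one clade's qualifying
    # branch swallowed another clade's references-free leaves; overlaps between
    # two *assigned* clades indicate inseparable clades -> drop both.
    names = list(assigned)
    inseparable: set[str] = set()
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if assigned[a] & assigned[b]:
                inseparable.update((a, b))
                errors.append(
                    f"clades {a!r} and {b!r} resolve to overlapping branches"
                )
    for name in inseparable:
        del assigned[name]

    covered: set[str] = set()
    for members in assigned.values():
        covered |= members
    unassigned = frozenset(tree.leaves - covered)
    return CladePartition(clades=assigned, unassigned=unassigned, errors=errors)


def read_reference_map(path: str | Path) -> dict[str, set[str]]:
    """Read a (clade, id) TSV with a header row into a reference map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"clade", "id"} <= set(df.columns):
        raise ValueError("reference map TSV must have columns: clade, id")
    out: dict[str, set[str]] = {}
    for clade, sid in zip(df["clade"], df["id"]):
        out.setdefault(clade, set()).add(sid)
    return out


def read_domain_ranges(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read an (id, start, end) TSV with a header row; 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "start": int, "end": int})
    if not {"id", "start", "end"} <= set(df.columns):
        raise ValueError("domain range TSV must have columns: id, start, end")
    return {
        str(r.id): (int(r.start), int(r.end)) for r in df.itertuples(index=False)
    }
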