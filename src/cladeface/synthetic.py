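"""Synthetic test-data generators with known ground truth.

Two generators cover the two halves of the pipeline:

* :func:`generate_clade_family` builds a multi-clade protein family
  alignment with a clade-conserved background and *planted* clade-
  diagnostic polymorphisms at known columns, together with the generating
  partition, a star-of-clades tree, and a truth record.  Planted sites are
  realized with exact fixation/leak counts (rounded proportions) so the
  ground truth is reproducible at any sample size.
* :func:`generate_toy_dimer` builds a two-chain structure of single-atom
  residues in which exactly the configured residue pairs sit just inside a
  distance cutoff and every other inter-chain distance is far outside it.

All randomness flows through one seeded numpy generator; equal seeds give
byte-identical outputs.  The background model is deliberately minimal —
uniform draws over the 20 amino acids for variable columns, a single
residue for invariant columns, independent per-character gaps — which
exposes both entropy extremes (0 and log2 20 bits) without modelling
substitution processes or indel evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curation import CladePartition
from .io_formats import (
    AMINO_ACIDS,
    GAP,
    Alignment,
    Atom,
    Residue,
    SequenceRecord,
    Structure,
    Tree,
    read_newick,
)

_AA = np.array(list(AMINO_ACIDS))


@dataclass(frozen=True)
class PlantedSite:
    """A clade-diagnostic polymorphism planted at one alignment column.

    The owning (query) clade carries ``clade_residue`` at an exact fraction
    ``query_fixation`` of its rows; all other rows carry
    ``background_residue`` except an exact fraction ``subject_leak`` that
    also carry the clade residue.
    """

    column: int  # 1-based
    clade_residue: str
    background_residue: str
    query_fixation: float = 1.0
    subject_leak: float = 0.0

    def __post_init__(self) -> None:
        if self.clade_residue == self.background_residue:
            raise ValueError("clade and background residues must differ")
        for res in (self.clade_residue, self.background_residue):
            if res not in AMINO_ACIDS:
                raise ValueError(f"not an amino acid: {res!r}")
        if not 0.8 < self.query_fixation <= 1.0:
            raise ValueError("query_fixation must be in (0.8, 1]")
        if not 0.0 <= self.subject_leak < 0.02:
            raise ValueError("subject_leak must be in [0, 0.02)")


@dataclass(frozen=True)
class FamilyParams:
    """Parameters of the synthetic clade family."""

    n_clades: int = 3
    seqs_per_clade: int = 40
    n_columns: int = 300
    background_conservation: float = 0.5
    planted_sites: dict[str, tuple[PlantedSite, ...]] = field(default_factory=dict)
    gap_rate: float = 0.05
    length_jitter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clades < 2 or self.seqs_per_clade < 2:
            raise ValueError("need >= 2 clades of >= 2 sequences")
        if self.n_columns < 1:
            raise ValueError("n_columns must be positive")
        if not 0.0 <= self.background_conservation <= 1.0:
            raise ValueError("background_conservation must be in [0, 1]")
        if not 0.0 <= self.gap_rate < 0.5:
            raise ValueError("gap_rate must be in [0, 0.5)")
        if self.length_jitter < 0:
            raise ValueError("length_jitter must be >= 0")
        names = self.clade_names
        unknown = set(self.planted_sites) - set(names)
        if unknown:
            raise ValueError(f"planted sites reference unknown clades: {unknown}")
        seen: set[int] = set()
        for sites in self.planted_sites.values():
            for site in sites:
                if not 1 <= site.column <= self.n_columns:
                    raise ValueError(f"planted column {site.column} out of range")
                if site.column in seen:
                    raise ValueError(
                        f"planted column {site.column} collides with another site"
                    )
                seen.add(site.column)

    @property
    def clade_names(self) -> list[str]:
        return [f"clade{i + 1}" for i in range(self.n_clades)]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated family: the realized planted sites, the
    family-pooled generating frequencies per column, and the seed."""

    planted: list[tuple[str, int, str]]  # (clade, column, clade_residue)
    generating_freqs: np.ndarray  # (n_columns, 20), pooled over all rows
    column_kind: np.ndarray  # 'invariant' | 'variable' | 'planted'
    seed: int


def default_planted_sites(
    params_columns: int,
    clade_names: Sequence[str],
    sites_per_clade: int,
    rng: np.random.Generator,
    query_fixation: float = 1.0,
    subject_leak: float = 0.0,
) -> dict[str, tuple[PlantedSite, ...]]:
    """Draw non-colliding planted sites with distinct residue pairs."""
    total = sites_per_clade * len(clade_names)
    if total > params_columns:
        raise ValueError("more planted sites than columns")
    columns = rng.choice(params_columns, size=total, replace=False) + 1
    out: dict[str, tuple[PlantedSite, ...]] = {}
    k = 0
    for name in clade_names:
        sites = []
        for _ in range(sites_per_clade):
            res_pair = rng.choice(20, size=2, replace=False)
            sites.append(
                PlantedSite(
                    column=int(columns[k]),
                    clade_residue=str(_AA[res_pair[0]]),
                    background_residue=str(_AA[res_pair[1]]),
                    query_fixation=query_fixation,
                    subject_leak=subject_leak,
                )
            )
            k += 1
        out[name] = tuple(sites)
    return out


def _exact_count(fraction: float, n: int) -> int:
    return int(round(fraction * n))


def generate_clade_family(
    params: FamilyParams,
) -> tuple[Alignment, CladePartition, Tree, SyntheticTruth]:
    """Generate the family alignment, partition, tree and ground truth."""
    rng = np.random.default_rng(params.seed)
    names = params.clade_names
    n_rows = params.n_clades * params.seqs_per_clade
    n_cols = params.n_columns
    row_ids = [
        f"{name}_s{j + 1}" for name in names for j in range(params.seqs_per_clade)
    ]
    clade_rows = {
        name: np.arange(i * params.seqs_per_clade, (i + 1) * params.seqs_per_clade)
        for i, name in enumerate(names)
    }

    planted_cols = {
        site.column: (name, site)
        for name, sites in params.planted_sites.items()
        for site in sites
    }

    matrix = np.empty((n_rows, n_cols), dtype="U1")
    kind = np.empty(n_cols, dtype=object)
    gen_freqs = np.zeros((n_cols, 20))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    invariant_draw = rng.random(n_cols) < params.background_conservation
    for j in range(n_cols):
        col = j + 1
        if col in planted_cols:
            name, site = planted_cols[col]
            kind[j] = "planted"
            qrows = clade_rows[name]
            srows = np.setdiff1d(np.arange(n_rows), qrows)
            matrix[:, j] = site.background_residue
            n_fix = _exact_count(site.query_fixation, len(qrows))
            fixed = rng.choice(qrows, size=n_fix, replace=False)
            matrix[fixed, j] = site.clade_residue
            n_leak = _exact_count(site.subject_leak, len(srows))
            if n_leak:
                leaked = rng.choice(srows, size=n_leak, replace=False)
                matrix[leaked, j] = site.clade_residue
            p_clade = (n_fix + n_leak) / n_rows
            gen_freqs[j, aa_index[site.clade_residue]] = p_clade
            gen_freqs[j, aa_index[site.background_residue]] = 1.0 - p_clade
        elif invariant_draw[j]:
            kind[j] = "invariant"
            res = rng.integers(20)
            matrix[:, j] = _AA[res]
            gen_freqs[j, res] = 1.0
        else:
            kind[j] = "variable"
            matrix[:, j] = _AA[rng.integers(20, size=n_rows)]
            gen_freqs[j, :] = 1.0 / 20.0

    if params.gap_rate > 0:
        gap_mask = rng.random((n_rows, n_cols)) < params.gap_rate
        matrix[gap_mask] = GAP
    if params.length_jitter > 0:
        starts = rng.integers(0, params.length_jitter + 1, size=n_rows)
        ends = rng.integers(0, params.length_jitter + 1, size=n_rows)
        for i in range(n_rows):
            if starts[i]:
                matrix[i, : starts[i]] = GAP
            if ends[i]:
                matrix[i, n_cols - ends[i] :] = GAP

    records = [
        SequenceRecord(id=sid, residues="".join(matrix[i]))
        for i, sid in enumerate(row_ids)
    ]
    alignment = Alignment(records)
    partition = CladePartition(
        clades={
            name: frozenset(row_ids[r] for r in rows)
            for name, rows in clade_rows.items()
        },
        unassigned=frozenset(),
    )
    tree = read_newick(_star_of_clades_newick(names, params.seqs_per_clade))
    truth = SyntheticTruth(
        planted=[
            (name, site.column, site.clade_residue)
            for name, sites in params.planted_sites.items()
            for site in sites
        ],
        generating_freqs=gen_freqs,
        column_kind=kind,
        seed=params.seed,
    )
    return alignment, partition, tree, truth


def _star_of_clades_newick(names: Sequence[str], seqs_per_clade: int) -> str:
    """Star of clades: support 1.0 on every clade stem, within-clade
    resolution as unlabeled ladders."""
    clades = []
    for name in names:
        tips = [f"{name}_s{j + 1}" for j in range(seqs_per_clade)]
        sub = f"({tips[0]},{tips[1]})"
        for tip in tips[2:]:
            sub = f"({sub},{tip})"
        clades.append(sub + "1.0")
    return "(" + ",".join(clades) + ");"


# ---------------------------------------------------------------------------
# Toy dimers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimerParams:
    """A two-chain toy structure with configured inter-chain contacts.

    Each residue is a single carbon pseudo-atom.  The configured pairs are
    placed at ``cutoff - 0.5`` Angstrom; every other inter-chain distance
    exceeds ``cutoff + 2``.
    """

    n_residues_per_chain: int = 10
    contact_residue_pairs: tuple[tuple[int, int], ...] = ()
    cutoff: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues_per_chain < 1:
            raise ValueError("need at least one residue per chain")
        if not 0.0 < self.cutoff <= 20.0:
            raise ValueError("cutoff must be in (0, 20] for the toy geometry")
        seen_a: set[int] = set()
        seen_b: set[int] = set()
        for ra, rb in self.contact_residue_pairs:
            for r in (ra, rb):
                if not 1 <= r <= self.n_residues_per_chain:
                    raise ValueError(f"contact residue {r} out of range")
            if ra in seen_a or rb in seen_b:
                raise ValueError(
                    "geometrically infeasible: a residue may appear in at "
                    "most one contact pair"
                )
            seen_a.add(ra)
            seen_b.add(rb)


def generate_toy_dimer(params: DimerParams) -> Structure:
    """Two single-atom-residue chains with exactly the configured contacts."""
    spacing = 30.0
    far_y = 200.0
    contact_a = {ra: k for k, (ra, _) in enumerate(params.contact_residue_pairs)}
    contact_b = {rb: k for k, (_, rb) in enumerate(params.contact_residue_pairs)}
    n_pairs = len(params.contact_residue_pairs)

    def build_chain(chain_id: str, contacts: dict[int, int], y_contact: float,
                    y_far: float) -> list[Residue]:
        residues = []
        free = 0
        for num in range(1, params.n_residues_per_chain + 1):
            if num in contacts:
                x, y = spacing * contacts[num], y_contact
            else:
                x, y = spacing * (n_pairs + free), y_far
                free += 1
            atom = Atom(name="CA", element="C", x=x, y=y, z=0.0, radius=1.70)
            residues.append(
                Residue(chain_id=chain_id, number=num, icode="", name="ALA",
                        atoms=[atom])
            )
        return residues

    chain_a = build_chain("A", contact_a, 0.0, 0.0)
    chain_b = build_chain("B", contact_b, params.cutoff - 0.5, far_y)
    return Structure(chains={"A": chain_a, "B": chain_b})
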