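"""Readers, writers and core domain types.

The pipeline operates on four kinds of objects: protein sequences
(:class:`SequenceRecord`, :class:`Alignment`), phylogenetic trees
(:class:`Tree`), atomic structures (:class:`Structure`) and tab-separated
report tables.  All parsing goes through the standard libraries (Biopython
for FASTA, DendroPy for newick, gemmi for PDB/mmCIF); this module adds the
strict validation the downstream statistics rely on.

Conventions
-----------
* The residue alphabet is the 20 standard amino acids plus ``-`` (gap) and
  ``X`` (unknown).  ``.`` gaps are normalised to ``-`` on read; lowercase
  letters are upper-cased.
* Alignment columns are numbered 1-based in every public table.
* Structure residue numbering is taken verbatim from the coordinate file
  (author numbering); hydrogens are discarded on read and van der Waals
  radii are assigned per element from a fixed table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import gemmi
import numpy as np
from Bio import SeqIO

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALLOWED_CHARS = frozenset(AMINO_ACIDS + GAP + UNKNOWN)

#: Van der Waals radii in Angstrom, by element symbol.  Elements not listed
#: fall back to the carbon radius.
VDW_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence, possibly gapped.

    Parameters
    ----------
    id
        Non-empty identifier, unique within any collection.
    residues
        Upper-case string over the 20 amino-acid letters plus ``-`` and ``X``.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence identifier must be non-empty")
        bad = set(self.residues) - ALLOWED_CHARS
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)!r}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    @property
    def length(self) -> int:
        """Residue count excluding gaps."""
        return len(self.ungapped)

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """An ordered collection of equal-length :class:`SequenceRecord`.

    The aligned residue matrix is the substrate of all column statistics;
    it is exposed as a numpy array of single characters via :meth:`to_array`.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise FormatError("alignment must contain at least one sequence")
        n = len(records[0].residues)
        if n == 0:
            raise FormatError("alignment columns must be > 0")
        for rec in records:
            if len(rec.residues) != n:
                raise FormatError(
                    f"record {rec.id!r} has length {len(rec.residues)}, expected {n}"
                )
        _check_unique_ids(records)
        self.records: list[SequenceRecord] = records
        self.n_columns: int = n
        self._index = {rec.id: i for i, rec in enumerate(records)}
        self._array: np.ndarray | None = None

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self.records[self._index[seq_id]]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def to_array(self) -> np.ndarray:
        """Return the (n_sequences, n_columns) matrix of single characters."""
        if self._array is None:
            self._array = np.array(
                [list(rec.residues) for rec in self.records], dtype="U1"
            )
        return self._array

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Row subset in the alignment's original order."""
        wanted = set(ids)
        missing = wanted - set(self._index)
        if missing:
            raise KeyError(f"identifiers not in alignment: {sorted(missing)}")
        return Alignment([rec for rec in self.records if rec.id in wanted])


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate sequence identifier {rec.id!r}")
        seen.add(rec.id)


def _normalise_residues(raw: str) -> str:
    return raw.upper().replace(".", GAP)


def read_fasta(path: str | Path, require_aligned: bool = False) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    One record per entry, order preserved.  ``.`` gaps are normalised to
    ``-``.  With ``require_aligned`` all entries must have equal (gapped)
    length.
    """
    path = Path(path)
    records = [
        SequenceRecord(id=seq.id, residues=_normalise_residues(str(seq.seq)))
        for seq in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    _check_unique_ids(records)
    if require_aligned:
        lengths = {len(rec.residues) for rec in records}
        if len(lengths) > 1:
            raise FormatError(
                f"aligned FASTA expected but lengths differ: {sorted(lengths)}"
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    return Alignment(read_fasta(path, require_aligned=True))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class Branch:
    """An internal branch of a rooted tree: its descendant leaf set and the
    support value attached to it (``None`` when the file carries none)."""

    leaves: frozenset[str]
    support: float | None


class Tree:
    """A parsed phylogenetic tree with optional branch supports.

    Tree *construction* is out of scope; this type only carries a tree read
    from newick (e.g. a FastTree output with SH-like supports in [0, 1]).
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        leaves = [lf.taxon.label if lf.taxon else "" for lf in dtree.leaf_node_iter()]
        if any(not name for name in leaves):
            raise FormatError("tree contains an empty leaf name")
        if len(set(leaves)) != len(leaves):
            raise FormatError("tree leaf names are not unique")
        self.leaves: frozenset[str] = frozenset(leaves)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def internal_branches(self) -> list[Branch]:
        """All internal, non-root branches as (leaf set, support) pairs.

        A support is parsed from the internal node label when it is a float
        in [0, 1]; otherwise it is recorded as missing (``None``), never
        coerced to zero.
        """
        out: list[Branch] = []
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root or node.is_leaf():
                continue
            label = node.label
            support: float | None = None
            if label is not None:
                try:
                    value = float(label)
                except ValueError:
                    value = None
                if value is not None:
                    if not 0.0 <= value <= 1.0:
                        raise FormatError(
                            f"branch support {value} outside [0, 1]"
                        )
                    support = value
            leafset = frozenset(
                lf.taxon.label for lf in node.leaf_iter() if lf.taxon
            )
            out.append(Branch(leaves=leafset, support=support))
        return out

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(
            self._tree.as_string(schema="newick", suppress_rooting=True)
        )


def read_newick(path_or_text: str | Path) -> Tree:
    """Parse newick, from a file path or a literal newick string."""
    raw = str(path_or_text)
    looks_like_newick = "(" in raw or raw.endswith(";")
    if not looks_like_newick and Path(raw).exists():
        text = Path(raw).read_text()
    elif isinstance(path_or_text, Path) or (not looks_like_newick):
        text = Path(raw).read_text()
    else:
        text = raw
    if text.count("(") != text.count(")"):
        raise FormatError("unbalanced parentheses in newick")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"malformed newick: {exc}") from exc
    return Tree(dtree)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise FormatError(f"atom {self.name!r} has non-positive radius")

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)


@dataclass
class Structure:
    """Heavy-atom coordinates grouped by chain and residue."""

    chains: dict[str, list[Residue]]

    def __post_init__(self) -> None:
        if not self.chains or all(not resl for resl in self.chains.values()):
            raise FormatError("structure has no residues")
        for chain_id, residues in self.chains.items():
            keys = [r.key for r in residues]
            if len(set(keys)) != len(keys):
                raise FormatError(
                    f"duplicate residue numbers in chain {chain_id!r}"
                )

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for resl in self.chains.values() for r in resl)

    def atoms_of(self, chain_id: str) -> list[tuple[Residue, Atom]]:
        return [(res, atom) for res in self.chains[chain_id] for atom in res.atoms]

    def atom_coords(self) -> np.ndarray:
        coords = [
            atom.coords
            for resl in self.chains.values()
            for res in resl
            for atom in res.atoms
        ]
        return np.asarray(coords, dtype=float)


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


def read_structure(
    path: str | Path,
    fmt: str | None = None,
    include_ligands: bool = False,
) -> Structure:
    """Read a PDB or mmCIF coordinate file into a :class:`Structure`.

    Only the first model is read; alternate locations other than '' / 'A'
    are dropped; hydrogens (and deuterium) are discarded; waters are always
    excluded.  Ligands and other het-groups are excluded unless
    ``include_ligands`` is set.  Format is inferred from the extension when
    ``fmt`` is not given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if fmt == "pdb":
        st = gemmi.read_pdb(str(path))
    elif fmt == "mmcif":
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    else:
        raise ValueError(f"unknown structure format {fmt!r}")
    st.setup_entities()
    if len(st) == 0:
        raise FormatError(f"empty structure in {path}")
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.is_water():
                continue
            if not include_ligands and res.het_flag == "H":
                continue
            atoms: list[Atom] = []
            for atom in res:
                if atom.altloc not in ("", "\x00", "A"):
                    continue
                element = atom.element.name
                if element in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=element,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        radius=vdw_radius(element),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        number=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        name=res.name,
                        atoms=atoms,
                    )
                )
        if residues:
            chains[chain.name] = residues
    return Structure(chains=chains)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as minimal single-model PDB."""
    st = gemmi.Structure()
    st.name = "cladeface"
    model = gemmi.Model("1")
    for chain_id, residues in structure.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(atom.x, atom.y, atom.z)
                gatom.occ = 1.0
                gatom.b_iso = 0.0
                gres.add_atom(gatom)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def max_entropy_bits() -> float:
    """log2(20): the entropy of a uniformly variable column, in bits."""
    return math.log2(len(AMINO_ACIDS))
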