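"""Homodimer interface extraction: contacts, stretches, buried surface area.

Given a two-protomer structure, this module

* lists inter-chain residue contacts at a distance cutoff (6 Angstrom by
  default, permissive enough to catch both short- and long-range
  interactions).  The distance between two residues is the minimum over
  all heavy-atom pairs and the cutoff comparison is ``<=``;
* groups each chain's interface residues into *stretches*: within each
  (own-domain, partner-domain) contact class, maximal runs of consecutive
  residue numbers.  Two contiguous runs contacting different partner
  domains therefore form distinct stretches;
* computes solvent-accessible surface area (SASA) with a Shrake-Rupley
  numerical scheme on a deterministic Fibonacci spiral lattice (no
  randomness, bit-reproducible), and buried surface area (BSA) per
  protomer as SASA(chain alone) - SASA(chain in complex).

Hydrogens never enter (they are dropped on file read); radii are per-element
van der Waals values from a fixed table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_formats import Structure

DEFAULT_DISTANCE_CUTOFF = 6.0
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SPHERE_POINTS = 960


@dataclass(frozen=True)
class InterfaceParams:
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF
    probe_radius: float = DEFAULT_PROBE_RADIUS
    sphere_points: int = DEFAULT_SPHERE_POINTS

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.sphere_points < 100:
            raise ValueError("need >= 100 sphere points")


@dataclass(frozen=True)
class ContactPair:
    """An inter-chain residue contact and its minimum heavy-atom distance."""

    residue_a: int
    residue_b: int
    distance: float


@dataclass
class Stretch:
    """A maximal run of consecutive interface residue numbers sharing one
    (own-domain, partner-domain) contact class."""

    name: str
    chain_id: str
    own_domain: str
    partner_domain: str
    start: int
    end: int
    residues: list[int]


@dataclass
class InterfaceReport:
    contact_pairs: list[ContactPair]
    interface_residues: dict[str, list[int]]
    stretches: dict[str, list[Stretch]] | None
    bsa_per_protomer: dict[str, float] | None
    bsa_total: float | None

    def contacts_frame(self) -> pd.DataFrame:
        chain_a, chain_b = list(self.interface_residues)
        return pd.DataFrame(
            [
                {
                    f"residue_{chain_a}": p.residue_a,
                    f"residue_{chain_b}": p.residue_b,
                    "min_distance_A": round(p.distance, 3),
                }
                for p in self.contact_pairs
            ]
        )


def _chain_atom_arrays(structure: Structure, chain_id: str):
    if chain_id not in structure.chains:
        raise KeyError(f"chain {chain_id!r} not in structure")
    coords, radii, res_numbers = [], [], []
    for res, atom in structure.atoms_of(chain_id):
        coords.append(atom.coords)
        radii.append(atom.radius)
        res_numbers.append(res.number)
    if not coords:
        raise ValueError(f"chain {chain_id!r} has no atoms")
    return (
        np.asarray(coords, dtype=float),
        np.asarray(radii, dtype=float),
        np.asarray(res_numbers, dtype=int),
    )


def find_interface_residues(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    cutoff: float = DEFAULT_DISTANCE_CUTOFF,
) -> tuple[list[ContactPair], dict[str, list[int]]]:
    """Inter-chain residue contacts at ``cutoff`` (minimum heavy-atom
    distance, inclusive comparison).

    Returns the contact pairs sorted by (residue_a, residue_b) and the
    per-chain interface residue sets (sorted), which are the projections of
    the pairs onto each chain.
    """
    xa, _, res_a = _chain_atom_arrays(structure, chain_a)
    xb, _, res_b = _chain_atom_arrays(structure, chain_b)
    tree_a, tree_b = cKDTree(xa), cKDTree(xb)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)
    best: dict[tuple[int, int], float] = {}
    for ia, neighbours in enumerate(pairs):
        for ib in neighbours:
            d = float(np.linalg.norm(xa[ia] - xb[ib]))
            key = (int(res_a[ia]), int(res_b[ib]))
            if d <= cutoff and (key not in best or d < best[key]):
                best[key] = d
    contact_pairs = [
        ContactPair(residue_a=a, residue_b=b, distance=d)
        for (a, b), d in sorted(best.items())
    ]
    residues = {
        chain_a: sorted({p.residue_a for p in contact_pairs}),
        chain_b: sorted({p.residue_b for p in contact_pairs}),
    }
    return contact_pairs, residues


# ---------------------------------------------------------------------------
# Stretches
# ---------------------------------------------------------------------------

def _domain_of(residue_number: int, boundaries: Mapping[str, tuple[int, int]]) -> str | None:
    for name, (start, end) in boundaries.items():
        if start <= residue_number <= end:
            return name
    return None


def derive_stretches(
    contact_pairs: Sequence[ContactPair],
    domain_boundaries: Mapping[str, Mapping[str, tuple[int, int]]],
    chain_a: str,
    chain_b: str,
) -> dict[str, list[Stretch]]:
    """Group interface residues into named stretches per chain.

    ``domain_boundaries`` maps chain id -> domain name -> (start, end)
    residue range (1-based inclusive, author numbering).  Each interface
    residue is labeled by the domain(s) of the partner residues it
    contacts; within every (own-domain, partner-domain) class, maximal runs
    of consecutive residue numbers become stretches, named ``s1``, ``s2``,
    ... per chain in ascending residue order.  A residue contacting several
    partner domains joins every relevant class.
    """
    for cid in (chain_a, chain_b):
        if cid not in domain_boundaries:
            raise ValueError(f"no domain boundaries for chain {cid!r}")

    # per chain: residue -> set of partner domains contacted
    partner_domains: dict[str, dict[int, set[str]]] = {chain_a: {}, chain_b: {}}
    for pair in contact_pairs:
        dom_b = _domain_of(pair.residue_b, domain_boundaries[chain_b])
        dom_a = _domain_of(pair.residue_a, domain_boundaries[chain_a])
        if dom_b is None:
            raise ValueError(
                f"residue {pair.residue_b} of chain {chain_b!r} outside all domains"
            )
        if dom_a is None:
            raise ValueError(
                f"residue {pair.residue_a} of chain {chain_a!r} outside all domains"
            )
        partner_domains[chain_a].setdefault(pair.residue_a, set()).add(dom_b)
        partner_domains[chain_b].setdefault(pair.residue_b, set()).add(dom_a)

    out: dict[str, list[Stretch]] = {}
    for cid in (chain_a, chain_b):
        classes: dict[tuple[str, str], list[int]] = {}
        for residue, doms in partner_domains[cid].items():
            own = _domain_of(residue, domain_boundaries[cid])
            assert own is not None  # checked above via the pair loop
            for dom in doms:
                classes.setdefault((own, dom), []).append(residue)
        runs: list[Stretch] = []
        for (own, dom), residues in classes.items():
            residues = sorted(set(residues))
            run_start = residues[0]
            prev = residues[0]
            members = [residues[0]]
            for r in residues[1:] + [None]:  # type: ignore[list-item]
                if r is not None and r == prev + 1:
                    members.append(r)
                    prev = r
                    continue
                runs.append(
                    Stretch(
                        name="",
                        chain_id=cid,
                        own_domain=own,
                        partner_domain=dom,
                        start=run_start,
                        end=prev,
                        residues=list(members),
                    )
                )
                if r is not None:
                    run_start = prev = r
                    members = [r]
        runs.sort(key=lambda s: (s.start, s.end, s.partner_domain))
        for i, s in enumerate(runs):
            s.name = f"s{i + 1}"
        out[cid] = runs
    return out


def stretches_frame(stretches: Mapping[str, Sequence[Stretch]]) -> pd.DataFrame:
    rows = [
        {
            "chain": s.chain_id,
            "stretch": s.name,
            "own_domain": s.own_domain,
            "partner_domain": s.partner_domain,
            "start": s.start,
            "end": s.end,
            "n_residues": len(s.residues),
        }
        for chain in stretches.values()
        for s in chain
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SASA / BSA
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (spiral
    lattice); no randomness, so areas are bit-reproducible."""
    k = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa_atoms(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Shrake-Rupley style.

    For each atom, test points on the sphere of radius (vdW + probe); the
    accessible fraction (points inside no neighbour's expanded sphere)
    times the full sphere area gives the atom's SASA.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if (radii <= 0).any():
        raise ValueError("all radii must be positive")
    n = len(coords)
    expanded = radii + probe_radius
    unit = _fibonacci_sphere(sphere_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.zeros(n)
    for i in range(n):
        # neighbours whose expanded spheres can clip atom i's test sphere
        neighbour_idx = tree.query_ball_point(coords[i], expanded[i] + max_r)
        neighbour_idx = [j for j in neighbour_idx if j != i]
        points = coords[i] + expanded[i] * unit
        if neighbour_idx:
            nb = np.asarray(neighbour_idx)
            diff = points[:, None, :] - coords[nb][None, :, :]
            dist2 = np.einsum("pnk,pnk->pn", diff, diff)
            buried = (dist2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = sphere_points
        areas[i] = (accessible / sphere_points) * 4.0 * np.pi * expanded[i] ** 2
    return areas


def sasa(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
    chains: Sequence[str] | None = None,
) -> tuple[float, dict[str, dict[tuple[int, str], float]]]:
    """Total and per-residue SASA of a structure (or a chain subset).

    Returns (total area, {chain: {(residue number, icode): area}}).
    """
    chain_ids = list(structure.chains) if chains is None else list(chains)
    coords, radii, owner = [], [], []
    for cid in chain_ids:
        for res in structure.chains[cid]:
            for atom in res.atoms:
                coords.append(atom.coords)
                radii.append(atom.radius)
                owner.append((cid, res.key))
    areas = sasa_atoms(
        np.asarray(coords), np.asarray(radii), probe_radius, sphere_points
    )
    per_residue: dict[str, dict[tuple[int, str], float]] = {c: {} for c in chain_ids}
    for (cid, key), area in zip(owner, areas):
        per_residue[cid][key] = per_residue[cid].get(key, 0.0) + float(area)
    return float(areas.sum()), per_residue


def buried_surface_area(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    params: InterfaceParams = InterfaceParams(),
) -> tuple[dict[str, float], float]:
    """Per-protomer and total buried surface area of a two-chain complex.

    BSA of a protomer is SASA(chain alone) minus its SASA within the
    complex; the total is the sum over both protomers.  Tiny negative
    values from lattice discretisation are clamped to zero.
    """
    kwargs = dict(
        probe_radius=params.probe_radius, sphere_points=params.sphere_points
    )
    complex_total, complex_res = sasa(
        structure, chains=[chain_a, chain_b], **kwargs
    )
    per_protomer: dict[str, float] = {}
    for cid in (chain_a, chain_b):
        alone_total, _ = sasa(structure, chains=[cid], **kwargs)
        in_complex = sum(complex_res[cid].values())
        per_protomer[cid] = max(0.0, alone_total - in_complex)
    return per_protomer, sum(per_protomer.values())


def interface_report(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    params: InterfaceParams = InterfaceParams(),
    domain_boundaries: Mapping[str, Mapping[str, tuple[int, int]]] | None = None,
) -> InterfaceReport:
    """Full interface analysis: contacts, optional stretches, BSA."""
    contact_pairs, residues = find_interface_residues(
        structure, chain_a, chain_b, cutoff=params.distance_cutoff
    )
    stretches = None
    if domain_boundaries is not None:
        stretches = derive_stretches(
            contact_pairs, domain_boundaries, chain_a, chain_b
        )
    per_protomer, total = buried_surface_area(structure, chain_a, chain_b, params)
    return InterfaceReport(
        contact_pairs=contact_pairs,
        interface_residues=residues,
        stretches=stretches,
        bsa_per_protomer=per_protomer,
        bsa_total=total,
    )
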