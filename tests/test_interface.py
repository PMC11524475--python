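"""Contacts, stretch grouping, SASA and buried surface area."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cladeface import (
    InterfaceParams,
    buried_surface_area,
    derive_stretches,
    find_interface_residues,
    generate_toy_dimer,
)
from cladeface.interface import sasa, sasa_atoms
from cladeface.io_formats import Atom, Residue, Structure
from cladeface.synthetic import DimerParams


def single_atom_structure(positions: dict[str, list[tuple[float, float, float]]],
                          radius: float = 1.70) -> Structure:
    chains = {}
    for cid, coords in positions.items():
        chains[cid] = [
            Residue(cid, i + 1, "", "ALA",
                    [Atom("CA", "C", x, y, z, radius)])
            for i, (x, y, z) in enumerate(coords)
        ]
    return Structure(chains=chains)


class TestContacts:
    @pytest.mark.parametrize("distance,n_pairs", [(5.9, 1), (6.1, 0)])
    def test_cutoff_boundary(self, distance, n_pairs):
        st = single_atom_structure(
            {"A": [(0, 0, 0)], "B": [(distance, 0, 0)]}
        )
        pairs, _ = find_interface_residues(st, "A", "B", cutoff=6.0)
        assert len(pairs) == n_pairs

    def test_toy_dimer_recovers_configured_pairs(self, five_pair_dimer_params):
        st = generate_toy_dimer(five_pair_dimer_params)
        pairs, residues = find_interface_residues(st, "A", "B", cutoff=6.0)
        assert {(p.residue_a, p.residue_b) for p in pairs} == set(
            five_pair_dimer_params.contact_residue_pairs
        )
        assert all(p.distance == pytest.approx(5.5) for p in pairs)
        assert residues["A"] == sorted(
            a for a, _ in five_pair_dimer_params.contact_residue_pairs
        )

    def test_contact_symmetry(self, five_pair_dimer_params):
        st = generate_toy_dimer(five_pair_dimer_params)
        ab, _ = find_interface_residues(st, "A", "B", cutoff=6.0)
        ba, _ = find_interface_residues(st, "B", "A", cutoff=6.0)
        assert {(p.residue_a, p.residue_b) for p in ab} == {
            (p.residue_b, p.residue_a) for p in ba
        }

    def test_interface_grows_with_cutoff(self):
        st = generate_toy_dimer(
            DimerParams(contact_residue_pairs=((1, 1), (2, 2)), cutoff=6.0)
        )
        small = find_interface_residues(st, "A", "B", cutoff=3.0)[1]["A"]
        large = find_interface_residues(st, "A", "B", cutoff=6.0)[1]["A"]
        assert set(small) <= set(large)

    def test_missing_chain_rejected(self, five_pair_dimer_params):
        st = generate_toy_dimer(five_pair_dimer_params)
        with pytest.raises(KeyError):
            find_interface_residues(st, "A", "C")


class TestStretches:
    def domains(self):
        return {
            "A": {"NBD": (1, 20), "LRR": (21, 40)},
            "B": {"NBD": (1, 20), "LRR": (21, 40)},
        }

    @staticmethod
    def pairs(*items):
        from cladeface.interface import ContactPair

        return [ContactPair(a, b, 5.0) for a, b in items]

    def test_single_run_single_partner_domain(self):
        pairs = self.pairs((10, 30), (11, 31), (12, 30), (13, 32), (14, 33))
        stretches = derive_stretches(pairs, self.domains(), "A", "B")
        runs_a = stretches["A"]
        assert len(runs_a) == 1
        assert (runs_a[0].start, runs_a[0].end) == (10, 14)
        assert runs_a[0].own_domain == "NBD"
        assert runs_a[0].partner_domain == "LRR"

    def test_contiguous_residues_split_by_partner_domain(self):
        # residues 25-29 contact partner LRR, 30-33 contact partner NBD:
        # two stretches despite contiguity
        pairs = self.pairs(*[(r, 25) for r in range(25, 30)],
                           *[(r, 15) for r in range(30, 34)])
        stretches = derive_stretches(pairs, self.domains(), "A", "B")
        runs_a = stretches["A"]
        assert len(runs_a) == 2
        assert [(s.start, s.end, s.partner_domain) for s in runs_a] == [
            (25, 29, "LRR"),
            (30, 33, "NBD"),
        ]

    def test_residue_contacting_two_partner_domains_joins_both(self):
        pairs = self.pairs((10, 15), (10, 25))
        stretches = derive_stretches(pairs, self.domains(), "A", "B")
        classes = {(s.own_domain, s.partner_domain) for s in stretches["A"]}
        assert classes == {("NBD", "NBD"), ("NBD", "LRR")}

    def test_residue_outside_all_domains_rejected(self):
        pairs = self.pairs((50, 10))
        with pytest.raises(ValueError, match="outside all domains"):
            derive_stretches(pairs, self.domains(), "A", "B")


class TestSasa:
    def test_lone_sphere_matches_closed_form_within_one_percent(self):
        areas = sasa_atoms(np.array([[0.0, 0.0, 0.0]]), np.array([1.70]),
                           probe_radius=1.4, sphere_points=960)
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert areas[0] == pytest.approx(exact, rel=0.01)

    def test_distant_atoms_do_not_occlude(self):
        areas = sasa_atoms(
            np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]]),
            np.array([1.70, 1.70]),
        )
        exact = 4 * math.pi * (3.1) ** 2
        assert areas.sum() == pytest.approx(2 * exact, rel=0.01)

    def test_overlapping_spheres_match_spherical_cap_oracle(self):
        """Two equal spheres at centre distance d < 2R each lose a cap of
        height h = R - d/2; accessible area per sphere is 4*pi*R^2 minus
        the cap area 2*pi*R*h."""
        vdw, probe = 1.70, 1.4
        expanded = vdw + probe
        d = 2.5
        areas = sasa_atoms(
            np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
            np.array([vdw, vdw]),
            probe_radius=probe,
            sphere_points=4000,
        )
        h = expanded - d / 2
        exact_each = 4 * math.pi * expanded**2 - 2 * math.pi * expanded * h
        assert areas[0] == pytest.approx(exact_each, rel=0.01)
        assert areas[1] == pytest.approx(exact_each, rel=0.01)

    def test_convergence_under_point_doubling(self, five_pair_dimer_params):
        st = generate_toy_dimer(five_pair_dimer_params)
        total_1, _ = sasa(st, sphere_points=960)
        total_2, _ = sasa(st, sphere_points=1920)
        assert abs(total_2 - total_1) / total_2 < 0.005

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError):
            sasa_atoms(np.array([[0.0, 0.0, 0.0]]), np.array([0.0]))


class TestBsa:
    def test_non_touching_chains_have_zero_bsa(self):
        st = generate_toy_dimer(DimerParams(n_residues_per_chain=4))
        per_protomer, total = buried_surface_area(st, "A", "B")
        assert per_protomer == {"A": 0.0, "B": 0.0}
        assert total == 0.0

    def test_c2_symmetric_dimer_has_equal_protomer_bsa(self):
        # chain B is chain A rotated 180 degrees about z: exact C2 symmetry
        coords_a = [(0.0, 0.0, 0.0), (3.0, 0.5, 0.2), (5.0, 1.0, -0.3)]
        offset = 4.0
        coords_b = [(-x + offset, -y, z) for x, y, z in coords_a]
        st = single_atom_structure({"A": coords_a, "B": coords_b})
        per_protomer, total = buried_surface_area(
            st, "A", "B", InterfaceParams(sphere_points=4000)
        )
        assert per_protomer["A"] > 0
        assert per_protomer["A"] == pytest.approx(per_protomer["B"], rel=0.01)
        assert total == pytest.approx(sum(per_protomer.values()))

    def test_bsa_total_is_sum_of_protomers(self, five_pair_dimer_params):
        st = generate_toy_dimer(five_pair_dimer_params)
        per_protomer, total = buried_surface_area(st, "A", "B")
        assert total == pytest.approx(sum(per_protomer.values()))
        assert all(v >= 0 for v in per_protomer.values())
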