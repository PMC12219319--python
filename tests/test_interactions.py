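"""Hydrogen-bond detection, center-of-mass distances, and distance profiles
against brute-force oracles on constructed fixtures."""

import numpy as np
import pytest

from nqeliq.constants import COULOMB
from nqeliq.forcefield import waldman_hagler_mix
from nqeliq.interactions import (
    DistanceProfile,
    Frame,
    HBondCriteria,
    SelectionError,
    com_distance,
    default_edges,
    find_hbonds,
    hbond_density_profile,
    interaction_energy_profile,
    molecule_com,
    orientation_profile,
)
from nqeliq.synthetic_data import DimerSpec, make_hbond_fixture
from nqeliq.topology import AtomSpec, BondTerm, MolecularTopology, replicate


@pytest.fixture()
def dimer():
    top, pos, box = make_hbond_fixture([DimerSpec(d_da=2.8, angle_deg=170.0)])
    return top, Frame(pos, box)


class TestFindHBonds:
    def test_compliant_dimer_detected(self, dimer):
        top, frame = dimer
        bonds = find_hbonds(frame, top)
        assert len(bonds) == 1
        d, h, a = bonds[0]
        assert top.elements[h] == "H"
        assert top.elements[d] == top.elements[a] == "O"

    @pytest.mark.parametrize(
        "spec, expected",
        [
            (DimerSpec(d_da=2.8, angle_deg=170.0), 1),
            (DimerSpec(d_da=2.8, angle_deg=120.0), 0),   # angle criterion
            (DimerSpec(d_da=3.7, angle_deg=170.0), 0),   # distance criterion
            (DimerSpec(d_da=3.6, angle_deg=170.0), 1),   # closed boundary
            (DimerSpec(d_da=2.8, angle_deg=150.0), 1),   # closed boundary
        ],
    )
    def test_geometric_criteria(self, spec, expected):
        top, pos, box = make_hbond_fixture([spec])
        assert len(find_hbonds(Frame(pos, box), top)) == expected

    def test_grid_of_ten_compliant_dimers(self):
        top, pos, box = make_hbond_fixture([DimerSpec()] * 10)
        assert len(find_hbonds(Frame(pos, box), top)) == 10

    def test_no_donors_warns_and_returns_empty(self):
        mol = MolecularTopology(
            atoms=[AtomSpec("C", 12.0, 0.0, 3.0, 0.1)] * 2,
            bonds=[BondTerm(0, 1, k=1000.0, r0=1.5)],
        )
        with pytest.warns(UserWarning):
            assert find_hbonds(Frame(np.zeros((2, 3)) + [[0, 0, 0], [1.5, 0, 0]], 50.0),
                               mol) == []

    def test_intramolecular_pairs_excluded(self):
        # one bent molecule with O-H and another O: same molecule → no bond
        top = MolecularTopology(
            atoms=[AtomSpec("O", 16.0, -0.4, 3.0, 0.5),
                   AtomSpec("H", 1.008, 0.4, 2.0, 0.1),
                   AtomSpec("O", 16.0, -0.4, 3.0, 0.5)],
            bonds=[BondTerm(0, 1, k=3000.0, r0=0.97),
                   BondTerm(1, 2, k=3000.0, r0=1.8)],
        )
        pos = np.array([[0.0, 0, 0], [0.97, 0, 0], [2.77, 0, 0]])
        assert find_hbonds(Frame(pos, 50.0), top) == []

    def test_agrees_with_brute_force_double_loop(self, rng):
        """Randomly perturbed grid of dimers vs an index-by-index oracle."""
        top, pos, box = make_hbond_fixture([DimerSpec()] * 6, box=40.0, spacing=10.0)
        pos = pos + 0.4 * rng.standard_normal(pos.shape)
        frame = Frame(pos, box)
        crit = HBondCriteria()
        got = set(find_hbonds(frame, top, crit))

        def mic(v):
            return v - box * np.round(v / box)

        mol = top.molecule_index()
        elems = top.elements
        expected = set()
        donors = [(b.i, b.j) if elems[b.j] == "H" else (b.j, b.i) for b in top.bonds]
        for d, h in donors:
            for a in range(top.n_atoms):
                if elems[a] not in crit.acceptor_elements or mol[a] == mol[d]:
                    continue
                if np.linalg.norm(mic(pos[a] - pos[d])) > crit.distance_cutoff:
                    continue
                v1, v2 = mic(pos[d] - pos[h]), mic(pos[a] - pos[h])
                ang = np.degrees(np.arccos(
                    v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)
                ))
                if ang >= crit.angle_cutoff - 1e-9:
                    expected.add((d, h, a))
        assert got == expected


class TestComDistance:
    def two_point_masses(self, box=100.0):
        top = MolecularTopology(atoms=[AtomSpec("X", 10.0, 0.0, 1.0, 0.0)] * 2)
        return top

    def test_superposed_and_simple_distance(self):
        top = self.two_point_masses()
        f = Frame(np.array([[1.0, 1, 1], [1.0, 1, 1]]), 100.0)
        assert com_distance([0], [1], f, top) == 0.0
        f2 = Frame(np.array([[0.0, 0, 0], [5.0, 0, 0]]), 100.0)
        assert com_distance([0], [1], f2, top) == pytest.approx(5.0)

    def test_image_wrapped_pair_vs_27_image_enumeration(self, rng):
        box = 10.0
        top = self.two_point_masses()
        for _ in range(20):
            pos = rng.uniform(0, box, (2, 3))
            f = Frame(pos, box)
            got = com_distance([0], [1], f, top)
            shifts = np.array([
                [i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            ]) * box
            brute = np.min(np.linalg.norm(pos[0] - (pos[1] + shifts), axis=1))
            assert got == pytest.approx(brute, rel=1e-12)

    def test_molecule_com_handles_split_molecule(self):
        # molecule straddling the boundary: COM must not sit mid-box
        masses = np.array([1.0, 1.0])
        pos = np.array([[0.2, 0, 0], [9.8, 0, 0]])
        com = molecule_com(pos, masses, 10.0)
        assert com[0] == pytest.approx(0.0, abs=1e-9)


class TestHBondDensityProfile:
    def test_zero_bond_system_gives_all_zero(self):
        top, pos, box = make_hbond_fixture([DimerSpec(angle_deg=100.0)])
        prof = hbond_density_profile([[Frame(pos, box)]], top)
        assert np.all(prof.values == 0.0)

    def test_single_dimer_mass_in_correct_bin(self):
        # d_da = 3.5 Å puts the pair's r_CM inside the [3.3, 9] Å window
        top, pos, box = make_hbond_fixture([DimerSpec(d_da=3.5, angle_deg=178.0)])
        frame = Frame(pos, box)
        mols = top.molecules()
        r_cm = com_distance(mols[0], mols[1], frame, top)
        prof = hbond_density_profile([[frame]], top)
        edges = default_edges()
        b = np.searchsorted(edges, r_cm, side="right") - 1
        expected = np.zeros(50)
        expected[b] = 1.0 / box**3
        np.testing.assert_allclose(prof.values, expected)

    def test_profile_sum_times_volume_counts_in_range_bonds(self):
        top, pos, box = make_hbond_fixture(
            [DimerSpec(d_da=3.5)] * 5, box=40.0, spacing=10.0
        )
        prof = hbond_density_profile([[Frame(pos, box)]], top)
        assert prof.values.sum() * box**3 == pytest.approx(5.0)

    def test_pairs_outside_window_are_dropped(self):
        # compliant bond but r_CM < 3.3 Å: detected, yet outside the profile
        top, pos, box = make_hbond_fixture([DimerSpec(d_da=2.8)])
        assert len(find_hbonds(Frame(pos, box), top)) == 1
        prof = hbond_density_profile([[Frame(pos, box)]], top)
        assert prof.values.sum() == 0.0

    def test_replica_scatter_gives_sems(self):
        top, pos, box = make_hbond_fixture([DimerSpec()])
        top2, pos2, _ = make_hbond_fixture([DimerSpec(d_da=3.0)])
        prof = hbond_density_profile([[Frame(pos, box)], [Frame(pos2, box)]], top)
        assert (prof.sems >= 0).all()

    def test_empty_frames_rejected(self, dimer):
        top, _ = dimer
        with pytest.raises(ValueError):
            hbond_density_profile([[]], top)


class TestInteractionEnergyProfile:
    def lj_pair_system(self, r, sigma=3.0, eps=1.2):
        mol = MolecularTopology(atoms=[AtomSpec("X", 10.0, 0.0, sigma, eps)])
        top = replicate(mol, 2)
        pos = np.array([[10.0, 10, 10], [10.0 + r, 10, 10]])
        return top, Frame(pos, 50.0)

    def test_contact_minimum_energy_in_bin(self):
        sigma, eps = 3.5, 1.2
        r = 2 ** (1 / 6) * sigma
        top, frame = self.lj_pair_system(r, sigma, eps)
        prof = interaction_energy_profile([[frame]], top)
        b = np.searchsorted(default_edges(), r, side="right") - 1
        assert prof.values[b] == pytest.approx(-eps, rel=1e-9)
        assert np.isnan(np.delete(prof.values, b)).all()

    def test_beyond_cutoff_pairs_contribute_zero(self):
        top, frame = self.lj_pair_system(8.0)
        prof = interaction_energy_profile([[frame]], top, cutoff=6.0)
        b = np.searchsorted(default_edges(), 8.0, side="right") - 1
        assert prof.values[b] == 0.0

    def test_doubling_charges_quadruples_coulomb_part(self):
        def system(q):
            mol = MolecularTopology(atoms=[AtomSpec("X", 10.0, q, 3.0, 0.0)])
            top = replicate(mol, 2)
            # neutralize LJ: epsilon 0, pure Coulomb
            pos = np.array([[10.0, 10, 10], [14.5, 10, 10]])
            return top, Frame(pos, 50.0)

        t1, f1 = system(0.2)
        t2, f2 = system(0.4)
        p1 = interaction_energy_profile([[f1]], t1)
        p2 = interaction_energy_profile([[f2]], t2)
        b = np.searchsorted(default_edges(), 4.5, side="right") - 1
        assert p2.values[b] == pytest.approx(4 * p1.values[b], rel=1e-12)
        assert p1.values[b] == pytest.approx(COULOMB * 0.04 / 4.5, rel=1e-12)

    def test_matches_hand_evaluated_mixed_pair(self):
        a = AtomSpec("X", 10.0, 0.0, 3.0, 1.0)
        b = AtomSpec("Y", 10.0, 0.0, 2.0, 0.5)
        mol_a = MolecularTopology(atoms=[a])
        mol_b = MolecularTopology(atoms=[b])
        top = MolecularTopology(atoms=[a, b])
        r = 4.0
        frame = Frame(np.array([[10.0, 10, 10], [14.0, 10, 10]]), 50.0)
        p = waldman_hagler_mix(a, b)
        s6 = (p.sigma_ij / r) ** 6
        expected = 4 * p.epsilon_ij * (s6**2 - s6)
        prof = interaction_energy_profile([[frame]], top)
        bin_ = np.searchsorted(default_edges(), r, side="right") - 1
        assert prof.values[bin_] == pytest.approx(expected, rel=1e-12)


class TestOrientationProfile:
    def chain_system(self, angle_deg, r_cm=5.0):
        mol = MolecularTopology(
            atoms=[AtomSpec("C", 12.0, 0.0, 3.0, 0.1), AtomSpec("O", 16.0, 0.0, 3.0, 0.1)],
            bonds=[BondTerm(0, 1, k=1000.0, r0=1.4)],
        )
        top = replicate(mol, 2)
        th = np.deg2rad(angle_deg)
        pos = np.array([
            [10.0, 10, 10], [11.4, 10, 10],
            [10.0, 10 + r_cm, 10],
            [10.0 + 1.4 * np.cos(th), 10 + r_cm + 1.4 * np.sin(th), 10],
        ])
        return top, Frame(pos, 60.0)

    @pytest.mark.parametrize("angle,expected", [(0.0, 1.0), (180.0, -1.0), (90.0, 0.0)])
    def test_known_relative_orientations(self, angle, expected):
        top, frame = self.chain_system(angle)
        prof = orientation_profile([[frame]], top, ("C", "O"))
        vals = prof.values[~np.isnan(prof.values)]
        assert len(vals) == 1
        assert vals[0] == pytest.approx(expected, abs=1e-9)

    def test_isotropic_orientations_average_to_zero(self, rng):
        mol = MolecularTopology(
            atoms=[AtomSpec("C", 12.0, 0.0, 3.0, 0.1), AtomSpec("O", 16.0, 0.0, 3.0, 0.1)],
            bonds=[BondTerm(0, 1, k=1000.0, r0=1.4)],
        )
        n = 40
        top = replicate(mol, n)
        frames = []
        for _ in range(30):
            pos = []
            for i in range(n):
                c = rng.uniform(10, 50, 3)
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                pos.extend([c, c + 1.4 * u])
            frames.append(Frame(np.array(pos), 60.0))
        prof = orientation_profile([frames], top, ("C", "O"), edges=np.array([0.0, 60.0]))
        n_pairs = 30 * n * (n - 1) / 2
        sem = 1.0 / np.sqrt(3 * n_pairs)  # Var(cosθ)=1/3 for isotropic pairs
        assert abs(prof.values[0]) < 3 * sem

    def test_ambiguous_selector_rejected(self, dimer):
        top, frame = dimer
        with pytest.raises(SelectionError):
            orientation_profile([[frame]], top, ("C", "O"))


class TestFrameInvariances:
    def test_profiles_invariant_under_global_translation_and_rotation(self):
        top, pos, box = make_hbond_fixture([DimerSpec()] * 3, box=200.0, spacing=15.0)
        frame = Frame(pos + 1.0, box)
        # rotation about the fixture centroid keeps everything in the box
        th = 0.3
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        center = pos.mean(axis=0)
        rot = Frame((pos - center) @ R.T + center + 40.0, box)
        p1 = hbond_density_profile([[frame]], top)
        p2 = hbond_density_profile([[rot]], top)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-12)
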