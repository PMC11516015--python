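"""Gradient modification algebra and scan termination behaviour."""

import numpy as np
import pytest

from rxnet import (
    MorseCalculator,
    NTSettings,
    PairPotentialParams,
    Structure,
    TrialCoordinate,
    ValidationError,
    nt1_modified_gradient,
    nt2_modified_gradient,
    run_nt_scan,
)
from rxnet.calculator import PairParams
from rxnet.elements import CovalentRadiiTable
from rxnet.fixtures_io import make_fixture


@pytest.fixture()
def settings():
    return NTSettings()


@pytest.fixture(scope="module")
def inert_pair():
    """A non-interacting pair of point-like pseudo-atoms on a flat surface."""
    table = CovalentRadiiTable()
    table.register("Q", covalent_radius=0.05)
    params = PairPotentialParams(radii=table)
    params.set_pair(
        "Q", "Q",
        PairParams(well_depth=0.0, equilibrium=0.1, morse_width=1.9, bo_decay=0.25),
    )
    return MorseCalculator(params), table


class TestNT1Gradient:
    def test_single_atom_pair_hand_arithmetic(self):
        """Two atoms on the x axis, attraction with unit force scale:
        the left atom's effective force is +x, the right atom's -x, and the
        x components of their natural gradients are discarded."""
        positions = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        natural = np.array([[0.7, 1.0, 0.0], [-0.3, 0.0, 2.0]])
        settings = NTSettings(alpha_nt1=1.0)
        modified = nt1_modified_gradient(positions, natural, (0,), (1,), settings)
        # gradient -0.5·x̂ ⇒ step -α_SD·g moves the left atom toward +x
        assert np.allclose(modified[0], [-0.5, 1.0, 0.0])
        assert np.allclose(modified[1], [+0.5, 0.0, 2.0])

    def test_multi_atom_site_shares_one_force(self):
        """A two-atom left site at (0, ±1, 0) has its centre at the origin;
        both atoms receive the identical artificial force."""
        positions = np.array(
            [[0.0, 1.0, 0.0], [0.0, -1.0, 0.0], [3.0, 0.0, 0.0]]
        )
        natural = np.zeros((3, 3))
        settings = NTSettings(alpha_nt1=1.0)
        modified = nt1_modified_gradient(positions, natural, (0, 1), (2,), settings)
        assert np.allclose(modified[0], modified[1])
        assert np.allclose(modified[0], [-0.5, 0.0, 0.0])

    def test_orthogonalization_keeps_perpendicular_component(self):
        """Natural gradient (1, 1, 0) against a reactive coordinate along x
        keeps its (0, 1, 0) part plus the applied force along x."""
        positions = np.array(
            [[0.0, 0.5, 0.0], [0.0, -0.5, 0.0], [2.0, 0.0, 0.0]]
        )
        natural = np.zeros((3, 3))
        natural[0] = [1.0, 1.0, 0.0]
        settings = NTSettings(alpha_nt1=1.0)
        modified = nt1_modified_gradient(positions, natural, (0, 1), (2,), settings)
        assert np.allclose(modified[0], [-0.5, 1.0, 0.0])

    def test_unconstrained_atoms_untouched(self, settings):
        rng = np.random.default_rng(1)
        positions = rng.uniform(-2, 2, (5, 3))
        natural = rng.normal(size=(5, 3))
        modified = nt1_modified_gradient(positions, natural, (0,), (4,), settings)
        assert np.array_equal(modified[1:4], natural[1:4])

    def test_overlapping_sites_rejected(self, settings):
        with pytest.raises(ValidationError):
            nt1_modified_gradient(
                np.zeros((3, 3)), np.zeros((3, 3)), (0, 1), (1, 2), settings
            )


class TestNT2Gradient:
    def test_formation_distance_weighting(self, radii, settings):
        """A formation pair at twice the radii sum gets force α_NT2/2 on
        each atom, opposite signs, along the pair axis."""
        r0 = radii.radii_sum("H", "H")
        positions = np.array([[0.0, 0.0, 0.0], [2 * r0, 0.0, 0.0]])
        natural = np.zeros((2, 3))
        settings = NTSettings(alpha_nt2=1.0)
        modified = nt2_modified_gradient(
            positions, natural, [(0, 1)], [], radii, ["H", "H"], settings
        )
        assert np.allclose(modified[0], [-0.5, 0.0, 0.0])
        assert np.allclose(modified[1], [+0.5, 0.0, 0.0])

    def test_cleavage_unit_direction_at_any_distance(self, radii):
        settings = NTSettings(alpha_nt2=1.0)
        for distance in (0.4, 1.0, 3.7):
            positions = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
            modified = nt2_modified_gradient(
                positions, np.zeros((2, 3)), [], [(0, 1)], radii, ["H", "H"], settings
            )
            assert np.allclose(modified[0], [+1.0, 0.0, 0.0])
            assert np.allclose(modified[1], [-1.0, 0.0, 0.0])

    def test_three_independent_constraints_null_the_gradient(self, radii, settings):
        """An atom held by three linearly independent pair vectors keeps no
        natural-gradient component at all."""
        positions = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.3, 1.1, 0.0], [0.2, -0.4, 0.9]]
        )
        natural = np.zeros((4, 3))
        natural[0] = [0.8, -1.3, 0.5]
        modified = nt2_modified_gradient(
            positions,
            natural,
            [(0, 1), (0, 2), (0, 3)],
            [],
            radii,
            ["H", "H", "H", "H"],
            settings,
        )
        # remove the applied forces to isolate the surviving natural part
        bare = nt2_modified_gradient(
            positions,
            np.zeros((4, 3)),
            [(0, 1), (0, 2), (0, 3)],
            [],
            radii,
            ["H", "H", "H", "H"],
            settings,
        )
        assert np.linalg.norm(modified[0] - bare[0]) < 1e-10

    def test_orthogonality_to_every_pair_vector(self, radii, settings):
        rng = np.random.default_rng(9)
        positions = rng.uniform(-2, 2, (6, 3))
        natural = rng.normal(size=(6, 3))
        form = [(0, 1), (1, 2)]
        broken = [(3, 4)]
        elements = ["H", "O", "C", "H", "N", "H"]
        modified = nt2_modified_gradient(
            positions, natural, form, broken, radii, elements, settings
        )
        bare = nt2_modified_gradient(
            positions, np.zeros((6, 3)), form, broken, radii, elements, settings
        )
        surviving = modified - bare
        for a, b in form + broken:
            unit = positions[b] - positions[a]
            unit /= np.linalg.norm(unit)
            assert abs(np.dot(surviving[a], unit)) < 1e-10
            assert abs(np.dot(surviving[b], unit)) < 1e-10
        assert np.array_equal(modified[5], natural[5])  # unconstrained

    def test_zero_length_pair_rejected(self, radii, settings):
        with pytest.raises(ValidationError):
            nt2_modified_gradient(
                np.zeros((2, 3)), np.zeros((2, 3)), [(0, 1)], [], radii, ["H", "H"], settings
            )


class TestScanDriver:
    def test_nt1_collision_kinematics(self, inert_pair):
        """On a non-interacting pair the macro-step count to collision
        matches |R_C|/(α_SD·α_NT1) within ±2 steps, and the pair distance
        decreases strictly monotonically."""
        calc, table = inert_pair
        start = Structure(["Q", "Q"], [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        coord = TrialCoordinate(sites_lhs=(0,), sites_rhs=(1,), mode="NT1")
        settings = NTSettings(alpha_nt1=0.1, max_gradient_calls=500)
        trajectory = run_nt_scan(start, coord, calc, settings, table)
        assert trajectory.stop_reason == "collision_or_converted"
        distances = [
            np.linalg.norm(f.positions[1] - f.positions[0]) for f in trajectory.frames
        ]
        assert all(d1 > d2 for d1, d2 in zip(distances, distances[1:]))
        assert distances[-1] <= 0.9 * table.radii_sum("Q", "Q") + 1e-12
        predicted = 3.0 / (settings.alpha_sd * settings.alpha_nt1)
        assert abs((trajectory.n_frames - 1) - predicted) <= 2

    def test_nt2_break_stops_at_closed_form_distance(self, morse_calculator, radii):
        """Cleaving H2 stops once BO ≤ 0.15, i.e. past r0 + b·ln(1/0.15)."""
        h2 = make_fixture("h2")
        coord = TrialCoordinate(break_pairs=frozenset({(0, 1)}), mode="NT2")
        settings = NTSettings(max_gradient_calls=300)
        trajectory = run_nt_scan(h2, coord, morse_calculator, settings, radii)
        assert trajectory.stop_reason == "collision_or_converted"
        final = np.linalg.norm(
            trajectory.frames[-1].positions[1] - trajectory.frames[-1].positions[0]
        )
        threshold = 0.62 + 0.25 * np.log(1.0 / 0.15)
        assert final >= threshold
        # one macro step earlier the bond was not yet broken
        previous = np.linalg.norm(
            trajectory.frames[-2].positions[1] - trajectory.frames[-2].positions[0]
        )
        assert previous < threshold

    def test_budget_of_three_calls_gives_three_frames(self, morse_calculator, radii):
        h2 = make_fixture("h2")
        coord = TrialCoordinate(break_pairs=frozenset({(0, 1)}), mode="NT2")
        settings = NTSettings(max_gradient_calls=3)
        trajectory = run_nt_scan(h2, coord, morse_calculator, settings, radii)
        assert trajectory.stop_reason == "max_calls"
        assert trajectory.n_frames == 3

    def test_barrier_crossing_profile_is_uphill_then_downhill(
        self, barrier_calculator, radii
    ):
        """Dissociation over the toy barrier: single interior maximum."""
        h2 = make_fixture("h2")
        coord = TrialCoordinate(break_pairs=frozenset({(0, 1)}), mode="NT2")
        trajectory = run_nt_scan(h2, coord, barrier_calculator, NTSettings(), radii)
        energies = trajectory.energies
        peak = int(np.argmax(energies))
        assert 0 < peak < energies.size - 1
        assert all(np.diff(energies[: peak + 1]) > 0)
        # downhill immediately after the crest (the tail may climb again
        # once the scan walks out of the shallow product-complex well)
        assert energies[peak + 1] < energies[peak]
        assert energies[peak:].min() < energies[peak] - 1e-3

    def test_nt1_attraction_on_plain_morse_h_atoms(self, morse_calculator, radii):
        """Two free H atoms pulled together collide near 0.9·r0."""
        atoms = make_fixture("two_h_atoms")
        coord = TrialCoordinate(sites_lhs=(0,), sites_rhs=(1,), mode="NT1")
        settings = NTSettings(max_gradient_calls=500)
        trajectory = run_nt_scan(atoms, coord, morse_calculator, settings, radii)
        assert trajectory.stop_reason == "collision_or_converted"
        final = np.linalg.norm(
            trajectory.frames[-1].positions[1] - trajectory.frames[-1].positions[0]
        )
        assert final < 0.9 * 0.62
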