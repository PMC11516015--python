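"""Savitzky–Golay filtering, saddle refinement, IRC validation, bookkeeping."""

import numpy as np
import pytest
from scipy.optimize import brentq

from rxnet import (
    MorseCalculator,
    NoTransitionStateGuess,
    Structure,
    TSOptimizationError,
    ValidationError,
    barrier_params,
    compute_energy_profile,
    extract_ts_guess,
    irc,
    optimize_minimum,
    optimize_ts,
    savitzky_golay_smooth,
    spline_path,
    validate_step,
)
from rxnet.calculator import CalcResult, Calculator
from rxnet.fixtures_io import make_fixture
from rxnet.nt_scan import Frame, Trajectory
from rxnet.step_refinement import IRCSettings, endpoint_structure


def _sg_oracle(values: np.ndarray) -> np.ndarray:
    """Least-squares oracle: fit a quadratic through each 5-point window of
    the reflect-padded series and evaluate it at the window centre."""
    padded = np.pad(values, 2, mode="reflect")
    out = np.empty_like(values, dtype=float)
    x = np.arange(-2.0, 3.0)
    design = np.vstack([np.ones(5), x, x * x]).T
    for i in range(values.size):
        window = padded[i : i + 5]
        coeffs, *_ = np.linalg.lstsq(design, window, rcond=None)
        out[i] = coeffs[0]
    return out


class TestSavitzkyGolay:
    def test_constants_invariant(self):
        values = np.full(9, 3.25)
        assert np.allclose(savitzky_golay_smooth(values, passes=4), values, atol=1e-12)

    def test_quadratics_invariant(self):
        x = np.arange(12.0)
        values = 0.3 * x * x - 1.7 * x + 0.4
        smoothed = savitzky_golay_smooth(values, passes=1)
        interior = slice(2, -2)  # reflection padding breaks the polynomial at edges
        assert np.allclose(smoothed[interior], values[interior], atol=1e-10)

    def test_impulse_response_equals_least_squares_kernel(self):
        impulse = np.zeros(11)
        impulse[5] = 1.0
        smoothed = savitzky_golay_smooth(impulse, passes=1)
        oracle = _sg_oracle(impulse)
        assert np.allclose(smoothed, oracle, atol=1e-12)
        assert np.allclose(
            smoothed[3:8], np.array([-3.0, 12.0, 17.0, 12.0, -3.0]) / 35.0
        )

    def test_matches_oracle_on_noisy_series(self):
        rng = np.random.default_rng(17)
        values = np.sin(np.linspace(0, 3, 25)) + 0.1 * rng.normal(size=25)
        assert np.allclose(
            savitzky_golay_smooth(values, passes=1), _sg_oracle(values), atol=1e-12
        )

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            savitzky_golay_smooth([1.0, 2.0, 3.0, 4.0])


def _trajectory(energies, template=None):
    frames = [
        Frame(np.array([[float(i), 0.0, 0.0], [0.0, 0.0, 0.0]]), e, i + 1)
        for i, e in enumerate(energies)
    ]
    return Trajectory(
        frames=frames,
        stop_reason="collision_or_converted",
        structure_template=template or make_fixture("h2"),
    )


class TestGuessExtraction:
    def test_symmetric_peak_yields_central_frame(self):
        _, index = extract_ts_guess(_trajectory([0, 1, 2, 3, 2, 1, 0]), passes=0)
        assert index == 3

    def test_higher_second_peak_wins_after_smoothing(self):
        energies = [0.0, 2.0, 0.5, 0.4, 3.0, 4.0, 3.2, 0.2, 0.0]
        smoothed = savitzky_golay_smooth(np.array(energies), passes=3)
        oracle_peak = max(
            (i for i in range(1, len(energies) - 1)
             if smoothed[i] > smoothed[i - 1] and smoothed[i] >= smoothed[i + 1]),
            key=lambda i: smoothed[i],
        )
        _, index = extract_ts_guess(_trajectory(energies), passes=3)
        assert index == oracle_peak

    def test_five_frame_trajectory_gives_no_guess(self):
        with pytest.raises(NoTransitionStateGuess):
            extract_ts_guess(_trajectory([0, 1, 2, 1, 0]))

    def test_monotone_profile_gives_no_guess(self):
        with pytest.raises(NoTransitionStateGuess):
            extract_ts_guess(_trajectory([0, 1, 2, 3, 4, 5, 6]), passes=0)


class TestTSOptimization:
    @pytest.mark.parametrize("method", ["bofill", "ev_following"])
    def test_converges_to_oracle_saddle_on_analytic_surface(
        self, mb_calculator, mb_saddles, method
    ):
        saddle = min(mb_saddles)  # the (-0.822, 0.624) saddle
        guess = Structure(["X"], [[saddle[0] + 0.05, saddle[1] - 0.06, 0.0]])
        result = optimize_ts(guess, mb_calculator, method=method, trust_radius=0.05)
        assert np.max(np.abs(result.structure.positions[0, :2] - saddle)) < 1e-4
        assert int(np.sum(result.eigenvalues < -1e-6)) == 1

    def test_guess_at_minimum_is_rejected(self, mb_calculator, mb_minima):
        x, y = mb_minima[0]
        exact = optimize_minimum(Structure(["X"], [[x, y, 0.0]]), mb_calculator)
        with pytest.raises(TSOptimizationError, match="minimum"):
            optimize_ts(exact, mb_calculator)

    def test_idempotent_on_converged_saddle(self, mb_calculator, mb_saddles):
        saddle = min(mb_saddles)
        guess = Structure(["X"], [[saddle[0] + 0.03, saddle[1] + 0.03, 0.0]])
        first = optimize_ts(guess, mb_calculator, trust_radius=0.05)
        second = optimize_ts(first.structure, mb_calculator, trust_radius=0.05)
        moved = np.max(np.abs(second.structure.positions - first.structure.positions))
        assert moved < 1e-6

    def test_toy_exchange_saddle_has_one_negative_mode(self):
        """Atom transfer between two non-interacting partners: the crest of
        the donor-side pair potential, located by a 1D root-finding oracle,
        is a first-order saddle of the full 3D system."""
        params = barrier_params()
        params.set_pair(
            "He",
            "Ne",
            # the spectator pair does not interact
            type(params.pair("H", "H"))(
                well_depth=1e-12, equilibrium=1.0, morse_width=1.9, bo_decay=0.25
            ),
        )
        calc = MorseCalculator(params)

        def radial_derivative(pair, r, eps=1e-6):
            def energy(d):
                s = Structure(list(pair), [[0, 0, 0], [d, 0, 0]], multiplicity=2)
                return calc.energy(s)

            return (energy(r + eps) - energy(r - eps)) / (2 * eps)

        # He-H: well at ~0.59 Å, barrier crest near 0.92 Å, outer complex
        # minimum near 1.03 Å — bracket the crest only
        r_crest = brentq(lambda r: radial_derivative(("He", "H"), r), 0.65, 0.98)
        r_min = brentq(lambda r: radial_derivative(("Ne", "H"), r), 0.7, 1.0)
        guess = Structure(
            ["He", "H", "Ne"],
            [[-r_crest - 0.01, 0.0, 0.0], [0.0, 0.0, 0.0], [r_min + 0.01, 0.0, 0.0]],
            multiplicity=2,
        )
        result = optimize_ts(guess, calc, method="ev_following", trust_radius=0.05)
        assert int(np.sum(result.eigenvalues < -1e-6)) == 1
        d_left = np.linalg.norm(
            result.structure.positions[1] - result.structure.positions[0]
        )
        d_right = np.linalg.norm(
            result.structure.positions[2] - result.structure.positions[1]
        )
        assert d_left == pytest.approx(r_crest, abs=1e-5)
        assert d_right == pytest.approx(r_min, abs=1e-5)


class TestIRC:
    def test_endpoints_reach_oracle_minima(self, mb_calculator, mb_saddles, mb_minima):
        saddle = min(mb_saddles)
        guess = Structure(["X"], [[saddle[0] + 0.02, saddle[1] - 0.02, 0.0]])
        ts = optimize_ts(guess, mb_calculator, trust_radius=0.05)
        forward, backward = irc(
            ts.structure,
            mb_calculator,
            IRCSettings(displacement=0.01, trust_radius=0.02),
            imaginary_mode=ts.imaginary_mode,
        )
        ends = sorted(
            (
                tuple(endpoint_structure(t).positions[0, :2])
                for t in (forward, backward)
            )
        )
        expected = sorted(m for m in mb_minima if abs(m[0]) < 1.0 or m[0] < 0)
        matches = 0
        for end in ends:
            for minimum in mb_minima:
                if np.hypot(end[0] - minimum[0], end[1] - minimum[1]) < 1e-3:
                    matches += 1
        assert matches == 2

    def test_profiles_descend(self, mb_calculator, mb_saddles):
        saddle = min(mb_saddles)
        ts = optimize_ts(
            Structure(["X"], [[saddle[0] + 0.02, saddle[1] - 0.02, 0.0]]),
            mb_calculator,
            trust_radius=0.05,
        )
        forward, backward = irc(
            ts.structure,
            mb_calculator,
            IRCSettings(displacement=0.01, trust_radius=0.02),
            imaginary_mode=ts.imaginary_mode,
        )
        for branch in (forward, backward):
            assert branch.stop_reason == "converged"
            assert all(np.diff(branch.energies) <= 1e-12)

    def test_requires_first_order_saddle(self, mb_calculator, mb_minima):
        x, y = mb_minima[0]
        minimum = optimize_minimum(Structure(["X"], [[x, y, 0.0]]), mb_calculator)
        with pytest.raises(ValidationError):
            irc(minimum, mb_calculator)


class TestValidation:
    def test_dissociated_endpoint_makes_new_step(self, barrier_calculator):
        h2 = make_fixture("h2")
        apart = Structure(["H", "H"], [[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        verdict = validate_step(h2, (h2.copy(), apart), barrier_calculator)
        assert verdict.status == "new_step"
        assert verdict.matched_end == "forward"
        assert verdict.forward_key != verdict.backward_key

    def test_both_endpoints_equal_start_is_unchanged(self, barrier_calculator):
        h2 = make_fixture("h2")
        verdict = validate_step(h2, (h2.copy(), h2.copy()), barrier_calculator)
        assert verdict.status == "unchanged"

    def test_neither_endpoint_matching_fails(self, barrier_calculator):
        h2 = make_fixture("h2")
        apart = Structure(["H", "H"], [[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        verdict = validate_step(apart, (h2.copy(), h2.copy()), barrier_calculator)
        assert verdict.status == "failed"
        assert verdict.matched_end is None


class _FixedEnergies(Calculator):
    """Stub backend mapping (elements, label) to fixed energies."""

    has_rigid_modes = True

    def __init__(self, table):
        self.table = table

    def compute(self, structure, required):
        return CalcResult(energy=self.table[(tuple(structure.elements), structure.label)])


class TestEnergyProfile:
    def _setup(self, e_ab_complex=-1.6, e_ts=-1.2):
        a = Structure(["H"], [[0.0, 0.0, 0.0]], multiplicity=2, label="minimum")
        b = Structure(["O"], [[0.0, 0.0, 0.0]], multiplicity=3, label="minimum")
        cd = Structure(["O", "H"], [[0, 0, 0], [1.4, 0, 0]], multiplicity=2, label="minimum")
        ab = Structure(["H", "O"], [[0, 0, 0], [1, 0, 0]], multiplicity=2, label="complex")
        cd_complex = Structure(
            ["O", "H"], [[0, 0, 0], [1.2, 0, 0]], multiplicity=2, label="complex"
        )
        ts = Structure(
            ["H", "O"], [[0, 0, 0], [1.2, 0, 0]], multiplicity=2, label="transition_state"
        )
        calc = _FixedEnergies(
            {
                (("H",), "minimum"): -1.0,
                (("O",), "minimum"): -0.5,
                (("O", "H"), "minimum"): -1.4,
                (("H", "O"), "complex"): e_ab_complex,
                (("O", "H"), "complex"): -1.45,
                (("H", "O"), "transition_state"): e_ts,
            }
        )
        return ([a, b], [cd], (ab, cd_complex), ts, calc)

    def test_separated_barrier_arithmetic(self):
        reactants, products, complexes, ts, calc = self._setup()
        profile = compute_energy_profile(reactants, products, complexes, ts, calc)
        # E(A) = -1.0, E(B) = -0.5, E(T) = -1.2 ⇒ ΔE‡ = 0.3
        assert profile.barrier_separated == pytest.approx(0.3)
        assert profile.reaction_energy_separated == pytest.approx(0.1)

    def test_complexed_barrier_arithmetic(self):
        reactants, products, complexes, ts, calc = self._setup(e_ab_complex=-1.6)
        profile = compute_energy_profile(reactants, products, complexes, ts, calc)
        # E([AB]) = -1.6 ⇒ ΔE‡ = 0.4
        assert profile.barrier_complexed == pytest.approx(0.4)
        assert profile.reaction_energy_complexed == pytest.approx(-1.45 - (-1.6))

    def test_negative_complexed_barrier_is_stored_and_flagged(self):
        reactants, products, complexes, ts, calc = self._setup(e_ab_complex=-1.1)
        profile = compute_energy_profile(reactants, products, complexes, ts, calc)
        assert profile.barrier_complexed == pytest.approx(-0.1)
        assert profile.has_negative_barrier

    def test_reaction_energy_is_barrier_difference(self):
        """ΔE_rxn = forward barrier − reverse barrier, in both variants."""
        reactants, products, complexes, ts, calc = self._setup()
        profile = compute_energy_profile(reactants, products, complexes, ts, calc)
        reverse_separated = profile.ts_energy - (-1.4)
        assert profile.reaction_energy_separated == pytest.approx(
            profile.barrier_separated - reverse_separated
        )
        reverse_complexed = profile.ts_energy - (-1.45)
        assert profile.reaction_energy_complexed == pytest.approx(
            profile.barrier_complexed - reverse_complexed
        )


class TestPathSpline:
    def _trajectory(self):
        rng = np.random.default_rng(23)
        positions = np.cumsum(rng.uniform(0.1, 0.3, size=(6, 1, 1)), axis=0) * np.array(
            [[1.0, 0.0, 0.0]]
        )
        positions = np.concatenate([positions, np.zeros((6, 1, 3))], axis=1)
        energies = rng.normal(size=6)
        frames = [Frame(p, e, i + 1) for i, (p, e) in enumerate(zip(positions, energies))]
        return Trajectory(frames, "converged", make_fixture("h2"))

    def test_knots_reproduce_energies_and_endpoints(self):
        trajectory = self._trajectory()
        spline = spline_path(trajectory)
        for t, energy in zip(spline.knots, trajectory.energies):
            assert spline.energy(float(t)) == pytest.approx(energy, abs=1e-10)
        assert np.allclose(spline.positions(0.0), trajectory.frames[0].positions)
        assert np.allclose(spline.positions(1.0), trajectory.frames[-1].positions)

    def test_linear_energy_data_gives_linear_spline(self):
        positions = np.array([[[i * 0.5, 0.0, 0.0], [0.0, 0.0, 0.0]] for i in range(5)])
        energies = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        frames = [Frame(p, e, i + 1) for i, (p, e) in enumerate(zip(positions, energies))]
        spline = spline_path(Trajectory(frames, "converged", make_fixture("h2")))
        ts = np.linspace(0, 1, 33)
        values = np.array([spline.energy(float(t)) for t in ts])
        assert np.allclose(values, ts, atol=1e-10)  # E is linear in arc length

    def test_too_few_frames_rejected(self):
        frames = [
            Frame(np.array([[0.0, 0.0, 0.0], [i, 0, 0]]), 0.0, 1) for i in range(3)
        ]
        with pytest.raises(ValidationError):
            spline_path(Trajectory(frames, "converged", make_fixture("h2")))

    def test_round_trip_serialization(self):
        spline = spline_path(self._trajectory())
        from rxnet.step_refinement import PathSpline

        rebuilt = PathSpline.from_doc(spline.to_doc())
        assert rebuilt.energy(0.37) == pytest.approx(spline.energy(0.37), abs=1e-12)
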