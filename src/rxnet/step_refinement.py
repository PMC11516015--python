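"""From scan trajectory to validated elementary step.

Covers the tail of an elementary-step trial: Savitzky–Golay smoothing of
the scan energies and extraction of the transition-state guess, saddle
refinement (Bofill-updated quasi-Newton or explicit eigenvector following,
both with partitioned rational-function steps), IRC validation into both
adjacent valleys, molecular-graph comparison of the endpoints against the
start structure, energy bookkeeping for the separated and complexed barrier
definitions, and cubic-spline storage of the path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from .calculator import Calculator, finite_difference_hessian
from .data_model import Structure, ValidationError
from .molgraph import GraphKey, canonical_key, perceive_graph
from .nt_scan import Frame, Trajectory

#: 5-point quadratic/cubic Savitzky–Golay convolution weights
_SG_KERNEL = np.array([-3.0, 12.0, 17.0, 12.0, -3.0]) / 35.0


class NoTransitionStateGuess(RuntimeError):
    """The trajectory carries no extractable interior energy maximum."""


class TSOptimizationError(RuntimeError):
    """Saddle refinement failed (budget, or converged to the wrong index)."""


# ---------------------------------------------------------------------------
# smoothing and guess extraction


def savitzky_golay_smooth(values: Sequence[float], passes: int = 3) -> np.ndarray:
    """Repeated 5-point Savitzky–Golay smoothing with reflected edges.

    Exactly reproduces constants and polynomials up to the fit degree;
    length is preserved.  The default of three passes damps the small
    oscillations BFGS micro-cycles leave in a scan profile.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 5:
        raise ValidationError("need a 1D series of at least 5 values")
    out = values
    for _ in range(max(passes, 0)):
        padded = np.pad(out, 2, mode="reflect")
        out = np.convolve(padded, _SG_KERNEL[::-1], mode="valid")
    return out


def extract_ts_guess(
    trajectory: Trajectory, passes: int = 3
) -> tuple[Structure, int]:
    """Extract the frame of the highest interior maximum of the smoothed
    energy profile as the transition-state guess.

    Only trajectories with more than 5 frames are analyzed.  Ties go to the
    earliest frame.  Raises :class:`NoTransitionStateGuess` when the
    trajectory is too short or the smoothed profile is monotone.
    """
    if trajectory.n_frames <= 5:
        raise NoTransitionStateGuess(
            f"trajectory has {trajectory.n_frames} frames; need more than 5"
        )
    smoothed = savitzky_golay_smooth(trajectory.energies, passes)
    interior = [
        i
        for i in range(1, smoothed.size - 1)
        if smoothed[i] > smoothed[i - 1] and smoothed[i] >= smoothed[i + 1]
    ]
    if not interior:
        raise NoTransitionStateGuess("smoothed energy profile has no interior maximum")
    best = interior[int(np.argmax(smoothed[interior]))]
    return trajectory.frame_structure(best), best


# ---------------------------------------------------------------------------
# Hessian analysis


def _rigid_mode_basis(structure: Structure) -> np.ndarray:
    """Orthonormal basis of rigid translations and rotations (3N vectors)."""
    n = structure.n_atoms
    pos = structure.positions - structure.positions.mean(axis=0)
    modes = []
    for axis in range(3):
        vec = np.zeros((n, 3))
        vec[:, axis] = 1.0
        modes.append(vec.ravel())
    for axis in np.eye(3):
        vec = np.cross(pos, axis)
        if np.linalg.norm(vec) > 1e-8:
            modes.append(vec.ravel())
    basis = np.array(modes).T  # (3N, k)
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-8
    return q[:, keep]


def projected_hessian(
    structure: Structure, calculator: Calculator, hessian: Optional[np.ndarray] = None
) -> np.ndarray:
    """Hessian with rigid-body modes projected out (when the backend has them)."""
    if hessian is None:
        hessian = finite_difference_hessian(structure, calculator)
    if not calculator.has_rigid_modes:
        return hessian
    q = _rigid_mode_basis(structure)
    projector = np.eye(hessian.shape[0]) - q @ q.T
    return projector @ hessian @ projector


def count_negative_eigenvalues(
    eigenvalues: np.ndarray, threshold: float = 1e-6
) -> int:
    return int(np.sum(eigenvalues < -threshold))


# ---------------------------------------------------------------------------
# transition-state optimization


@dataclass
class TSResult:
    structure: Structure
    energy: float
    n_iterations: int
    eigenvalues: np.ndarray
    imaginary_mode: np.ndarray  # (N, 3) unit vector along the negative mode


def _prfo_step(
    eigenvalues: np.ndarray,
    eigenvectors: np.ndarray,
    gradient: np.ndarray,
    trust_radius: float,
    null_threshold: float = 1e-7,
) -> np.ndarray:
    """Partitioned rational-function step: maximize along the lowest mode,
    minimize along all others; near-null (rigid) modes carry no step."""
    live = np.where(np.abs(eigenvalues) > null_threshold)[0]
    if live.size == 0:
        return np.zeros_like(gradient)
    lam = eigenvalues[live]
    vecs = eigenvectors[:, live]
    g_modes = vecs.T @ gradient
    step = np.zeros_like(gradient)
    # uphill shift for the followed (lowest) mode
    lam1, g1 = lam[0], g_modes[0]
    shift_up = 0.5 * (lam1 + np.sqrt(lam1 * lam1 + 4.0 * g1 * g1))
    denom = lam1 - shift_up
    if abs(denom) < 1e-12:
        denom = -1e-12
    step += (-g1 / denom) * vecs[:, 0]
    if live.size > 1:
        lam_rest, g_rest = lam[1:], g_modes[1:]
        # downhill shift keeping all remaining denominators positive
        shift_down = 0.0
        if lam_rest[0] <= null_threshold:
            shift_down = lam_rest[0] - abs(g_rest[0]) - 1e-3
        denominators = lam_rest - shift_down
        step += vecs[:, 1:] @ (-g_rest / denominators)
    norm = np.linalg.norm(step)
    if norm > trust_radius:
        step *= trust_radius / norm
    return step


def optimize_ts(
    guess: Structure,
    calculator: Calculator,
    method: str = "bofill",
    gradient_threshold: float = 1e-6,
    max_iterations: int = 200,
    trust_radius: float = 0.1,
    hessian_refresh: int = 20,
) -> TSResult:
    """Refine a guess to a first-order saddle point.

    ``bofill``: quasi-Newton with an exact finite-difference Hessian at the
    start, mixed SR1/PSB (Bofill) updates along the way, and a periodic
    exact refresh; ``ev_following``: explicit eigenvector following with an
    exact finite-difference Hessian every iteration.  Convergence requires
    the gradient max-component below the threshold *and* exactly one
    negative eigenvalue of the (rigid-mode-projected) Hessian.
    """
    if method not in {"bofill", "ev_following"}:
        raise ValidationError(f"unknown TS optimizer: {method!r}")
    current = guess.copy(label="unoptimized")
    hessian = finite_difference_hessian(current, calculator)
    result = calculator.compute(current, {"energy", "gradient"})
    gradient = result.gradient.ravel()
    for iteration in range(1, max_iterations + 1):
        if np.max(np.abs(gradient)) < gradient_threshold:
            projected = projected_hessian(current, calculator)
            eigenvalues, eigenvectors = np.linalg.eigh(projected)
            negatives = count_negative_eigenvalues(eigenvalues)
            if negatives == 0:
                raise TSOptimizationError("converged to a minimum (0 negative modes)")
            if negatives > 1:
                raise TSOptimizationError(
                    f"converged to a higher-order saddle ({negatives} negative modes)"
                )
            mode = eigenvectors[:, int(np.argmin(eigenvalues))]
            return TSResult(
                structure=current.copy(label="transition_state"),
                energy=result.energy,
                n_iterations=iteration - 1,
                eigenvalues=eigenvalues,
                imaginary_mode=(mode / np.linalg.norm(mode)).reshape(-1, 3),
            )
        if method == "ev_following" or iteration % hessian_refresh == 0:
            hessian = finite_difference_hessian(current, calculator)
        work = projected_hessian(current, calculator, hessian)
        eigenvalues, eigenvectors = np.linalg.eigh(work)
        step = _prfo_step(eigenvalues, eigenvectors, gradient, trust_radius)
        current.positions = current.positions + step.reshape(-1, 3)
        new_result = calculator.compute(current, {"energy", "gradient"})
        new_gradient = new_result.gradient.ravel()
        if method == "bofill":
            hessian = _bofill_update(hessian, step, new_gradient - gradient)
        result, gradient = new_result, new_gradient
    raise TSOptimizationError(f"no convergence within {max_iterations} iterations")


def _bofill_update(
    hessian: np.ndarray, step: np.ndarray, delta_gradient: np.ndarray
) -> np.ndarray:
    """Bofill-mixed SR1/PSB Hessian update."""
    ss = float(step @ step)
    if ss < 1e-16:
        return hessian
    xi = delta_gradient - hessian @ step
    xx = float(xi @ xi)
    if xx < 1e-16:
        return hessian
    sx = float(step @ xi)
    phi = sx * sx / (ss * xx)
    psb = (
        (np.outer(xi, step) + np.outer(step, xi)) / ss
        - sx * np.outer(step, step) / (ss * ss)
    )
    update = (1.0 - phi) * psb
    if abs(sx) > 1e-12:
        update += phi * np.outer(xi, xi) / sx
    return hessian + update


# ---------------------------------------------------------------------------
# IRC


@dataclass
class IRCSettings:
    displacement: float = 0.05  # Å along the imaginary mode
    step_scale: float = 1e-3  # initial α for damped descent (Å²/energy)
    trust_radius: float = 0.05  # Å cap per descent step
    # steepest descent converges slowly in stiff, ill-conditioned valleys;
    # 1e-5 keeps endpoint positions accurate to ~1e-7 at toy curvatures
    gradient_threshold: float = 1e-5
    max_steps: int = 5000


def irc(
    ts: Structure,
    calculator: Calculator,
    settings: Optional[IRCSettings] = None,
    imaginary_mode: Optional[np.ndarray] = None,
) -> tuple[Trajectory, Trajectory]:
    """Damped steepest-descent relaxation from the saddle into both valleys.

    The saddle is displaced by ±δ along the imaginary-mode eigenvector and
    each branch relaxed downhill (step halving on energy increase, capped at
    the trust radius) to a local minimum.  Returns the forward and backward
    trajectories, each ending at its valley structure.
    """
    settings = settings or IRCSettings()
    if imaginary_mode is None:
        projected = projected_hessian(ts, calculator)
        eigenvalues, eigenvectors = np.linalg.eigh(projected)
        if count_negative_eigenvalues(eigenvalues) != 1:
            raise ValidationError(
                "IRC requires a first-order saddle (exactly one negative mode)"
            )
        imaginary_mode = eigenvectors[:, int(np.argmin(eigenvalues))].reshape(-1, 3)
    imaginary_mode = imaginary_mode / np.linalg.norm(imaginary_mode)
    branches = []
    for sign in (+1.0, -1.0):
        start = ts.copy(label="unoptimized")
        start.positions = start.positions + sign * settings.displacement * imaginary_mode
        branches.append(_damped_descent(start, calculator, settings))
    forward, backward = branches
    return forward, backward


def _damped_descent(
    structure: Structure, calculator: Calculator, settings: IRCSettings
) -> Trajectory:
    current = structure.copy()
    alpha = settings.step_scale
    frames: list[Frame] = []
    result = calculator.compute(current, {"energy", "gradient"})
    frames.append(Frame(current.positions.copy(), result.energy, 1))
    calls = 1
    stop_reason = "max_calls"
    for _ in range(settings.max_steps):
        if np.max(np.abs(result.gradient)) < settings.gradient_threshold:
            stop_reason = "converged"
            break
        step = -alpha * result.gradient
        norm = np.linalg.norm(step)
        if norm > settings.trust_radius:
            step *= settings.trust_radius / norm
        accepted = False
        for _ in range(30):
            trial = current.copy()
            trial.positions = current.positions + step
            trial_result = calculator.compute(trial, {"energy", "gradient"})
            if trial_result.energy <= result.energy + 1e-14:
                accepted = True
                break
            step *= 0.5
            alpha *= 0.5
        calls += 1
        if not accepted:
            stop_reason = "converged"  # cannot descend further: at a minimum
            break
        current, result = trial, trial_result
        frames.append(Frame(current.positions.copy(), result.energy, calls))
        alpha = min(alpha * 1.2, 1.0)
    return Trajectory(
        frames=frames, stop_reason=stop_reason, structure_template=structure.copy()
    )


def endpoint_structure(trajectory: Trajectory) -> Structure:
    """The last frame of a trajectory as a structure."""
    return trajectory.frame_structure(trajectory.n_frames - 1)


# ---------------------------------------------------------------------------
# validation


@dataclass
class StepValidationVerdict:
    status: str  # new_step | back_to_start? -> {new_step, unchanged, failed}
    forward_key: GraphKey
    backward_key: GraphKey
    matched_end: Optional[str]  # "forward" | "backward" | None


def structure_graph_key(
    structure: Structure, calculator: Calculator, threshold: float = 0.5
) -> GraphKey:
    result = calculator.compute(structure, {"energy", "bond_orders"})
    graph = perceive_graph(structure, result.bond_orders, threshold)
    return canonical_key(graph)


def validate_step(
    start_complex: Structure,
    irc_endpoints: tuple[Structure, Structure],
    calculator: Calculator,
    threshold: float = 0.5,
) -> StepValidationVerdict:
    """Compare the molecular graphs of both IRC endpoints with the start.

    One endpoint equal to the start and the other different → a new
    elementary step; both equal → the scan fell back (unchanged); neither
    equal → the saddle does not connect the intended reactants (failed).
    """
    start_key = structure_graph_key(start_complex, calculator, threshold)
    forward_key = structure_graph_key(irc_endpoints[0], calculator, threshold)
    backward_key = structure_graph_key(irc_endpoints[1], calculator, threshold)
    if forward_key == start_key and backward_key == start_key:
        status, matched = "unchanged", "forward"
    elif forward_key == start_key:
        status, matched = "new_step", "forward"
    elif backward_key == start_key:
        status, matched = "new_step", "backward"
    else:
        status, matched = "failed", None
    return StepValidationVerdict(
        status=status,
        forward_key=forward_key,
        backward_key=backward_key,
        matched_end=matched,
    )


# ---------------------------------------------------------------------------
# energy bookkeeping


@dataclass
class EnergyProfile:
    """Separated and complexed barrier/reaction-energy definitions.

    The separated variant sums independently optimized fragment energies on
    each side; the complexed variant uses the associated reactant/product
    complexes at the ends of the IRC.  Negative complexed barriers can occur
    (over-stabilized artificial association) and are stored and flagged,
    not discarded.
    """

    barrier_separated: float
    reaction_energy_separated: float
    barrier_complexed: float
    reaction_energy_complexed: float
    ts_energy: float

    @property
    def has_negative_barrier(self) -> bool:
        return self.barrier_separated < 0 or self.barrier_complexed < 0

    def to_doc(self) -> dict:
        return {
            "barrier_separated": self.barrier_separated,
            "reaction_energy_separated": self.reaction_energy_separated,
            "barrier_complexed": self.barrier_complexed,
            "reaction_energy_complexed": self.reaction_energy_complexed,
            "ts_energy": self.ts_energy,
            "negative_barrier": self.has_negative_barrier,
        }


def compute_energy_profile(
    reactant_minima: Sequence[Structure],
    product_minima: Sequence[Structure],
    complexes: tuple[Structure, Structure],
    ts: Structure,
    calculator: Calculator,
) -> EnergyProfile:
    """Energy bookkeeping for one elementary step.

    All energies must come from the same model — here, the same calculator.
    """
    if not reactant_minima or not product_minima:
        raise ValidationError("need at least one structure on each side")
    e_reactants = sum(calculator.energy(s) for s in reactant_minima)
    e_products = sum(calculator.energy(s) for s in product_minima)
    e_reactant_complex = calculator.energy(complexes[0])
    e_product_complex = calculator.energy(complexes[1])
    e_ts = calculator.energy(ts)
    return EnergyProfile(
        barrier_separated=e_ts - e_reactants,
        reaction_energy_separated=e_products - e_reactants,
        barrier_complexed=e_ts - e_reactant_complex,
        reaction_energy_complexed=e_product_complex - e_reactant_complex,
        ts_energy=e_ts,
    )


# ---------------------------------------------------------------------------
# minimum optimization and spline storage


def optimize_minimum(
    structure: Structure,
    calculator: Calculator,
    gradient_threshold: float = 1e-7,
    max_iterations: int = 500,
) -> Structure:
    """Plain BFGS relaxation to a local minimum."""
    probe = structure.copy()

    def objective(x: np.ndarray):
        probe.positions = x.reshape(-1, 3)
        result = calculator.compute(probe, {"energy", "gradient"})
        return result.energy, result.gradient.ravel()

    solution = minimize(
        objective,
        structure.positions.ravel(),
        jac=True,
        method="BFGS",
        options={"gtol": gradient_threshold, "maxiter": max_iterations},
    )
    return structure.copy(positions=solution.x.reshape(-1, 3), label="minimum")


@dataclass
class PathSpline:
    """Cubic splines of energy and coordinates over normalized arc length."""

    knots: np.ndarray  # (M,) in [0, 1]
    energies: np.ndarray  # (M,)
    coordinates: np.ndarray  # (M, N, 3)

    def __post_init__(self) -> None:
        self._energy_spline = CubicSpline(self.knots, self.energies)
        flat = self.coordinates.reshape(self.coordinates.shape[0], -1)
        self._coordinate_spline = CubicSpline(self.knots, flat, axis=0)

    def energy(self, t: float) -> float:
        return float(self._energy_spline(t))

    def positions(self, t: float) -> np.ndarray:
        return self._coordinate_spline(t).reshape(-1, 3)

    def to_doc(self) -> dict:
        return {
            "knots": self.knots.tolist(),
            "energies": self.energies.tolist(),
            "coordinates": self.coordinates.tolist(),
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "PathSpline":
        return cls(
            knots=np.asarray(doc["knots"]),
            energies=np.asarray(doc["energies"]),
            coordinates=np.asarray(doc["coordinates"]),
        )


def spline_path(trajectory: Trajectory) -> PathSpline:
    """Interpolate a trajectory over normalized arc length in [0, 1]."""
    if trajectory.n_frames < 4:
        raise ValidationError("spline storage needs at least 4 frames")
    coords = np.array([frame.positions for frame in trajectory.frames])
    flat = coords.reshape(coords.shape[0], -1)
    seglen = np.linalg.norm(np.diff(flat, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    if arc[-1] < 1e-12:
        raise ValidationError("degenerate path: zero arc length")
    knots = arc / arc[-1]
    # collapse duplicate knots (frames that did not move)
    keep = np.concatenate([[True], np.diff(knots) > 1e-12])
    return PathSpline(
        knots=knots[keep], energies=trajectory.energies[keep], coordinates=coords[keep]
    )
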