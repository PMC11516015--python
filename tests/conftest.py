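"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import fsolve

from rxnet import (
    CovalentRadiiTable,
    MorseCalculator,
    MuellerBrownCalculator,
    PairPotentialParams,
    barrier_params,
)
from rxnet.calculator import mueller_brown_gradient


@pytest.fixture(scope="session")
def morse_calculator() -> MorseCalculator:
    """Plain pairwise Morse backend (no dissociation barriers)."""
    return MorseCalculator(PairPotentialParams())


@pytest.fixture(scope="session")
def barrier_calculator() -> MorseCalculator:
    """Morse backend with a Gaussian dissociation barrier on every pair."""
    return MorseCalculator(barrier_params())


@pytest.fixture(scope="session")
def mb_calculator() -> MuellerBrownCalculator:
    return MuellerBrownCalculator()


@pytest.fixture(scope="session")
def radii() -> CovalentRadiiTable:
    return CovalentRadiiTable()


def mueller_brown_stationary_points() -> list[tuple[float, float, int]]:
    """Independent oracle: dense grid of Newton starts polished with fsolve.

    Returns deduplicated stationary points (x, y, n_negative_eigenvalues)
    of the analytic 2D surface inside the physically relevant window.
    """
    points: list[tuple[float, float, int]] = []
    for x0 in np.linspace(-1.7, 1.1, 24):
        for y0 in np.linspace(-0.4, 2.1, 22):
            solution, info, ier, _ = fsolve(
                lambda p: mueller_brown_gradient(p[0], p[1]),
                [x0, y0],
                full_output=True,
            )
            if ier != 1 or np.linalg.norm(info["fvec"]) > 1e-9:
                continue
            x, y = float(solution[0]), float(solution[1])
            if not (-1.8 <= x <= 1.2 and -0.5 <= y <= 2.2):
                continue
            if any(np.hypot(x - px, y - py) < 1e-5 for px, py, _ in points):
                continue
            eps = 1e-5
            hessian = np.zeros((2, 2))
            for k, (dx, dy) in enumerate([(eps, 0.0), (0.0, eps)]):
                hessian[:, k] = (
                    mueller_brown_gradient(x + dx, y + dy)
                    - mueller_brown_gradient(x - dx, y - dy)
                ) / (2 * eps)
            hessian = 0.5 * (hessian + hessian.T)
            negatives = int(np.sum(np.linalg.eigvalsh(hessian) < 0))
            points.append((x, y, negatives))
    return points


@pytest.fixture(scope="session")
def mb_stationary_points() -> list[tuple[float, float, int]]:
    return mueller_brown_stationary_points()


@pytest.fixture(scope="session")
def mb_minima(mb_stationary_points) -> list[tuple[float, float]]:
    return sorted((x, y) for x, y, neg in mb_stationary_points if neg == 0)


@pytest.fixture(scope="session")
def mb_saddles(mb_stationary_points) -> list[tuple[float, float]]:
    return sorted((x, y) for x, y, neg in mb_stationary_points if neg == 1)
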