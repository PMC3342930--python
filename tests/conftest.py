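"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

import mechsynergy as ms


@pytest.fixture
def schematic():
    return ms.make_schematic_limb()


@pytest.fixture
def finger():
    return ms.make_finger_like()


@pytest.fixture
def leg():
    return ms.make_leg_like()


def active_set_vertices(a_eq: np.ndarray, b_eq: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Brute-force vertex oracle for {a in [0,1]^n : A a = b}.

    Every vertex has at least n - rank(A) coordinates tight at a bound, so:
    fix each size-(n - rank) coordinate subset at each 0/1 combination, solve
    the equalities on the remaining coordinates (only nonsingular
    subsystems), and keep feasible, duplicate-free solutions.  Exponential
    and entirely independent of the package's incremental-cut enumerator.
    """
    A = np.atleast_2d(np.asarray(a_eq, dtype=float))
    b = np.atleast_1d(np.asarray(b_eq, dtype=float))
    n = A.shape[1]
    r = np.linalg.matrix_rank(A)
    found: list[np.ndarray] = []
    for fixed in combinations(range(n), n - r):
        free = [j for j in range(n) if j not in fixed]
        Af = A[:, free]
        if np.linalg.matrix_rank(Af) < r:
            continue
        for bits in product((0.0, 1.0), repeat=n - r):
            rhs = b - A[:, list(fixed)] @ np.array(bits)
            x, *_ = np.linalg.lstsq(Af, rhs, rcond=None)
            a = np.empty(n)
            a[list(fixed)] = bits
            a[free] = x
            if (
                np.max(np.abs(A @ a - b)) < tol
                and np.all(a >= -1e-10)
                and np.all(a <= 1 + 1e-10)
            ):
                found.append(np.clip(a, 0.0, 1.0))
    if not found:
        return np.empty((0, n))
    arr = np.array(sorted(map(tuple, found)))
    keep = [0]
    for i in range(1, arr.shape[0]):
        if np.max(np.abs(arr[i] - arr[keep[-1]])) > 1e-8:
            keep.append(i)
    return arr[keep]


@pytest.fixture
def vertex_oracle():
    return active_set_vertices
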