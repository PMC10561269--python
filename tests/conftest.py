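"""Shared fixtures: small molecules and harmonic Cartesian test surfaces."""

from __future__ import annotations

import numpy as np
import pytest

from tgaspec import molgeom
from tgaspec.potentials import QuadraticPotential


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def water() -> molgeom.AtomicSystem:
    """Bent triatomic (water-like), coordinates in bohr."""
    coords = np.array(
        [
            [0.0, 0.0, 0.2217],
            [0.0, 1.4309, -0.8867],
            [0.0, -1.4309, -0.8867],
        ]
    ).ravel()
    return molgeom.AtomicSystem.from_labels(["O", "H", "H"], coords)


def trans_rot_vectors(system: molgeom.AtomicSystem) -> np.ndarray:
    """Orthonormal mass-scaled translation/rotation generators, (3N, 6)."""
    sys0 = molgeom.shift_to_com(system)
    sqrt_m = np.sqrt(sys0.masses)
    n = sys0.n_atoms
    cols = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = sqrt_m
        cols.append(t.ravel())
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        r = np.cross(np.broadcast_to(e, (n, 3)), sys0.coords3) * sqrt_m[:, None]
        cols.append(r.ravel())
    basis = np.column_stack(cols)
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10  # drop the null rotation of linear molecules
    return q[:, keep]


def make_cart_hessian(
    system: molgeom.AtomicSystem,
    freqs_au,
    seed: int = 0,
) -> np.ndarray:
    """Cartesian Hessian whose mass-scaled form has the given vibrational
    frequencies and *exact* zero translation/rotation modes.

    The vibrational eigenvectors are a reproducible random orthonormal basis
    of the complement of the translation/rotation space.
    """
    freqs = np.atleast_1d(np.asarray(freqs_au, float))
    sys0 = molgeom.shift_to_com(system)
    tr = trans_rot_vectors(sys0)
    n3 = 3 * sys0.n_atoms
    if freqs.size != n3 - tr.shape[1]:
        raise ValueError("need one frequency per vibrational mode")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n3, n3))
    raw -= tr @ (tr.T @ raw)
    q, _ = np.linalg.qr(raw)
    vib = q[:, : freqs.size]
    h_ms = vib @ np.diag(freqs**2) @ vib.T
    sqrt_m3 = np.sqrt(sys0.masses3)
    return h_ms * np.outer(sqrt_m3, sqrt_m3)


def cartesian_harmonic_surface(
    system: molgeom.AtomicSystem,
    freqs_au,
    e0: float = 0.0,
    seed: int = 0,
) -> tuple[QuadraticPotential, np.ndarray]:
    """Quadratic Cartesian PES with minimum at the COM-shifted geometry."""
    sys0 = molgeom.shift_to_com(system)
    hess = make_cart_hessian(sys0, freqs_au, seed)
    surface = QuadraticPotential(
        sys0.coords, e0, np.zeros_like(sys0.coords), hess, coords="cartesian"
    )
    return surface, hess


def random_proper_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform random proper rotations, shape (n, 3, 3), via quaternions."""
    quat = rng.standard_normal((n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    w, x, y, z = quat.T
    return np.stack(
        [
            np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x**2 + z**2), 2 * (y * z - w * x)], -1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x**2 + y**2)], -1),
        ],
        axis=1,
    )
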