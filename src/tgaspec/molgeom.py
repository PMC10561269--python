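"""Molecular configurations and normal-mode machinery.

This module handles the purely geometric side of wavepacket propagation in
vibrational coordinates: isotope substitution, removal of translations
(center-of-mass shift) and rotations (Eckart-frame alignment via the
mass-weighted Kabsch algorithm), diagonalization of the mass-scaled Cartesian
Hessian, and the chain-rule transformation of gradients and Hessians between
Cartesian and mass-scaled vibrational normal-mode coordinates.

All quantities are in Hartree atomic units; XYZ files (angstrom) are
converted at the I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constants import (
    BOHR_PER_ANGSTROM,
    INV_CM_PER_HARTREE,
    ME_PER_AMU,
    isotope_mass,
)

__all__ = [
    "AtomicSystem",
    "EckartAlignment",
    "NormalModeBasis",
    "substitute_isotopes",
    "shift_to_com",
    "eckart_rotation",
    "normal_mode_analysis",
    "cart_to_nm",
    "nm_to_cart",
    "transform_derivatives",
    "duschinsky_matrix",
    "read_xyz",
    "write_xyz",
]


@dataclass(frozen=True)
class AtomicSystem:
    """A molecular configuration: labels, per-atom masses, and coordinates.

    Parameters
    ----------
    labels
        Per-atom element or isotope tags (e.g. ``"N"``, ``"H"``, ``"D"``).
    masses
        Per-atom masses in atomic units (electron masses), strictly positive.
    coords
        Flat array of 3N Cartesian coordinates in bohr.
    """

    labels: tuple[str, ...]
    masses: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float).ravel())
        if self.masses.ndim != 1 or len(self.labels) != self.masses.size:
            raise ValueError("labels and masses must have one entry per atom")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")
        if self.coords.size != 3 * self.masses.size:
            raise ValueError(
                f"expected {3 * self.masses.size} coordinates, got {self.coords.size}"
            )

    @classmethod
    def from_labels(cls, labels: Sequence[str], coords_bohr) -> "AtomicSystem":
        """Build a system looking masses up from the bundled isotope table."""
        masses = np.array([isotope_mass(lab) for lab in labels])
        return cls(tuple(labels), masses, np.asarray(coords_bohr, dtype=float))

    @property
    def n_atoms(self) -> int:
        return self.masses.size

    @property
    def coords3(self) -> np.ndarray:
        """Coordinates reshaped to (N, 3)."""
        return self.coords.reshape(-1, 3)

    @property
    def masses3(self) -> np.ndarray:
        """Masses repeated per Cartesian component, shape (3N,)."""
        return np.repeat(self.masses, 3)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coords3 / self.total_mass

    def with_coords(self, coords) -> "AtomicSystem":
        return AtomicSystem(self.labels, self.masses.copy(), np.asarray(coords, float))


@dataclass(frozen=True)
class EckartAlignment:
    """Result of aligning a configuration to a reference in the Eckart frame.

    ``rotation`` is the proper rotation R minimizing the squared mass-scaled
    distance between the rotated, COM-shifted configuration and the
    reference; ``com_shift`` is the center of mass of the input configuration
    (subtracted before rotating); ``residual`` is the minimized squared
    mass-scaled distance.
    """

    rotation: np.ndarray
    com_shift: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        object.__setattr__(self, "com_shift", np.asarray(self.com_shift, float))
        if self.residual < -1e-12:
            raise ValueError("residual must be nonnegative")

    def apply(self, coords3: np.ndarray) -> np.ndarray:
        """Rotate (N, 3) coordinates: r -> R·r."""
        return coords3 @ self.rotation.T

    def apply_inverse(self, coords3: np.ndarray) -> np.ndarray:
        return coords3 @ self.rotation


def substitute_isotopes(
    system: AtomicSystem, substitutions: Mapping[int, str]
) -> AtomicSystem:
    """Replace the masses of selected atoms by other isotopes.

    Coordinates are returned bit-identical: on the Born-Oppenheimer surface
    the potential does not depend on nuclear masses, so isotopologues share
    the PES and differ only in their dynamics.

    Parameters
    ----------
    substitutions
        Mapping from 0-based atom index to isotope tag (e.g. ``{1: "D"}``).
    """
    labels = list(system.labels)
    masses = system.masses.copy()
    for idx, tag in substitutions.items():
        if not (0 <= idx < system.n_atoms):
            raise IndexError(f"atom index {idx} out of range for {system.n_atoms} atoms")
        masses[idx] = isotope_mass(tag)
        labels[idx] = tag
    return AtomicSystem(tuple(labels), masses, system.coords)


def shift_to_com(system: AtomicSystem) -> AtomicSystem:
    """Translate the configuration so its center of mass sits at the origin."""
    return system.with_coords((system.coords3 - system.center_of_mass()).ravel())


def eckart_rotation(system: AtomicSystem, reference: AtomicSystem) -> EckartAlignment:
    """Align ``system`` to ``reference`` in the Eckart frame.

    The configuration is first shifted to its center of mass and then rotated
    by the proper rotation R that minimizes the squared mass-scaled distance

        sum_a m_a |R r'_a - r_ref,a|^2 .

    R is obtained from the mass-weighted Kabsch construction: SVD of the
    mass-weighted covariance matrix with a determinant correction enforcing
    det R = +1.  The stationarity condition of this minimization is exactly
    the (rotational) Eckart condition, so the aligned displacement carries no
    first-order rotational component.

    The reference must already have its center of mass at the origin.
    """
    if system.n_atoms != reference.n_atoms:
        raise ValueError(
            f"atom count mismatch: {system.n_atoms} vs {reference.n_atoms}"
        )
    if not np.allclose(system.masses, reference.masses, rtol=1e-10):
        raise ValueError("system and reference must share per-atom masses")
    if np.linalg.norm(reference.center_of_mass()) > 1e-8:
        raise ValueError("reference configuration must have its COM at the origin")

    com = system.center_of_mass()
    x = system.coords3 - com  # r'_a
    xr = reference.coords3

    # mass-weighted covariance: B = sum_a m_a r_ref,a r'_a^T
    b = (reference.masses[:, None] * xr).T @ x
    u, _s, vt = np.linalg.svd(b)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, d]) @ vt

    rotated = x @ r.T
    residual = float(np.sum(system.masses[:, None] * (rotated - xr) ** 2))
    return EckartAlignment(rotation=r, com_shift=com, residual=max(residual, 0.0))


def _inertia_moments(system: AtomicSystem) -> np.ndarray:
    x = system.coords3 - system.center_of_mass()
    m = system.masses
    i_mat = np.einsum("a,aij->ij", m, np.einsum("a,ij->aij", np.sum(x * x, axis=1), np.eye(3)))
    i_mat -= np.einsum("a,ai,aj->ij", m, x, x)
    return np.linalg.eigvalsh(i_mat)


def is_linear(system: AtomicSystem, tol: float = 1e-8) -> bool:
    """Detect a linear configuration via the rank of the inertia tensor."""
    moments = _inertia_moments(system)
    return bool(moments[0] < tol * max(moments[-1], 1.0))


@dataclass(frozen=True)
class NormalModeBasis:
    """Mass-scaled vibrational normal-mode basis at a reference geometry.

    ``modes`` holds the 3N x (3N-6) matrix L of retained eigenvectors of the
    mass-scaled Cartesian Hessian (3N-5 columns for a linear reference); its
    columns are orthonormal.  ``frequencies`` are the corresponding mode
    frequencies in atomic units, using a sign-preserving square root
    (negative entries flag imaginary frequencies at non-stationary or
    saddle-type reference points).
    """

    ref_system: AtomicSystem
    modes: np.ndarray
    frequencies: np.ndarray
    eigenvalues: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "modes", np.asarray(self.modes, float))
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, float))
        if self.eigenvalues is None:
            object.__setattr__(
                self, "eigenvalues", np.sign(self.frequencies) * self.frequencies**2
            )
        n3 = 3 * self.ref_system.n_atoms
        if self.modes.shape[0] != n3 or self.modes.shape[1] != self.frequencies.size:
            raise ValueError("mode matrix shape inconsistent with reference system")

    @property
    def n_modes(self) -> int:
        return self.frequencies.size

    @property
    def frequencies_cm1(self) -> np.ndarray:
        return self.frequencies * INV_CM_PER_HARTREE

    def to_json(self, path) -> None:
        """Serialize (frequencies in cm^-1, L matrix, reference geometry)."""
        ref = self.ref_system
        payload = {
            "labels": list(ref.labels),
            "masses_amu": (ref.masses / ME_PER_AMU).tolist(),
            "coords_bohr": ref.coords.tolist(),
            "frequencies_cm1": self.frequencies_cm1.tolist(),
            "modes": self.modes.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "NormalModeBasis":
        payload = json.loads(Path(path).read_text())
        ref = AtomicSystem(
            tuple(payload["labels"]),
            np.asarray(payload["masses_amu"]) * ME_PER_AMU,
            np.asarray(payload["coords_bohr"]),
        )
        freqs = np.asarray(payload["frequencies_cm1"]) / INV_CM_PER_HARTREE
        return cls(ref, np.asarray(payload["modes"]), freqs)


def normal_mode_analysis(
    reference: AtomicSystem,
    cart_hessian: np.ndarray,
    *,
    linear: bool | None = None,
    symmetry_tol: float = 1e-8,
) -> NormalModeBasis:
    """Diagonalize the mass-scaled Cartesian Hessian at a reference geometry.

    The Hessian is scaled as m^(-1/2) H m^(-1/2) and diagonalized; the 6
    modes of smallest absolute eigenvalue (5 for a linear reference) are
    projected out as translations/rotations and the remainder returned sorted
    by ascending frequency.  Projecting out the *smallest-magnitude*
    eigenvalues rather than exact zeros keeps the construction robust at
    non-stationary reference points, where the would-be zero modes pick up
    small nonzero curvatures.

    Frequencies are sign-preserving square roots of the eigenvalues, so a
    basis built at a minimum has all-positive (real) frequencies.
    """
    h = np.asarray(cart_hessian, dtype=float)
    n3 = 3 * reference.n_atoms
    if h.shape != (n3, n3):
        raise ValueError(f"Hessian must be {n3}x{n3}, got {h.shape}")
    scale = max(1.0, float(np.abs(h).max()))
    if np.abs(h - h.T).max() > symmetry_tol * scale:
        raise ValueError("Cartesian Hessian is asymmetric beyond tolerance")

    ref0 = shift_to_com(reference)
    inv_sqrt_m = 1.0 / np.sqrt(ref0.masses3)
    hm = h * np.outer(inv_sqrt_m, inv_sqrt_m)
    hm = 0.5 * (hm + hm.T)
    vals, vecs = np.linalg.eigh(hm)

    n_zero = 5 if (linear if linear is not None else is_linear(ref0)) else 6
    keep = np.argsort(np.abs(vals))[n_zero:]
    keep = keep[np.argsort(vals[keep])]

    modes = vecs[:, keep]
    # reproducible sign convention: largest-magnitude component positive
    for j in range(modes.shape[1]):
        k = int(np.argmax(np.abs(modes[:, j])))
        if modes[k, j] < 0:
            modes[:, j] = -modes[:, j]
    eigenvalues = vals[keep]
    freqs = np.sign(eigenvalues) * np.sqrt(np.abs(eigenvalues))
    return NormalModeBasis(ref0, modes, freqs, eigenvalues)


def cart_to_nm(
    system: AtomicSystem,
    basis: NormalModeBasis,
    *,
    return_alignment: bool = False,
):
    """Map a configuration to mass-scaled vibrational normal-mode coordinates.

    The configuration is COM-shifted, Eckart-aligned to the basis reference,
    and projected:  q = L^T m^(1/2) (xi_rot - xi_ref).  The reference
    geometry itself maps to q = 0.
    """
    align = eckart_rotation(system, basis.ref_system)
    rotated = align.apply(system.coords3 - align.com_shift).ravel()
    disp = rotated - basis.ref_system.coords
    q = basis.modes.T @ (np.sqrt(basis.ref_system.masses3) * disp)
    if return_alignment:
        return q, align
    return q


def nm_to_cart(
    q: np.ndarray,
    basis: NormalModeBasis,
    alignment: EckartAlignment | None = None,
) -> AtomicSystem:
    """Map normal-mode coordinates back to a Cartesian configuration.

    Without an alignment the geometry is returned in the Eckart frame of the
    basis reference; passing the alignment from :func:`cart_to_nm` undoes the
    rotation and COM shift, returning to the original frame.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (basis.n_modes,):
        raise ValueError(f"expected {basis.n_modes} normal-mode coordinates")
    ref = basis.ref_system
    xi = ref.coords + (basis.modes @ q) / np.sqrt(ref.masses3)
    if alignment is not None:
        xi = (alignment.apply_inverse(xi.reshape(-1, 3)) + alignment.com_shift).ravel()
    return ref.with_coords(xi)


def transform_derivatives(
    cart_gradient: np.ndarray,
    cart_hessian: np.ndarray,
    basis: NormalModeBasis,
    alignment: EckartAlignment | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Chain-rule a Cartesian gradient and Hessian into normal-mode coordinates.

    With D = m^(-1/2) and the block rotation R_xi = I_N (x) R,

        g_q = L^T D R_xi g,      H_q = L^T D R_xi H R_xi^T D L .

    The returned Hessian is explicitly symmetrized to remove roundoff
    asymmetry.
    """
    g = np.asarray(cart_gradient, float).ravel()
    h = np.asarray(cart_hessian, float)
    n3 = 3 * basis.ref_system.n_atoms
    if g.size != n3 or h.shape != (n3, n3):
        raise ValueError("gradient/Hessian shapes inconsistent with basis")
    if alignment is not None:
        r = alignment.rotation
        g3 = g.reshape(-1, 3) @ r.T
        g = g3.ravel()
        rbig = np.kron(np.eye(basis.ref_system.n_atoms), r)
        h = rbig @ h @ rbig.T
    inv_sqrt_m = 1.0 / np.sqrt(basis.ref_system.masses3)
    lt = basis.modes.T
    g_q = lt @ (inv_sqrt_m * g)
    h_q = lt @ (h * np.outer(inv_sqrt_m, inv_sqrt_m)) @ basis.modes
    return g_q, 0.5 * (h_q + h_q.T)


def duschinsky_matrix(
    basis_g: NormalModeBasis, basis_e: NormalModeBasis
) -> tuple[np.ndarray, np.ndarray]:
    """Mode-mixing matrix J and displacement between two normal-mode bases.

    J = L_e^T R_xi L_g with R the Eckart rotation of the ground reference
    onto the excited reference; the displacement vector is the excited-frame
    normal-mode position of the ground reference geometry.
    """
    if not np.allclose(basis_g.ref_system.masses, basis_e.ref_system.masses, rtol=1e-10):
        raise ValueError("bases must share atomic masses")
    align = eckart_rotation(basis_g.ref_system, basis_e.ref_system)
    rbig = np.kron(np.eye(basis_e.ref_system.n_atoms), align.rotation)
    j = basis_e.modes.T @ rbig @ basis_g.modes
    disp = cart_to_nm(basis_g.ref_system, basis_e)
    return j, disp


# ---------------------------------------------------------------------------
# XYZ I/O (standard two-header-line dialect, coordinates in angstrom)

def read_xyz(path) -> AtomicSystem:
    """Read an XYZ file.

    The element column may carry isotope tags directly (``D``, ``13C`` ...);
    alternatively the comment line may carry ``isotope=i:TAG,j:TAG`` entries
    with 1-based atom indices.
    """
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    comment = lines[1] if len(lines) > 1 else ""
    labels, xyz = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        labels.append(parts[0])
        xyz.append([float(v) for v in parts[1:4]])
    system = AtomicSystem.from_labels(
        labels, np.asarray(xyz).ravel() * BOHR_PER_ANGSTROM
    )
    for tok in comment.replace(";", " ").split():
        if tok.startswith("isotope="):
            subs = {}
            for entry in tok[len("isotope="):].split(","):
                idx, tag = entry.split(":")
                subs[int(idx) - 1] = tag
            system = substitute_isotopes(system, subs)
    return system


def write_xyz(path, system: AtomicSystem, comment: str = "") -> None:
    lines = [str(system.n_atoms), comment]
    for lab, r in zip(system.labels, system.coords3 / BOHR_PER_ANGSTROM):
        lines.append(f"{lab:4s} {r[0]:18.12f} {r[1]:18.12f} {r[2]:18.12f}")
    Path(path).write_text("\n".join(lines) + "\n")
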