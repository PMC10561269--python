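"""Thawed Gaussian wavepacket dynamics in Hagedorn's parameterization.

A single D-dimensional Gaussian wavepacket

    psi(x) = (pi hbar)^(-D/4) det(Q_t)^(-1/2)
             exp[ (i/2hbar) x.P_t Q_t^(-1).x + (i/hbar) p_t.x + (i/hbar) S_t ],

with x = q - q_t, is propagated under the local harmonic approximation of
the potential about its own center.  The center (q_t, p_t) follows the
classical trajectory of the *full* potential, the complex width matrices
(Q_t, P_t) evolve under the local Hessian, and the classical action S_t
accumulates the Lagrangian:

    dq/dt = p,        dp/dt = -grad V(q),
    dQ/dt = P,        dP/dt = -Hess V(q) . Q,
    dS/dt = |p|^2/2 - V(q).

The Hagedorn matrices satisfy the symplecticity/normalization relations

    Q^T P - P^T Q = 0,        Q^dag P - P^dag Q = 2i I_D,

which guarantee that Q_t stays invertible and the packet stays normalized;
the second-order symplectic integrator used here preserves both relations
exactly (to roundoff) because each sub-step is a linear symplectic update.

Everything runs in mass-scaled (unit-mass) coordinates with hbar = 1; a
surface in those coordinates is produced by :class:`~tgaspec.potentials.
MassScaledSurface` or :class:`~tgaspec.potentials.NormalModeSurface`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import molgeom
from .constants import INV_CM_PER_HARTREE
from .potentials import PotentialSurface
from .spectra import Autocorrelation

__all__ = [
    "HagedornWavepacket",
    "TrajectoryRecord",
    "ground_state_wavepacket",
    "init_wavepacket",
    "propagate",
    "autocorrelation",
    "mode_activation",
    "ModeActivation",
]


@dataclass
class HagedornWavepacket:
    """Gaussian wavepacket parameters (q, p, Q, P, S) in mass-scaled coordinates."""

    q: np.ndarray
    p: np.ndarray
    Q: np.ndarray
    P: np.ndarray
    action: float = 0.0

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, float))
        self.p = np.atleast_1d(np.asarray(self.p, float))
        self.Q = np.atleast_2d(np.asarray(self.Q, complex))
        self.P = np.atleast_2d(np.asarray(self.P, complex))
        d = self.q.size
        if self.p.size != d or self.Q.shape != (d, d) or self.P.shape != (d, d):
            raise ValueError("inconsistent wavepacket parameter shapes")

    @property
    def dim(self) -> int:
        return self.q.size

    def copy(self) -> "HagedornWavepacket":
        return HagedornWavepacket(
            self.q.copy(), self.p.copy(), self.Q.copy(), self.P.copy(), self.action
        )

    def hagedorn_defect(self) -> float:
        """Max-norm residual of the two Hagedorn relations."""
        d = self.dim
        r1 = self.Q.conj().T @ self.P - self.P.conj().T @ self.Q - 2j * np.eye(d)
        r2 = self.Q.T @ self.P - self.P.T @ self.Q
        return float(max(np.abs(r1).max(), np.abs(r2).max()))

    def norm(self) -> float:
        """L2 norm of the packet, computed from the width matrices.

        Equals 1 exactly when the Hagedorn relations hold.
        """
        x = 1j * (self.P.conj().T @ self.Q - self.Q.conj().T @ self.P)
        det = np.linalg.det(x)
        return float(np.real(2.0 ** (self.dim / 2) * det ** (-0.25) * np.conj(det) ** (-0.25)))

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Evaluate psi at points of shape (..., D) (principal det branch)."""
        pts = np.atleast_2d(np.asarray(points, float))
        x = pts - self.q
        a = self.P @ np.linalg.inv(self.Q)
        quad = 0.5j * np.einsum("ni,ij,nj->n", x, a, x)
        lin = 1j * (x @ self.p)
        pref = np.pi ** (-self.dim / 4) * np.linalg.det(self.Q) ** (-0.5)
        return pref * np.exp(quad + lin + 1j * self.action)

    def position_covariance(self) -> np.ndarray:
        """Position covariance matrix  Cov = Re(Q Q^dag) / 2  (hbar = 1)."""
        return 0.5 * np.real(self.Q @ self.Q.conj().T)


def ground_state_wavepacket(
    hessian_nm: np.ndarray, center, momentum=None
) -> HagedornWavepacket:
    """Ground vibrational eigenstate of a harmonic fit, as a Hagedorn packet.

    Given the (mass-scaled) normal-mode Hessian kappa of the initial-state
    harmonic fit, the width matrices are  Q_0 = kappa^(-1/4), P_0 = i
    kappa^(1/4), which satisfy the Hagedorn relations by construction and
    give the 1D position variance hbar / (2 omega).  All eigenvalues of
    kappa must be positive (a bound fit).
    """
    kappa = np.atleast_2d(np.asarray(hessian_nm, float))
    kappa = 0.5 * (kappa + kappa.T)
    vals, vecs = np.linalg.eigh(kappa)
    if np.any(vals <= 0):
        raise ValueError(
            "ground-state Hessian has nonpositive eigenvalues; "
            "the harmonic fit has no ground eigenstate"
        )
    q_mat = (vecs * vals**-0.25) @ vecs.T
    p_mat = 1j * (vecs * vals**0.25) @ vecs.T
    center = np.atleast_1d(np.asarray(center, float))
    momentum = np.zeros_like(center) if momentum is None else np.asarray(momentum, float)
    return HagedornWavepacket(center, momentum, q_mat, p_mat, action=0.0)


def init_wavepacket(
    ground_basis: molgeom.NormalModeBasis,
    excited_basis: molgeom.NormalModeBasis,
    ground_equilibrium: molgeom.AtomicSystem,
) -> HagedornWavepacket:
    """Initial packet for an absorption calculation, in excited-state modes.

    The packet is the ground vibrational eigenstate of the harmonic fit to
    the initial electronic state, placed at the Franck-Condon point: q_0 is
    the excited-frame normal-mode position of the ground-state equilibrium
    geometry, p_0 = 0, and the width matrices come from the ground-state
    Hessian expressed in the excited-state modes via the Duschinsky matrix,
    kappa = J Omega_g^2 J^T.
    """
    j, _disp = molgeom.duschinsky_matrix(ground_basis, excited_basis)
    kappa = j @ np.diag(ground_basis.frequencies**2) @ j.T
    q0 = molgeom.cart_to_nm(ground_equilibrium, excited_basis)
    return ground_state_wavepacket(kappa, q0)


@dataclass
class TrajectoryRecord:
    """Time series of wavepacket parameters and local PES data along a run.

    Arrays are indexed by snapshot (n_steps + 1 of them, uniform grid);
    ``hessians[k]`` etc. are the single per-step PES evaluation, taken
    exactly at the recorded center ``positions[k]``.
    """

    times: np.ndarray
    positions: np.ndarray
    momenta: np.ndarray
    q_matrices: np.ndarray
    p_matrices: np.ndarray
    actions: np.ndarray
    potentials: np.ndarray
    gradients: np.ndarray
    hessians: np.ndarray

    def __len__(self) -> int:
        return self.times.size

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def energies(self) -> np.ndarray:
        """Classical energy of the center, |p|^2/2 + V(q), per snapshot."""
        return 0.5 * np.sum(self.momenta**2, axis=1) + self.potentials

    def wavepacket(self, k: int) -> HagedornWavepacket:
        return HagedornWavepacket(
            self.positions[k],
            self.momenta[k],
            self.q_matrices[k],
            self.p_matrices[k],
            float(self.actions[k]),
        )

    @property
    def initial(self) -> HagedornWavepacket:
        return self.wavepacket(0)

    @property
    def final(self) -> HagedornWavepacket:
        return self.wavepacket(len(self) - 1)

    def hagedorn_defects(self) -> np.ndarray:
        return np.array([self.wavepacket(k).hagedorn_defect() for k in range(len(self))])

    def norms(self) -> np.ndarray:
        return np.array([self.wavepacket(k).norm() for k in range(len(self))])

    def save(self, path) -> None:
        """Persist to a structured binary container (NumPy .npz)."""
        np.savez_compressed(
            Path(path),
            times=self.times,
            positions=self.positions,
            momenta=self.momenta,
            q_matrices=self.q_matrices,
            p_matrices=self.p_matrices,
            actions=self.actions,
            potentials=self.potentials,
            gradients=self.gradients,
            hessians=self.hessians,
        )

    @classmethod
    def load(cls, path) -> "TrajectoryRecord":
        with np.load(Path(path)) as data:
            return cls(**{key: data[key] for key in data.files})


def propagate(
    wp: HagedornWavepacket,
    surface: PotentialSurface,
    dt: float,
    n_steps: int,
    *,
    callback=None,
) -> TrajectoryRecord:
    """Propagate a thawed Gaussian with the second-order symplectic integrator.

    One kick-drift-kick step advances (q, p) and (Q, P) jointly:

        p_half = p - (dt/2) grad V(q_n)       P_half = P - (dt/2) H_n Q_n
        q_new  = q + dt p_half                Q_new  = Q + dt P_half
        p_new  = p_half - (dt/2) grad V(q_new)  etc.

    so there is exactly one gradient + Hessian evaluation per step (the
    evaluation at q_new is reused as the next step's q_n), and it falls on
    the recorded snapshot positions.  The action accumulates the matching
    discrete Lagrangian, dt |p_half|^2/2 - dt (V_n + V_{n+1})/2.

    Each sub-step is a linear symplectic map, so the Hagedorn relations are
    conserved exactly (to roundoff) along the trajectory; the classical
    energy of the center oscillates with an O(dt^2) amplitude.
    """
    if dt <= 0:
        raise ValueError("time step must be positive")
    if n_steps < 1:
        raise ValueError("need at least one step")
    if surface.ndim != wp.dim:
        raise ValueError(
            f"surface dimension {surface.ndim} != wavepacket dimension {wp.dim}"
        )
    d = wp.dim
    n_snap = n_steps + 1
    times = dt * np.arange(n_snap)
    positions = np.empty((n_snap, d))
    momenta = np.empty((n_snap, d))
    q_mats = np.empty((n_snap, d, d), complex)
    p_mats = np.empty((n_snap, d, d), complex)
    actions = np.empty(n_snap)
    potentials = np.empty(n_snap)
    gradients = np.empty((n_snap, d))
    hessians = np.empty((n_snap, d, d))

    q, p = wp.q.copy(), wp.p.copy()
    qm, pm = wp.Q.copy(), wp.P.copy()
    action = wp.action

    try:
        v, g, h = surface.evaluate(q)
    except Exception as exc:  # noqa: BLE001 - annotate with step index
        raise RuntimeError(f"surface evaluation failed at step 0: {exc}") from exc

    positions[0], momenta[0], q_mats[0], p_mats[0] = q, p, qm, pm
    actions[0], potentials[0], gradients[0], hessians[0] = action, v, g, h

    for step in range(1, n_snap):
        p_half = p - 0.5 * dt * g
        pm_half = pm - 0.5 * dt * (h @ qm)
        q = q + dt * p_half
        qm = qm + dt * pm_half
        v_prev = v
        try:
            v, g, h = surface.evaluate(q)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"surface evaluation failed at step {step}: {exc}") from exc
        p = p_half - 0.5 * dt * g
        pm = pm_half - 0.5 * dt * (h @ qm)
        action += dt * (0.5 * p_half @ p_half) - 0.5 * dt * (v_prev + v)

        positions[step], momenta[step] = q, p
        q_mats[step], p_mats[step] = qm, pm
        actions[step], potentials[step] = action, v
        gradients[step], hessians[step] = g, h
        if callback is not None:
            callback(step, times[step], q, p)

    return TrajectoryRecord(
        times, positions, momenta, q_mats, p_mats, actions, potentials, gradients, hessians
    )


def autocorrelation(
    record: TrajectoryRecord, initial: HagedornWavepacket | None = None
) -> Autocorrelation:
    """C(t) = <psi_0 | psi_t> via the closed-form overlap of two Gaussians.

    For Hagedorn packets the Gaussian integral collapses to

        C(t) = 2^(D/2) det(X_t)^(-1/2) exp( b.M^(-1)b / 2 + c ),
        X_t  = i (P_0^dag Q_t - Q_0^dag P_t),

    with M, b, c the quadratic, linear, and constant parts of the combined
    exponent (M = i (A_0^* - A_t), A = P Q^(-1)).  At t = 0, X = 2 I and
    C = 1 exactly.  The square-root branch of det(X_t) is tracked
    continuously along the time grid, which keeps the phase of C(t) smooth
    through the zeros crossed by det(Q_t).
    """
    wp0 = record.initial if initial is None else initial
    if wp0.dim != record.dim:
        raise ValueError("initial packet dimension does not match the record")
    d = record.dim
    n = len(record)
    a0c = np.conj(wp0.P @ np.linalg.inv(wp0.Q))
    q0d = wp0.Q.conj().T
    p0d = wp0.P.conj().T

    dets = np.empty(n, complex)
    exponents = np.empty(n, complex)
    for k in range(n):
        qt, pt = record.q_matrices[k], record.p_matrices[k]
        x = 1j * (p0d @ qt - q0d @ pt)
        dets[k] = np.linalg.det(x)
        if abs(dets[k]) < 1e-300:
            raise np.linalg.LinAlgError(
                f"singular combined width matrix at step {k}"
            )
        at = pt @ np.linalg.inv(qt)
        m = 1j * (a0c - at)
        qk, pk = record.positions[k], record.momenta[k]
        b = 1j * (a0c @ wp0.q - at @ qk + pk - wp0.p)
        c = 1j * (
            -0.5 * wp0.q @ a0c @ wp0.q
            + 0.5 * qk @ at @ qk
            + wp0.p @ wp0.q
            - pk @ qk
            + record.actions[k]
            - wp0.action
        )
        exponents[k] = 0.5 * b @ np.linalg.solve(m, b) + c

    # continuous branch of det^(-1/2)
    phase = np.unwrap(np.angle(dets))
    det_inv_sqrt = np.abs(dets) ** -0.5 * np.exp(-0.5j * phase)
    values = 2.0 ** (d / 2) * det_inv_sqrt * np.exp(exponents)
    return Autocorrelation(record.times, values)


@dataclass(frozen=True)
class ModeActivation:
    """Per-mode center trajectories q_j(t) and their dominant frequencies."""

    times: np.ndarray
    series: np.ndarray  # (n_snapshots, D)
    dominant_frequencies: np.ndarray  # a.u., one per mode; 0 for flat modes

    @property
    def dominant_frequencies_cm1(self) -> np.ndarray:
        return self.dominant_frequencies * INV_CM_PER_HARTREE


def mode_activation(
    record: TrajectoryRecord, *, pad_factor: int = 8, flat_tol: float = 1e-10
) -> ModeActivation:
    """Extract normal-mode activation from a trajectory.

    Returns each mode's center coordinate q_j(t) and its dominant
    oscillation frequency, located from the peak of the zero-padded discrete
    Fourier transform of the Hann-windowed, mean-subtracted series (refined
    by quadratic interpolation; the window suppresses the leakage bias of a
    non-integer number of periods).  Modes whose excursion never exceeds
    ``flat_tol`` are reported with frequency 0.
    """
    if len(record) < 2:
        raise ValueError("trajectory record is empty")
    series = record.positions
    n = series.shape[0]
    n_pad = 1 << int(np.ceil(np.log2(max(pad_factor, 1) * n)))
    freqs = 2.0 * np.pi * np.fft.rfftfreq(n_pad, d=record.dt)
    hann = np.hanning(n)
    dominant = np.zeros(record.dim)
    for j in range(record.dim):
        y = series[:, j] - series[:, j].mean()
        if np.abs(y).max() < flat_tol:
            continue
        amp = np.abs(np.fft.rfft(y * hann, n=n_pad))
        k = int(np.argmax(amp[1:])) + 1  # exclude DC
        if 0 < k < amp.size - 1:
            denom = amp[k - 1] - 2 * amp[k] + amp[k + 1]
            delta = 0.5 * (amp[k - 1] - amp[k + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        dominant[j] = freqs[k] + delta * (freqs[1] - freqs[0])
    return ModeActivation(record.times, series, dominant)
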