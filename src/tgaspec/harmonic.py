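"""Global harmonic models, Duschinsky rotation, and 1D Franck-Condon spectra.

Two global quadratic expansions of an excited-state surface are standard:
the adiabatic harmonic (AH) model, expanded about the excited-state
equilibrium geometry, and the vertical harmonic (VH) model, expanded about
the Franck-Condon point (the ground-state equilibrium).  Either costs a
single Hessian evaluation of the true surface.

For one-dimensional displaced (and optionally distorted, k_e != k_g)
harmonic-oscillator pairs, the Franck-Condon intensities are available in
closed form: a Poisson distribution exp(-S) S^n / n! in the Huang-Rhys
parameter S for the displaced-only case, and a stable Hermite-type
recursion for the general displaced + squeezed overlap <n_e|0_g>.
Multidimensional harmonic spectra are obtained through the time-dependent
(thawed Gaussian) route, which is exact on quadratic surfaces, rather than
through explicit Duschinsky-rotated FC sums.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import molgeom
from .potentials import PotentialSurface, QuadraticPotential
from .spectra import PeakTable, SpectrumResult
from .constants import INV_CM_PER_HARTREE

__all__ = [
    "GlobalHarmonicModel",
    "DuschinskyTransform",
    "DisplacedOscillatorModel",
    "build_harmonic_model",
    "duschinsky",
    "huang_rhys",
    "fc_poisson",
    "fc_distorted_1d",
    "fc_profile_1d",
    "stick_spectrum_1d",
]


@dataclass(frozen=True)
class GlobalHarmonicModel:
    """Quadratic PES expansion V = e_ref + v.x + x.K.x/2, x = q - q_ref."""

    q_ref: np.ndarray
    e_ref: float
    gradient: np.ndarray
    hessian: np.ndarray
    flavor: str  # "adiabatic" | "vertical"

    def __post_init__(self) -> None:
        object.__setattr__(self, "q_ref", np.atleast_1d(np.asarray(self.q_ref, float)))
        object.__setattr__(self, "gradient", np.atleast_1d(np.asarray(self.gradient, float)))
        object.__setattr__(self, "hessian", np.atleast_2d(np.asarray(self.hessian, float)))
        if self.flavor not in ("adiabatic", "vertical"):
            raise ValueError("flavor must be 'adiabatic' or 'vertical'")

    def as_surface(self) -> QuadraticPotential:
        return QuadraticPotential(self.q_ref, self.e_ref, self.gradient, self.hessian)

    def evaluate(self, point):
        return self.as_surface().evaluate(point)


def _point_of(obj) -> np.ndarray:
    if isinstance(obj, molgeom.AtomicSystem):
        return obj.coords
    return np.atleast_1d(np.asarray(obj, float))


def build_harmonic_model(
    surface: PotentialSurface,
    flavor: str,
    ground_equilibrium,
    excited_equilibrium,
    *,
    strict: bool = True,
    gradient_tol: float = 1e-6,
) -> GlobalHarmonicModel:
    """Construct a global harmonic model with a single surface evaluation.

    ``flavor = "adiabatic"`` expands about the excited-state equilibrium;
    ``"vertical"`` expands about the ground-state equilibrium (Franck-Condon
    point).  For the adiabatic flavor the reference must be a stationary
    point of the surface: a non-negligible gradient raises in strict mode
    and warns otherwise.
    """
    if flavor not in ("adiabatic", "vertical"):
        raise ValueError("flavor must be 'adiabatic' or 'vertical'")
    ref = _point_of(excited_equilibrium if flavor == "adiabatic" else ground_equilibrium)
    v, g, h = surface.evaluate(ref)  # the single Hessian call
    if flavor == "adiabatic" and np.linalg.norm(g) > gradient_tol:
        msg = (
            f"adiabatic model requested at a point with |gradient| = "
            f"{np.linalg.norm(g):.3e} > {gradient_tol:.1e}"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return GlobalHarmonicModel(ref, v, g, 0.5 * (h + h.T), flavor)


@dataclass(frozen=True)
class DuschinskyTransform:
    """Linear relation between two electronic states' normal modes.

    ``matrix`` (J) maps ground-state to excited-state mode coordinates up to
    the ``displacement`` between the two minima expressed in the excited
    frame.  When no modes are truncated J is orthogonal, |det J| = 1.
    """

    matrix: np.ndarray
    displacement: np.ndarray


def duschinsky(
    basis_g: molgeom.NormalModeBasis, basis_e: molgeom.NormalModeBasis
) -> DuschinskyTransform:
    j, disp = molgeom.duschinsky_matrix(basis_g, basis_e)
    return DuschinskyTransform(j, disp)


@dataclass(frozen=True)
class DisplacedOscillatorModel:
    """A pair of 1D harmonic surfaces displaced by dq and offset by dE.

    ``k_g``/``k_e`` are ground/excited force constants, ``mu`` the reduced
    mass (all atomic units).  The derived frequencies are
    omega = sqrt(k / mu); for k_g = k_e the Franck-Condon intensities follow
    a Poisson distribution in the Huang-Rhys parameter S.
    """

    k_g: float
    k_e: float
    mu: float
    dq: float
    de: float = 0.0

    def __post_init__(self) -> None:
        if self.k_g <= 0 or self.k_e <= 0 or self.mu <= 0:
            raise ValueError("force constants and reduced mass must be positive")

    @property
    def omega_g(self) -> float:
        return math.sqrt(self.k_g / self.mu)

    @property
    def omega_e(self) -> float:
        return math.sqrt(self.k_e / self.mu)

    @property
    def distorted(self) -> bool:
        return not math.isclose(self.k_g, self.k_e, rel_tol=1e-12)


def huang_rhys(model: DisplacedOscillatorModel) -> float:
    """Huang-Rhys parameter S = sqrt(mu k) dq^2 / (2 hbar).

    Defined for the displaced-only model (k_g = k_e); S is dimensionless,
    zero iff the displacement vanishes, and scales as sqrt(mu) at fixed k
    and dq.
    """
    if model.distorted:
        raise ValueError("Huang-Rhys parameter requires k_g = k_e")
    return math.sqrt(model.mu * model.k_g) * model.dq**2 / 2.0


def fc_poisson(s: float, n: int) -> float:
    """Poisson Franck-Condon factor exp(-S) S^n / n! of a displaced oscillator."""
    if s < 0:
        raise ValueError("Huang-Rhys parameter must be nonnegative")
    if n < 0 or n != int(n):
        raise ValueError("vibrational quantum number must be a nonnegative integer")
    if s == 0:
        return 1.0 if n == 0 else 0.0
    return math.exp(-s + n * math.log(s) - math.lgamma(n + 1))


def fc_profile_1d(model: DisplacedOscillatorModel, n_max: int) -> np.ndarray:
    """|<n_e|0_g>|^2 for n = 0..n_max of a displaced + distorted pair.

    Uses a numerically stable recursion for the overlap of the ground-state
    Gaussian (exponent alpha = mu omega_g) with the excited-state Hermite
    functions (exponent beta = mu omega_e) displaced by dq:

        K_0 = sqrt(2 pi / (alpha + beta)),
        K_{n+1} = 2 c0 K_n + 2 n (beta - alpha)/(alpha + beta) K_{n-1},
        c0 = -sqrt(beta) alpha dq / (alpha + beta),

    and I_n = (alpha beta / pi^2)^(1/4) (2^n n!)^(-1/2)
              exp(-alpha beta dq^2 / (2 (alpha+beta))) K_n.

    For k_e = k_g this reduces exactly to the Poisson distribution; for
    dq = 0 the odd-n factors vanish by parity.
    """
    if n_max < 0:
        raise ValueError("n_max must be nonnegative")
    alpha = model.mu * model.omega_g
    beta = model.mu * model.omega_e
    s = alpha + beta
    c0 = -math.sqrt(beta) * alpha * model.dq / s
    k = np.zeros(n_max + 2)
    k[0] = math.sqrt(2.0 * math.pi / s)
    if n_max >= 0:
        k[1] = 2.0 * c0 * k[0]
    for n in range(1, n_max + 1):
        k[n + 1] = 2.0 * c0 * k[n] + 2.0 * n * (beta - alpha) / s * k[n - 1]
    pref = (alpha * beta) ** 0.25 / math.sqrt(math.pi)
    expo = math.exp(-alpha * beta * model.dq**2 / (2.0 * s))
    out = np.empty(n_max + 1)
    log2fact = 0.0
    for n in range(n_max + 1):
        if n > 0:
            log2fact += math.log(2.0 * n)
        amp = pref * expo * k[n] * math.exp(-0.5 * log2fact)
        out[n] = amp * amp
    return out


def fc_distorted_1d(model: DisplacedOscillatorModel, n: int) -> float:
    """Closed-form displaced + squeezed Franck-Condon factor |<n_e|0_g>|^2."""
    if n < 0 or n != int(n):
        raise ValueError("vibrational quantum number must be a nonnegative integer")
    return float(fc_profile_1d(model, int(n))[int(n)])


def stick_spectrum_1d(model: DisplacedOscillatorModel, n_max: int) -> SpectrumResult:
    """Time-independent stick spectrum of the 1D model.

    Sticks sit at the transition energies

        E_n = dE + (n + 1/2) omega_e - (1/2) omega_g        (hartree),

    reported in cm^-1, with Poisson intensities in the displaced-only case
    and the displaced + distorted closed form otherwise.  Intensities are
    returned unnormalized FC factors (they sum to 1 as n_max -> inf).

    For k_e = k_g the 0-0 position dE + (omega_e - omega_g)/2 = dE is
    independent of the reduced mass; only the distorted model moves it.
    """
    if n_max < 0:
        raise ValueError("n_max must be nonnegative")
    n = np.arange(n_max + 1)
    positions_au = model.de + (n + 0.5) * model.omega_e - 0.5 * model.omega_g
    if model.distorted:
        intensities = fc_profile_1d(model, n_max)
    else:
        s = huang_rhys(model)
        intensities = np.array([fc_poisson(s, int(k)) for k in n])
    positions = positions_au * INV_CM_PER_HARTREE
    peaks = PeakTable(positions, intensities)
    return SpectrumResult(positions, intensities, kind="stick", peaks=peaks)
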