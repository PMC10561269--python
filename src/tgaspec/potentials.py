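"""Potential-energy-surface providers.

Every surface exposes a single evaluation contract, ``evaluate(point) ->
(value, gradient, Hessian)``, mirroring how on-the-fly electronic-structure
drivers feed local PES information to a propagator one point at a time.  The
analytic families here (multidimensional harmonic, Morse, and a coupled
two-mode anharmonic model with a quasi-bound Franck-Condon region) stand in
for ab initio surfaces while keeping derivatives exact.

Masses never enter any potential: isotopologues share the PES and differ
only through the mass-scaled coordinates in which the dynamics run
(:class:`MassScaledSurface`).
"""

from __future__ import annotations

import abc
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from scipy.optimize import minimize

from . import molgeom

__all__ = [
    "PotentialSurface",
    "QuadraticPotential",
    "HarmonicPotential",
    "MorsePotential",
    "CoupledAnharmonicPotential",
    "MassScaledSurface",
    "NormalModeSurface",
    "LocalQuadraticExpansion",
    "local_quadratic",
    "ModelSpec",
    "make_ammonia_like_model",
    "EvalCounter",
    "check_gradients",
    "DomainError",
    "ModelError",
]


class DomainError(ValueError):
    """Evaluation requested outside a surface's validity domain."""


class ModelError(ValueError):
    """Model parameters do not define a bound surface."""


class PotentialSurface(abc.ABC):
    """Abstract PES with a value/gradient/Hessian contract.

    ``coords`` documents which coordinates the surface expects:
    ``"cartesian"`` (bohr), ``"normal"`` (mass-scaled normal modes, unit
    mass), or ``"internal"`` (model coordinates with explicit masses handled
    by a :class:`MassScaledSurface` wrapper).
    """

    ndim: int
    coords: str = "internal"

    @abc.abstractmethod
    def evaluate(self, point) -> tuple[float, np.ndarray, np.ndarray]:
        """Return (V in hartree, gradient, symmetric Hessian) at ``point``."""

    def value(self, point) -> float:
        return self.evaluate(point)[0]

    def _as_point(self, point) -> np.ndarray:
        p = np.atleast_1d(np.asarray(point, dtype=float))
        if p.shape != (self.ndim,):
            raise ValueError(f"expected a point of dimension {self.ndim}, got {p.shape}")
        return p


class QuadraticPotential(PotentialSurface):
    """General quadratic PES  V = e0 + v.x + x.K.x/2  with x = q - q_ref."""

    def __init__(self, ref, e0, grad, hess, coords: str = "internal"):
        self.ref = np.atleast_1d(np.asarray(ref, float))
        self.ndim = self.ref.size
        self.e0 = float(e0)
        self.grad = np.atleast_1d(np.asarray(grad, float))
        self.hess = np.atleast_2d(np.asarray(hess, float))
        self.coords = coords
        if self.grad.shape != (self.ndim,) or self.hess.shape != (self.ndim, self.ndim):
            raise ValueError("gradient/Hessian shapes inconsistent with reference point")
        if not np.allclose(self.hess, self.hess.T, atol=1e-10 * max(1.0, np.abs(self.hess).max())):
            raise ValueError("Hessian must be symmetric")

    def evaluate(self, point):
        x = self._as_point(point) - self.ref
        v = self.e0 + self.grad @ x + 0.5 * x @ self.hess @ x
        return float(v), self.grad + self.hess @ x, self.hess.copy()


class HarmonicPotential(QuadraticPotential):
    """Separable harmonic oscillator in mass-scaled coordinates.

    ``omegas`` are mode frequencies (a.u.); the Hessian is diag(omega^2).
    """

    def __init__(self, omegas, minimum=None, e0: float = 0.0, coords: str = "normal"):
        omegas = np.atleast_1d(np.asarray(omegas, float))
        minimum = np.zeros_like(omegas) if minimum is None else minimum
        super().__init__(minimum, e0, np.zeros_like(omegas), np.diag(omegas**2), coords)
        self.omegas = omegas


class MorsePotential(PotentialSurface):
    """One-dimensional Morse oscillator  V = De (1 - exp(-a (r - re)))^2 + e0.

    ``r_min`` (default 0 when ``r_e`` > 0, else no bound) guards against
    evaluation at unphysical radial coordinates.  The harmonic frequency in
    mass-scaled coordinates (unit mass) is  omega = a sqrt(2 De).
    """

    ndim = 1

    def __init__(self, de, a, r_e=0.0, e0=0.0, r_min=None, coords: str = "internal"):
        if de <= 0 or a <= 0:
            raise ModelError("Morse requires De > 0 and a > 0")
        self.de, self.a, self.r_e, self.e0 = float(de), float(a), float(r_e), float(e0)
        self.r_min = (0.0 if r_e > 0 else None) if r_min is None else r_min
        self.coords = coords

    @property
    def omega(self) -> float:
        return self.a * np.sqrt(2.0 * self.de)

    def evaluate(self, point):
        r = float(self._as_point(point)[0])
        if self.r_min is not None and r <= self.r_min:
            raise DomainError(f"Morse evaluated at r = {r} <= {self.r_min}")
        u = np.exp(-self.a * (r - self.r_e))
        v = self.de * (1.0 - u) ** 2 + self.e0
        g = 2.0 * self.de * self.a * u * (1.0 - u)
        h = 2.0 * self.de * self.a**2 * u * (2.0 * u - 1.0)
        return float(v), np.array([g]), np.array([[h]])


class CoupledAnharmonicPotential(PotentialSurface):
    """Bound two-mode anharmonic model: Morse stretch + quartic bend + bilinear coupling.

    V(x) = De (1 - e^(-a x1))^2 + k_bend x2^2 / 2 + beta x2^4 + c x1 x2 + e0

    with x = (stretch, bend) internal displacements from the minimum at the
    origin.  The model emulates an excited state that is quasi-bound in the
    Franck-Condon region: the wavepacket launched from a displaced ground
    minimum oscillates in a bound anharmonic well for the whole propagation.
    Boundness requires c^2 < 2 De a^2 k_bend and beta >= 0.
    """

    ndim = 2

    def __init__(self, de, a, k_bend, quartic=0.0, coupling=0.0, e0=0.0):
        if de <= 0 or a <= 0 or k_bend <= 0:
            raise ModelError("require De, a, k_bend > 0")
        if quartic < 0:
            raise ModelError("negative quartic term makes the bend unbound")
        if coupling**2 >= 2.0 * de * a**2 * k_bend:
            raise ModelError(
                "bilinear coupling too strong: c^2 must be < 2 De a^2 k_bend"
            )
        self.de, self.a = float(de), float(a)
        self.k_bend, self.quartic, self.coupling = float(k_bend), float(quartic), float(coupling)
        self.e0 = float(e0)
        self.coords = "internal"

    def evaluate(self, point):
        x1, x2 = self._as_point(point)
        u = np.exp(-self.a * x1)
        v = (
            self.de * (1.0 - u) ** 2
            + 0.5 * self.k_bend * x2**2
            + self.quartic * x2**4
            + self.coupling * x1 * x2
            + self.e0
        )
        g = np.array(
            [
                2.0 * self.de * self.a * u * (1.0 - u) + self.coupling * x2,
                self.k_bend * x2 + 4.0 * self.quartic * x2**3 + self.coupling * x1,
            ]
        )
        h = np.array(
            [
                [2.0 * self.de * self.a**2 * u * (2.0 * u - 1.0), self.coupling],
                [self.coupling, self.k_bend + 12.0 * self.quartic * x2**2],
            ]
        )
        return float(v), g, h


class MassScaledSurface(PotentialSurface):
    """Express an internal-coordinate surface in mass-scaled coordinates.

    With per-coordinate effective masses mu_i, the mass-scaled coordinates
    are q_i = sqrt(mu_i) x_i so the kinetic energy takes unit-mass form, as
    the propagator assumes.  The potential value is mass-independent; only
    the coordinate scaling (and hence gradient and Hessian) changes between
    isotopologues.
    """

    coords = "normal"

    def __init__(self, inner: PotentialSurface, masses):
        self.inner = inner
        self.masses = np.atleast_1d(np.asarray(masses, float))
        if self.masses.shape != (inner.ndim,) or np.any(self.masses <= 0):
            raise ValueError("need one positive mass per coordinate")
        self.ndim = inner.ndim
        self._s = np.sqrt(self.masses)

    def evaluate(self, point):
        q = self._as_point(point)
        v, g, h = self.inner.evaluate(q / self._s)
        return v, g / self._s, h / np.outer(self._s, self._s)


class NormalModeSurface(PotentialSurface):
    """A Cartesian surface viewed through a vibrational normal-mode basis.

    Evaluation maps q -> geometry via the basis, calls the Cartesian surface,
    and chain-rules the derivatives back.  This is the adapter that lets the
    propagator (which works in mass-scaled normal modes) run on a molecular
    PES, exactly as an on-the-fly driver would.
    """

    coords = "normal"

    def __init__(self, cart_surface: PotentialSurface, basis: molgeom.NormalModeBasis):
        if cart_surface.coords != "cartesian":
            raise ValueError("inner surface must take Cartesian coordinates")
        self.cart_surface = cart_surface
        self.basis = basis
        self.ndim = basis.n_modes

    def evaluate(self, point):
        q = self._as_point(point)
        system = molgeom.nm_to_cart(q, self.basis)
        v, g, h = self.cart_surface.evaluate(system.coords)
        g_q, h_q = molgeom.transform_derivatives(g, h, self.basis)
        return v, g_q, h_q


@dataclass(frozen=True)
class LocalQuadraticExpansion:
    """Second-order Taylor expansion of a surface about a point q_t.

    Evaluating the expansion at its own center returns the stored value
    exactly; away from the center the error is O(|x|^3) on a smooth surface.
    """

    center: np.ndarray
    value: float
    gradient: np.ndarray
    hessian: np.ndarray

    def evaluate(self, point) -> tuple[float, np.ndarray, np.ndarray]:
        x = np.atleast_1d(np.asarray(point, float)) - self.center
        if np.all(x == 0):
            return self.value, self.gradient.copy(), self.hessian.copy()
        v = self.value + self.gradient @ x + 0.5 * x @ self.hessian @ x
        return float(v), self.gradient + self.hessian @ x, self.hessian.copy()

    def as_surface(self) -> QuadraticPotential:
        return QuadraticPotential(self.center, self.value, self.gradient, self.hessian)


def local_quadratic(surface: PotentialSurface, q_t) -> LocalQuadraticExpansion:
    """Local harmonic approximation of ``surface`` about ``q_t``."""
    q_t = np.atleast_1d(np.asarray(q_t, float))
    v, g, h = surface.evaluate(q_t)
    return LocalQuadraticExpansion(q_t.copy(), v, g, 0.5 * (h + h.T))


# ---------------------------------------------------------------------------
# Model specification / construction

_FAMILIES = ("harmonic", "morse", "coupled_anharmonic")


@dataclass
class ModelSpec:
    """Serializable description of an analytic model surface.

    ``family`` is one of ``harmonic | morse | coupled_anharmonic``; ``params``
    feed the corresponding constructor.  ``seed`` is stored for generated
    instances so a spec fully determines its surface.
    """

    family: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ModelError(f"unknown model family {self.family!r}; one of {_FAMILIES}")

    def build(self) -> PotentialSurface:
        if self.family == "harmonic":
            return HarmonicPotential(**self.params)
        if self.family == "morse":
            return MorsePotential(**self.params)
        return make_ammonia_like_model(self)

    @classmethod
    def random_coupled(cls, seed: int) -> "ModelSpec":
        """Draw a bound coupled-anharmonic spec reproducibly from a seed."""
        rng = np.random.default_rng(seed)
        de = rng.uniform(0.1, 0.25)
        a = rng.uniform(0.4, 0.8)
        k_bend = rng.uniform(0.05, 0.12)
        cmax = np.sqrt(2.0 * de * a**2 * k_bend)
        coupling = rng.uniform(-0.3, 0.3) * cmax
        quartic = rng.uniform(0.0, 5e-4)
        return cls(
            "coupled_anharmonic",
            {
                "de": float(de),
                "a": float(a),
                "k_bend": float(k_bend),
                "quartic": float(quartic),
                "coupling": float(coupling),
                "e0": 0.0,
            },
            seed=seed,
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(d["family"], dict(d.get("params", {})), d.get("seed"))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def make_ammonia_like_model(spec: ModelSpec) -> CoupledAnharmonicPotential:
    """Build the coupled two-mode anharmonic model and verify its minimum.

    The stated minimum (the origin) is checked by a local optimization: the
    located stationary point must coincide with the origin to 1e-8 and have a
    gradient norm below 1e-10; otherwise the parameters are rejected.
    """
    if spec.family != "coupled_anharmonic":
        raise ModelError("make_ammonia_like_model requires family 'coupled_anharmonic'")
    surface = CoupledAnharmonicPotential(**spec.params)
    res = minimize(
        lambda x: surface.evaluate(x)[0],
        x0=np.zeros(2),
        jac=lambda x: surface.evaluate(x)[1],
        method="BFGS",
        options={"gtol": 1e-12},
    )
    if np.linalg.norm(res.x) > 1e-8 or np.linalg.norm(surface.evaluate(res.x)[1]) > 1e-10:
        raise ModelError("surface minimum does not sit at the stated origin")
    return surface


# ---------------------------------------------------------------------------
# Instrumentation / verification helpers

class EvalCounter(PotentialSurface):
    """Pass-through wrapper counting surface evaluations (PES-call budget)."""

    def __init__(self, inner: PotentialSurface):
        self.inner = inner
        self.ndim = inner.ndim
        self.coords = inner.coords
        self.n_calls = 0

    def evaluate(self, point):
        self.n_calls += 1
        return self.inner.evaluate(point)


def check_gradients(
    surface: PotentialSurface, point, *, step: float = 1e-5
) -> tuple[float, float]:
    """Max abs errors of analytic gradient/Hessian vs central finite differences."""
    point = np.atleast_1d(np.asarray(point, float))
    _, g, h = surface.evaluate(point)
    d = point.size
    g_fd = np.empty(d)
    h_fd = np.empty((d, d))
    for i in range(d):
        e = np.zeros(d)
        e[i] = step
        vp = surface.evaluate(point + e)[0]
        vm = surface.evaluate(point - e)[0]
        g_fd[i] = (vp - vm) / (2 * step)
        gp = surface.evaluate(point + e)[1]
        gm = surface.evaluate(point - e)[1]
        h_fd[i] = (gp - gm) / (2 * step)
    return float(np.abs(g - g_fd).max()), float(np.abs(h - 0.5 * (h_fd + h_fd.T)).max())
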