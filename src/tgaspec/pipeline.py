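"""End-to-end driver: configuration, pipeline stages, and the isotopologue demo.

The pipeline chains geometry/initial-state preparation, optional global
harmonic construction, thawed-Gaussian propagation, autocorrelation,
spectrum synthesis, and the isotope-effect analysis, writing all artifacts
plus a machine-readable manifest.  Runs are deterministic for a fixed
configuration and seed.

The bundled demo emulates the physics of an XH3-type absorption band on a
two-mode model: a Morse-like symmetric stretch coupled to an anharmonic
symmetric-bend (umbrella) coordinate, propagated for four mass patterns
(all-light, two mixed, all-heavy) that mimic progressive deuteration.  The
masses enter only through the mass-scaled coordinates; the internal-
coordinate surface is shared by all patterns, exactly as a Born-Oppenheimer
PES is shared by isotopologues.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import molgeom, tga
from .constants import INV_CM_PER_HARTREE, ME_PER_AMU
from .potentials import (
    MassScaledSurface,
    ModelSpec,
    NormalModeSurface,
    QuadraticPotential,
)
from .spectra import (
    correlation_to_spectrum,
    envelope_width,
    find_peaks,
    mean_peak_spacing,
    mime_wavenumber,
    peak_spacing_shifts,
)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "demo_isotopologues", "DEMO_MODEL"]

logger = logging.getLogger("tgaspec")


class ConfigError(ValueError):
    """Invalid run configuration."""


# ---------------------------------------------------------------------------
# Bundled demo model (parameters in atomic units unless suffixed)

_M_H = 1.00782503207  # amu
_M_D = 2.01410177785
_M_N = 14.0030740048

#: Excited-state two-mode model: Morse stretch + quartic bend + bilinear
#: coupling.  Parameters chosen so the all-light pattern has a ~930 cm^-1
#: bend progression and a stretch at about twice that frequency, with an
#: electronic offset near the XH3 first absorption band.
DEMO_MODEL = ModelSpec(
    "coupled_anharmonic",
    {
        "de": 0.18,          # hartree
        "a": 0.58472,        # 1/bohr
        "k_bend": 0.081370,  # hartree/bohr^2
        "quartic": 2.0e-4,   # hartree/bohr^4
        "coupling": 5.0e-3,  # hartree/bohr^2
        "e0": 0.21,          # vertical electronic offset, hartree
    },
)

#: Ground-state harmonic fit in the same internal coordinates: force
#: constants chosen to give ~3337 cm^-1 (stretch) and ~950 cm^-1 (bend)
#: for the all-light pattern, with the ground minimum displaced mostly
#: along the bend (pyramidalization) and slightly along the stretch.
DEMO_GROUND = {
    "minimum": [-0.05, -0.55],          # bohr, relative to excited minimum
    "hessian": [[0.39627, 0.0], [0.0, 0.084911]],
}

#: Per-pattern Lorentzian HWHM (cm^-1), phenomenological peak widths.
DEMO_HWHM = [170.0, 137.0, 95.0, 110.0]

DEMO_LABELS = ["all_light", "mixed_1", "mixed_2", "all_heavy"]


def demo_masses_amu(n_heavy: int) -> tuple[float, float]:
    """Effective (stretch, bend) reduced masses for n_heavy substitutions.

    Models an XH3 unit with n_heavy of the three light atoms replaced by the
    double-mass isotope: the symmetric-stretch reduced mass is m X / (m + X)
    and the umbrella reduced mass 3 m X / (3 m + X) with m the mean light
    mass.
    """
    if not 0 <= n_heavy <= 3:
        raise ValueError("n_heavy must be 0..3")
    m = ((3 - n_heavy) * _M_H + n_heavy * _M_D) / 3.0
    mu_s = m * _M_N / (m + _M_N)
    mu_b = 3.0 * m * _M_N / (3.0 * m + _M_N)
    return mu_s, mu_b


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Validated configuration for :func:`run_pipeline`.

    Keys carry explicit unit suffixes (``dt_au``, ``hwhm_cm1``) to keep unit
    bookkeeping at the I/O boundary.  ``mode`` selects the model-space route
    (analytic surface + effective masses) or the molecular route (XYZ
    geometries + Cartesian Hessian files, propagated on a global harmonic
    model in normal-mode coordinates).
    """

    out_dir: Path
    mode: str = "model"
    dt_au: float = 8.0
    n_steps: int = 1000
    hwhm_cm1: float | None = 170.0
    shift_cm1: float = 0.0
    min_rel_intensity: float = 0.05
    seed: int = 0
    log_level: str = "INFO"
    # model mode
    surface: ModelSpec | None = None
    masses_amu: list[float] | None = None
    ground_minimum: list[float] | None = None
    ground_hessian: list[list[float]] | None = None
    # molecular mode
    geometry: Path | None = None
    excited_geometry: Path | None = None
    ground_hessian_file: Path | None = None
    excited_hessian_file: Path | None = None
    excited_gradient_file: Path | None = None
    flavor: str = "adiabatic"
    coords: str = "excited"
    isotopes: dict[int, str] = field(default_factory=dict)
    excitation_energy_hartree: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        base = Path(path).parent
        mode = raw.get("mode", "model")
        kwargs: dict[str, Any] = {
            "out_dir": Path(raw.get("out_dir", "tgaspec_out")),
            "mode": mode,
            "dt_au": float(raw.get("dt_au", 8.0)),
            "n_steps": int(raw.get("n_steps", 1000)),
            "shift_cm1": float(raw.get("shift_cm1", 0.0)),
            "min_rel_intensity": float(raw.get("min_rel_intensity", 0.05)),
            "seed": int(raw.get("seed", 0)),
            "log_level": str(raw.get("log_level", "INFO")),
            "coords": raw.get("coords", "excited"),
            "flavor": raw.get("flavor", "adiabatic"),
            "excitation_energy_hartree": float(raw.get("excitation_energy_hartree", 0.0)),
        }
        hwhm = raw.get("hwhm_cm1", 170.0)
        kwargs["hwhm_cm1"] = None if hwhm in (None, "none") else float(hwhm)
        if mode == "model":
            surf = raw.get("surface")
            if isinstance(surf, str):
                kwargs["surface"] = ModelSpec.from_yaml(base / surf)
            elif isinstance(surf, dict):
                kwargs["surface"] = ModelSpec.from_dict(surf)
            ground = raw.get("ground", {})
            kwargs["masses_amu"] = raw.get("masses_amu")
            kwargs["ground_minimum"] = ground.get("minimum")
            kwargs["ground_hessian"] = ground.get("hessian")
        elif mode == "molecular":
            for key, target in [
                ("geometry", "geometry"),
                ("excited_geometry", "excited_geometry"),
                ("ground_hessian", "ground_hessian_file"),
                ("excited_hessian", "excited_hessian_file"),
                ("excited_gradient", "excited_gradient_file"),
            ]:
                if raw.get(key) is not None:
                    kwargs[target] = base / raw[key]
            kwargs["isotopes"] = {
                int(k): str(v) for k, v in (raw.get("isotopes") or {}).items()
            }
        else:
            raise ConfigError(f"unknown mode {mode!r}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.dt_au <= 0:
            raise ConfigError("dt_au must be positive")
        if self.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")
        if self.hwhm_cm1 is not None and self.hwhm_cm1 <= 0:
            raise ConfigError("hwhm_cm1 must be positive (or none)")
        if self.coords not in ("excited", "ground"):
            raise ConfigError("coords must be 'excited' or 'ground'")
        if self.mode == "model":
            if self.surface is None:
                raise ConfigError("model mode requires a surface spec")
            for name in ("masses_amu", "ground_minimum", "ground_hessian"):
                if getattr(self, name) is None:
                    raise ConfigError(f"model mode requires {name}")
        elif self.mode == "molecular":
            for name in (
                "geometry",
                "excited_geometry",
                "ground_hessian_file",
                "excited_hessian_file",
            ):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"molecular mode requires {name}")
                if not Path(path).exists():
                    raise ConfigError(f"{name} does not exist: {path}")
            if self.flavor not in ("adiabatic", "vertical"):
                raise ConfigError("flavor must be 'adiabatic' or 'vertical'")
        else:
            raise ConfigError(f"unknown mode {self.mode!r}")

    def echo(self) -> dict:
        d: dict[str, Any] = {
            "mode": self.mode,
            "dt_au": self.dt_au,
            "n_steps": self.n_steps,
            "hwhm_cm1": self.hwhm_cm1,
            "shift_cm1": self.shift_cm1,
            "min_rel_intensity": self.min_rel_intensity,
            "seed": self.seed,
            "coords": self.coords,
        }
        if self.mode == "model":
            d.update(
                surface=self.surface.to_dict(),
                masses_amu=list(self.masses_amu),
                ground={"minimum": list(self.ground_minimum), "hessian": self.ground_hessian},
            )
        else:
            d.update(
                geometry=str(self.geometry),
                excited_geometry=str(self.excited_geometry),
                flavor=self.flavor,
                isotopes=self.isotopes,
                excitation_energy_hartree=self.excitation_energy_hartree,
            )
        return d


# ---------------------------------------------------------------------------
# Pipeline

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _single_run(
    surface,
    q0: np.ndarray,
    kappa_ground: np.ndarray,
    zpe_au: float,
    config: RunConfig,
):
    """Shared propagate -> correlate -> transform -> analyze stage chain."""
    wp0 = tga.ground_state_wavepacket(kappa_ground, q0)

    def monitor(step, t, q, p):
        if step % 100 == 0:
            v = surface.evaluate(q)[0]
            logger.info(
                "step %5d  t=%9.1f au  E=%.10f  |q|=%.4f", step, t, 0.5 * p @ p + v, np.linalg.norm(q)
            )

    record = tga.propagate(
        wp0, surface, config.dt_au, config.n_steps,
        callback=monitor if logger.isEnabledFor(logging.INFO) else None,
    )
    corr = tga.autocorrelation(record)
    spectrum = correlation_to_spectrum(
        corr, config.hwhm_cm1, config.shift_cm1, zpe_au=zpe_au
    )
    peaks = find_peaks(spectrum, config.min_rel_intensity)
    return record, corr, spectrum, peaks


def _model_stage(config: RunConfig):
    masses_me = np.asarray(config.masses_amu, float) * ME_PER_AMU
    inner = config.surface.build()
    if inner.ndim != masses_me.size:
        raise ConfigError("masses_amu length must match the surface dimension")
    surface = MassScaledSurface(inner, masses_me)
    x0 = np.asarray(config.ground_minimum, float)
    q0 = np.sqrt(masses_me) * x0
    k_int = np.asarray(config.ground_hessian, float)
    kappa = k_int / np.sqrt(np.outer(masses_me, masses_me))
    zpe = 0.5 * np.sum(np.sqrt(np.clip(np.linalg.eigvalsh(kappa), 0, None)))
    return surface, q0, kappa, zpe


def _molecular_stage(config: RunConfig):
    """Global harmonic molecular route.

    The excited Hessian file is taken at the flavor's reference geometry
    (excited equilibrium for the adiabatic flavor, Franck-Condon point for
    the vertical one); the excited surface is its quadratic expansion.  An
    optional gradient file supplies the non-stationary vertical expansion's
    linear term.
    """
    ground_sys = molgeom.read_xyz(config.geometry)
    excited_sys = molgeom.read_xyz(config.excited_geometry)
    if config.isotopes:
        ground_sys = molgeom.substitute_isotopes(ground_sys, config.isotopes)
        excited_sys = molgeom.substitute_isotopes(excited_sys, config.isotopes)
    h_g = np.asarray(json.loads(Path(config.ground_hessian_file).read_text())["hessian"])
    h_e = np.asarray(json.loads(Path(config.excited_hessian_file).read_text())["hessian"])
    g_e = np.zeros(3 * ground_sys.n_atoms)
    if config.excited_gradient_file is not None:
        g_e = np.asarray(
            json.loads(Path(config.excited_gradient_file).read_text())["gradient"], float
        )

    basis_g = molgeom.normal_mode_analysis(ground_sys, h_g)
    ref_sys = excited_sys if config.flavor == "adiabatic" else ground_sys
    basis_e = molgeom.normal_mode_analysis(ref_sys, h_e)
    basis = basis_e if config.coords == "excited" else basis_g

    cart_surface = QuadraticPotential(
        molgeom.shift_to_com(ref_sys).coords,
        config.excitation_energy_hartree,
        g_e,
        0.5 * (h_e + h_e.T),
        coords="cartesian",
    )
    surface = NormalModeSurface(cart_surface, basis)
    wp0 = tga.init_wavepacket(basis_g, basis, ground_sys)
    zpe = 0.5 * float(np.sum(basis_g.frequencies))
    return surface, wp0, zpe, basis, basis_g, basis_e


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured workflow and write all artifacts.

    Returns a result dictionary (also serialized as ``analysis.json``); the
    manifest records the config echo, package version, and SHA-256 checksums
    of every output, so repeated runs with the same config are byte-checkable.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "prepare"
    try:
        if config.mode == "model":
            surface, q0, kappa, zpe = _model_stage(config)
            stage = "propagate"
            record, corr, spectrum, peaks = _single_run(surface, q0, kappa, zpe, config)
        else:
            surface, wp0, zpe, basis, basis_g, basis_e = _molecular_stage(config)
            stage = "propagate"
            record = tga.propagate(wp0, surface, config.dt_au, config.n_steps)
            corr = tga.autocorrelation(record)
            spectrum = correlation_to_spectrum(
                corr, config.hwhm_cm1, config.shift_cm1, zpe_au=zpe
            )
            peaks = find_peaks(spectrum, config.min_rel_intensity)
            basis_e.to_json(out / "excited_modes.json")
            basis_g.to_json(out / "ground_modes.json")

        stage = "analyze"
        analysis = {
            "n_peaks": len(peaks),
            "peaks": peaks.to_dict(),
            "norm_drift": float(np.abs(record.norms() - 1.0).max()),
            "hagedorn_defect": float(record.hagedorn_defects().max()),
            "energy_drift": float(np.abs(record.energies - record.energies[0]).max()),
        }
        if len(peaks) >= 2:
            analysis["mean_peak_spacing_cm1"] = mean_peak_spacing(peaks)
            analysis["envelope_width_cm1"] = envelope_width(peaks)

        stage = "write"
        record.save(out / "trajectory.npz")
        corr.save_txt(out / "autocorrelation.txt")
        spectrum.save_txt(out / "spectrum.txt")
        spectrum.to_json(out / "spectrum.json", config.min_rel_intensity)
        (out / "analysis.json").write_text(json.dumps(analysis, indent=1))
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    from . import __version__

    manifest = {
        "version": __version__,
        "config": config.echo(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return analysis


# ---------------------------------------------------------------------------
# Isotopologue demo

def demo_isotopologues(
    seed: int = 0,
    out_dir: Path | None = None,
    *,
    dt_au: float = 8.0,
    n_steps: int = 1000,
    min_rel_intensity: float = 0.05,
) -> dict:
    """Run the bundled two-mode model for four mass patterns and analyze.

    Reproduces the isotope-effect workflow on the bundled surface: for each
    mass pattern the thawed Gaussian is launched from the (mass-scaled)
    ground-state minimum, propagated with the standard protocol (time step
    8 a.u., 1000 steps), transformed to a spectrum, and the analysis
    statistics computed: mean peak spacing, envelope width, per-peak shifts
    relative to the lightest pattern, and the MIME wavenumber from the
    excited-state mode frequencies and displacements.

    ``seed`` is recorded for provenance; the bundled model is deterministic.
    """
    inner = DEMO_MODEL.build()
    x0 = np.asarray(DEMO_GROUND["minimum"], float)
    k_int = np.asarray(DEMO_GROUND["hessian"], float)

    patterns = []
    for n_heavy, label, hwhm in zip(range(4), DEMO_LABELS, DEMO_HWHM):
        mu_s, mu_b = demo_masses_amu(n_heavy)
        masses_me = np.array([mu_s, mu_b]) * ME_PER_AMU
        s = np.sqrt(masses_me)
        surface = MassScaledSurface(inner, masses_me)

        kappa_g = k_int / np.outer(s, s)
        zpe = 0.5 * np.sum(np.sqrt(np.linalg.eigvalsh(kappa_g)))
        wp0 = tga.ground_state_wavepacket(kappa_g, s * x0)
        record = tga.propagate(wp0, surface, dt_au, n_steps)
        corr = tga.autocorrelation(record)
        # the coherent two-mode correlation has not decayed at Gamma T of a
        # few: apodize to keep truncation ringing out of the peak tables
        spectrum = correlation_to_spectrum(corr, hwhm, zpe_au=zpe, window="hann")
        peaks = find_peaks(spectrum, min_rel_intensity)

        # excited-state mode frequencies / displacements for the MIME input
        h_exc = surface.evaluate(np.zeros(2))[2]
        evals, evecs = np.linalg.eigh(h_exc)
        freqs_cm1 = np.sqrt(evals) * INV_CM_PER_HARTREE
        dq = evecs.T @ (s * x0)
        mime = mime_wavenumber(freqs_cm1, dq)
        activation = tga.mode_activation(record)

        patterns.append(
            {
                "label": label,
                "n_heavy": n_heavy,
                "mu_stretch_amu": mu_s,
                "mu_bend_amu": mu_b,
                "hwhm_cm1": hwhm,
                "mode_frequencies_cm1": freqs_cm1.tolist(),
                "mode_displacements": dq.tolist(),
                "dominant_mode_frequencies_cm1": activation.dominant_frequencies_cm1.tolist(),
                "n_peaks": len(peaks),
                "mean_peak_spacing_cm1": mean_peak_spacing(peaks),
                "envelope_width_cm1": envelope_width(peaks),
                "mime_wavenumber_cm1": mime.omega_m,
                "mime_integers": mime.integers.tolist(),
                "_spectrum": spectrum,
                "_peaks": peaks,
                "_record": record,
            }
        )

    reference = patterns[0]
    for pat in patterns:
        shifts = peak_spacing_shifts(pat["_spectrum"], reference["_spectrum"])
        pat["delta_omega_cm1"] = shifts.delta.tolist()

    report = {
        "seed": seed,
        "dt_au": dt_au,
        "n_steps": n_steps,
        "patterns": [
            {k: v for k, v in pat.items() if not k.startswith("_")} for pat in patterns
        ],
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pat in patterns:
            pat["_spectrum"].save_txt(out / f"spectrum_{pat['label']}.txt")
            pat["_spectrum"].to_json(out / f"spectrum_{pat['label']}.json", min_rel_intensity)
        table = pd.DataFrame(report["patterns"]).drop(
            columns=["mode_displacements", "delta_omega_cm1", "mime_integers"]
        )
        table.to_csv(out / "report.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=1))

    for pat in patterns:
        for key in ("_spectrum", "_peaks", "_record"):
            pat.pop(key)
    return report
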