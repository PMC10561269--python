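"""Spectrum synthesis and isotope-effect analysis statistics.

The time-dependent route to a vibronic absorption spectrum Fourier-transforms
the wavepacket autocorrelation function,

    sigma(omega)  propto  Re  int_0^inf  C(t) e^(i omega t) e^(-Gamma |t|) dt ,

where the exponential damping gives every line a Lorentzian profile of
half-width-at-half-maximum Gamma.  The analysis statistics operate on peak
tables extracted from such spectra: the intensity-weighted envelope width,
per-peak spacing shifts between isotopologues, the missing-mode-effect (MIME)
recurrence frequency, and the best-fit rigid shift against reference peaks.

All statistics are invariant under rigid spectral shifts and intensity
rescaling, which is what makes them meaningful observables independent of
the phenomenological broadening and of any overall energy offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.signal

from .constants import HARTREE_PER_INV_CM, INV_CM_PER_HARTREE

__all__ = [
    "Autocorrelation",
    "SpectrumResult",
    "PeakTable",
    "MimeResult",
    "correlation_to_spectrum",
    "find_peaks",
    "envelope_width",
    "mean_peak_spacing",
    "peak_spacing_shifts",
    "mime_wavenumber",
    "fit_spectral_shift",
]


@dataclass(frozen=True)
class Autocorrelation:
    """Wavepacket autocorrelation C(t) on a uniform time grid (a.u.)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "values", np.asarray(self.values, complex))
        if self.times.size != self.values.size or self.times.size < 2:
            raise ValueError("need matching time and value arrays of length >= 2")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-8):
            raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def save_txt(self, path) -> None:
        """Three-column text: t (a.u.), Re C, Im C."""
        data = np.column_stack([self.times, self.values.real, self.values.imag])
        np.savetxt(path, data, header="t_au  re_C  im_C")

    @classmethod
    def load_txt(cls, path) -> "Autocorrelation":
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1] + 1j * data[:, 2])


@dataclass(frozen=True)
class PeakTable:
    """Peak positions (cm^-1, ascending) and intensities."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, float))
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have matching shapes")

    def __len__(self) -> int:
        return self.positions.size

    def to_dict(self) -> dict:
        return {
            "positions_cm1": self.positions.tolist(),
            "intensities": self.intensities.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PeakTable":
        return cls(np.asarray(d["positions_cm1"]), np.asarray(d["intensities"]))


@dataclass(frozen=True)
class SpectrumResult:
    """A spectrum on a wavenumber grid, max intensity normalized to 1.

    ``kind`` distinguishes continuous (FT of a damped correlation) spectra
    from stick spectra, where the grid points *are* the line positions.
    ``shift_cm1`` records any rigid shift already applied to the grid.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    shift_cm1: float = 0.0
    kind: str = "continuous"
    peaks: PeakTable | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavenumbers", np.asarray(self.wavenumbers, float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, float))
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("grid and intensities must have matching shapes")

    def save_txt(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.wavenumbers, self.intensities]),
            header="wavenumber_cm1  intensity",
        )

    def to_json(self, path, min_rel_intensity: float = 0.01) -> None:
        peaks = self.peaks if self.peaks is not None else find_peaks(self, min_rel_intensity)
        payload = {
            "kind": self.kind,
            "shift_cm1": self.shift_cm1,
            "wavenumbers_cm1": self.wavenumbers.tolist(),
            "intensities": self.intensities.tolist(),
            "peaks": peaks.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SpectrumResult":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["wavenumbers_cm1"]),
            np.asarray(d["intensities"]),
            d.get("shift_cm1", 0.0),
            d.get("kind", "continuous"),
            PeakTable.from_dict(d["peaks"]) if "peaks" in d else None,
        )


def correlation_to_spectrum(
    corr: Autocorrelation,
    hwhm_cm1: float | None = None,
    shift_cm1: float = 0.0,
    *,
    zpe_au: float = 0.0,
    pad_factor: int = 8,
    frequency_prefactor: bool = False,
    window: str = "none",
) -> SpectrumResult:
    """Fourier-transform a damped autocorrelation into an absorption spectrum.

    Parameters
    ----------
    hwhm_cm1
        Lorentzian half-width at half-maximum applied to every line via the
        damping exp(-Gamma t), Gamma = hwhm in hartree.  ``None`` disables
        damping.
    shift_cm1
        Rigid shift added to the wavenumber axis (e.g. to compensate
        systematic electronic-structure errors).
    zpe_au
        Initial-state vibrational energy: multiplies C(t) by exp(i E0 t) so
        peak positions are transition energies rather than final-state
        absolute energies.
    pad_factor
        Zero padding of the correlation (at least 8x by default) for
        sub-linewidth peak-position accuracy.
    frequency_prefactor
        Include the omega prefactor of the absorption cross-section.  Off by
        default: relative intensities within a narrow band are insensitive
        to it and all analysis statistics are normalization-invariant.
    window
        ``"none"`` (default) or ``"hann"``: a cos^2 half-window forcing the
        damped correlation smoothly to zero at the final time.  Use it when
        the correlation has not decayed within the propagated interval
        (Gamma T of only a few): it suppresses the truncation ringing that
        would otherwise contaminate weak peaks, at the cost of an extra
        ~1/T broadening shared identically by every line, so peak positions
        and relative intensities are unaffected.
    """
    t = corr.times
    c = corr.values.copy()
    if zpe_au:
        c = c * np.exp(1j * zpe_au * t)
    if hwhm_cm1 is not None:
        if hwhm_cm1 <= 0:
            raise ValueError("hwhm_cm1 must be positive when damping is requested")
        gamma = hwhm_cm1 * HARTREE_PER_INV_CM
        c = c * np.exp(-gamma * np.abs(t))
    if window == "hann":
        c = c * np.cos(0.5 * np.pi * t / t[-1]) ** 2
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")
    # trapezoid end-point weights for the half-line integral
    c[0] *= 0.5
    c[-1] *= 0.5

    n = c.size
    n_pad = 1 << int(np.ceil(np.log2(max(pad_factor, 1) * n)))
    dt = corr.dt
    # sum_j c_j e^{+i omega_k t_j} dt  with  omega_k = 2 pi k / (n_pad dt)
    transform = np.fft.ifft(c, n=n_pad) * n_pad * dt
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=dt)
    order = np.argsort(omega)
    omega = omega[order]
    intensity = transform.real[order]
    if frequency_prefactor:
        intensity = intensity * omega
    peak = np.abs(intensity).max()
    if peak > 0:
        intensity = intensity / peak
    wavenumbers = omega * INV_CM_PER_HARTREE + shift_cm1
    return SpectrumResult(wavenumbers, intensity, shift_cm1=shift_cm1)


def find_peaks(spectrum: SpectrumResult, min_rel_intensity: float = 0.01) -> PeakTable:
    """Locate spectral peaks above a relative-intensity threshold.

    Local maxima on the grid are refined by local quadratic interpolation
    through the three surrounding points, giving sub-grid peak positions.
    For stick spectra the sticks themselves are thresholded and returned.
    """
    y = spectrum.intensities
    x = spectrum.wavenumbers
    top = y.max()
    if spectrum.kind == "stick":
        mask = y >= min_rel_intensity * top
        return PeakTable(x[mask], y[mask])
    idx, _props = scipy.signal.find_peaks(y, height=min_rel_intensity * top)
    positions, heights = [], []
    for i in idx:
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            positions.append(x[i] + delta * (x[i + 1] - x[i]))
            heights.append(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta)
        else:
            positions.append(x[i])
            heights.append(y[i])
    return PeakTable(np.asarray(positions), np.asarray(heights))


def _as_peaks(obj) -> PeakTable:
    if isinstance(obj, PeakTable):
        return obj
    if isinstance(obj, SpectrumResult):
        return obj.peaks if obj.peaks is not None else find_peaks(obj)
    raise TypeError("expected a PeakTable or SpectrumResult")


def envelope_width(peaks) -> float:
    """Spectral-envelope width: twice the root of the intensity-weighted
    variance of the peak positions.

    A single peak has width 0; two equal peaks at omega0 +/- a have width 2a.
    The statistic is invariant under rigid shifts and intensity rescaling.
    """
    peaks = _as_peaks(peaks)
    if len(peaks) == 0:
        raise ValueError("empty peak table")
    w = peaks.intensities
    x = peaks.positions
    mean = np.average(x, weights=w)
    return float(2.0 * np.sqrt(np.average((x - mean) ** 2, weights=w)))


def mean_peak_spacing(peaks) -> float:
    """Mean spacing between adjacent peaks in the table."""
    peaks = _as_peaks(peaks)
    if len(peaks) < 2:
        raise ValueError("need at least two peaks for a spacing")
    return float(np.mean(np.diff(np.sort(peaks.positions))))


@dataclass(frozen=True)
class PeakShiftSeries:
    """Per-peak wavenumber differences between two spectra.

    Peaks are paired by progression index counted from the first (0-0) peak
    upward, not by nearest wavenumber: index pairing stays stable when the
    spacing changes substantially between isotopologues.
    """

    indices: np.ndarray
    delta: np.ndarray
    wavenumbers: np.ndarray
    truncated: bool = False


def peak_spacing_shifts(spectrum_a, spectrum_b) -> PeakShiftSeries:
    """Difference of corresponding peak wavenumbers, Delta = a - b.

    If the tables have different lengths, pairs are formed up to the shorter
    one and the series is flagged as truncated.
    """
    pa = _as_peaks(spectrum_a)
    pb = _as_peaks(spectrum_b)
    if len(pa) < 2 or len(pb) < 2:
        raise ValueError("need at least two peaks in each spectrum")
    m = min(len(pa), len(pb))
    xa = np.sort(pa.positions)[:m]
    xb = np.sort(pb.positions)[:m]
    return PeakShiftSeries(
        indices=np.arange(m),
        delta=xa - xb,
        wavenumbers=xa,
        truncated=(len(pa) != len(pb)),
    )


@dataclass(frozen=True)
class MimeResult:
    """Missing-mode-effect recurrence: collusion time t_M and omega_M = 2 pi / t_M.

    ``integers`` are the per-mode nearest integers n_j ~ omega_j t_M / (2 pi);
    the MIME frequency is the single progression frequency at which several
    displaced modes rephase together, and generally corresponds to no
    individual normal mode.
    """

    t_m: float
    omega_m: float
    integers: np.ndarray
    omegas: np.ndarray
    weights: np.ndarray

    @property
    def mismatch(self) -> float:
        return float(
            np.sum(self.weights * (self.omegas * self.t_m - 2 * np.pi * self.integers) ** 2)
        )


def _mime_objective(t, omegas, weights):
    n = np.round(omegas * t / (2 * np.pi))
    return np.sum(weights * (omegas * t - 2 * np.pi * n) ** 2), n


def mime_wavenumber(
    omegas, displacements, *, weighting: str = "dq2", max_iter: int = 100
) -> MimeResult:
    """Missing-mode-effect frequency of a set of displaced modes.

    Finds the collusion time t_M minimizing the displacement-weighted squared
    mismatch  sum_j w_j (omega_j t_M - 2 pi n_j)^2  with n_j the nearest
    integers, solved self-consistently: given integers, the quadratic
    minimizer is t = 2 pi (sum w omega n) / (sum w omega^2), and the
    integers are refreshed until a fixed point.  The iteration is seeded at
    the period of the most-displaced mode, which excludes the trivial
    solution t -> 0 where every n_j = 0.

    ``omegas`` may be in any frequency unit; ``omega_m`` is returned in the
    same unit.  ``weighting`` is ``"dq2"`` (squared mass-scaled
    displacements, default) or ``"dq"``.
    """
    omegas = np.atleast_1d(np.asarray(omegas, float))
    dq = np.atleast_1d(np.asarray(displacements, float))
    if omegas.shape != dq.shape or omegas.size == 0:
        raise ValueError("need matching, nonempty omega and displacement arrays")
    if np.all(dq == 0):
        raise ValueError("all displacements are zero: no mode drives a progression")
    if weighting == "dq2":
        w = dq**2
    elif weighting == "dq":
        w = np.abs(dq)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    dominant = int(np.argmax(w))
    t = 2.0 * np.pi / omegas[dominant]
    n = None
    for _ in range(max_iter):
        n_new = np.round(omegas * t / (2 * np.pi))
        n_new[dominant] = max(n_new[dominant], 1.0)
        if n is not None and np.array_equal(n_new, n):
            break
        n = n_new
        t = 2.0 * np.pi * np.sum(w * omegas * n) / np.sum(w * omegas**2)
    return MimeResult(
        t_m=float(t),
        omega_m=float(2.0 * np.pi / t),
        integers=n.astype(int),
        omegas=omegas,
        weights=w,
    )


def fit_spectral_shift(computed, reference_peaks) -> tuple[float, float]:
    """Best rigid shift of a computed spectrum onto reference peaks.

    Peaks are paired by progression index; the shift minimizing the mean
    absolute peak-position error is the median of the per-peak differences.
    Returns ``(shift_cm1, mae_cm1)``.
    """
    pc = _as_peaks(computed)
    pr = _as_peaks(reference_peaks)
    m = min(len(pc), len(pr))
    if m == 0:
        raise ValueError("no matchable peaks")
    diffs = np.sort(pr.positions)[:m] - np.sort(pc.positions)[:m]
    shift = float(np.median(diffs))
    mae = float(np.mean(np.abs(diffs - shift)))
    return shift, mae
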