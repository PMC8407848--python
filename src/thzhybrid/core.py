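"""Domain types and spectral transforms shared by all modules.

Conventions
-----------
* Time-harmonic fields evolve as ``exp(+i omega t)``; a lossy medium has
  complex refractive index ``n_tilde = n - i*kappa`` so that the propagation
  factor ``exp(-i n_tilde omega L / c)`` decays for ``kappa > 0``.
* Spectra are one-sided (non-negative angular frequency); negative
  frequencies are implied by conjugate symmetry of real signals.
* Angular frequency (rad/s) internally; files and the CLI speak THz and ps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.constants import c as C_LIGHT
from scipy.signal.windows import tukey

__all__ = [
    "C_LIGHT",
    "THZ",
    "PS",
    "Waveform",
    "Spectrum",
    "ComplexIndex",
    "TabulatedIndex",
    "Layer",
    "LayerStack",
    "KKSettings",
    "PhaseOffsetResult",
    "RetrievalGrid",
    "to_spectrum",
    "from_spectrum",
    "band_select",
    "unwrap_phase",
    "read_waveform",
    "write_waveform",
]

THZ = 1e12  # Hz per THz
PS = 1e-12  # s per ps

SEMI_INFINITE = np.inf


def _check_uniform(time: np.ndarray, rtol: float = 1e-9) -> float:
    """Return the grid step, raising if the grid is not strictly increasing
    and uniform to within ``rtol`` relative tolerance."""
    dt = np.diff(time)
    if np.any(dt <= 0):
        k = int(np.argmax(dt <= 0))
        raise ValueError(
            f"time grid not strictly increasing at sample {k + 1} "
            f"(t[{k}]={time[k]:.6g}, t[{k + 1}]={time[k + 1]:.6g})"
        )
    step = float(np.median(dt))
    bad = np.abs(dt - step) > rtol * max(abs(step), np.max(np.abs(dt)))
    if np.any(bad):
        k = int(np.argmax(bad))
        raise ValueError(
            f"non-uniform time grid: spacing at sample {k + 1} is "
            f"{dt[k]:.6g} s, expected {step:.6g} s"
        )
    return step


@dataclass
class Waveform:
    """A sampled time-domain electric-field trace on a uniform time grid.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing, uniform spacing.
    amplitude : ndarray
        Field amplitude, arbitrary units. Same length as ``time``.
    label : str
        Free-text description.
    """

    time: np.ndarray
    amplitude: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.amplitude.shape:
            raise ValueError("time and amplitude must be 1-D arrays of equal length")
        if self.time.size < 16:
            raise ValueError(f"waveform needs >= 16 samples, got {self.time.size}")
        self._dt = _check_uniform(self.time)

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return self._dt

    @property
    def n_samples(self) -> int:
        return self.time.size

    def peak_to_peak(self) -> float:
        return float(np.max(self.amplitude) - np.min(self.amplitude))


@dataclass
class Spectrum:
    """Complex field amplitude versus angular frequency (one-sided).

    ``band`` marks the usable (omega_min, omega_max) range; it must lie
    within the tabulated grid.
    """

    omega: np.ndarray
    value: np.ndarray
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.value = np.asarray(self.value, dtype=complex)
        if self.omega.ndim != 1 or self.omega.shape != self.value.shape:
            raise ValueError("omega and value must be 1-D arrays of equal length")
        if np.any(self.omega < 0):
            raise ValueError("omega must be non-negative")
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega must be strictly increasing")
        if self.band is None:
            self.band = (float(self.omega[0]), float(self.omega[-1]))
        lo, hi = self.band
        if lo < self.omega[0] - 1e-6 * self.omega[-1] or hi > self.omega[-1] * (1 + 1e-12):
            raise ValueError("band must be contained in the omega grid")

    @property
    def freq_thz(self) -> np.ndarray:
        """Ordinary frequency in THz."""
        return self.omega / (2 * np.pi * THZ)

    def copy(self) -> "Spectrum":
        return Spectrum(self.omega.copy(), self.value.copy(), self.band)


@dataclass(frozen=True)
class ComplexIndex:
    """Frequency-independent complex refractive index ``n - i*kappa``."""

    n: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"refractive index must be positive, got n={self.n}")
        if self.kappa < 0:
            raise ValueError(f"extinction coefficient must be >= 0, got kappa={self.kappa}")

    def at(self, omega) -> complex | np.ndarray:
        """Complex index evaluated at omega (constant; broadcasts)."""
        val = self.n - 1j * self.kappa
        if np.ndim(omega) == 0:
            return val
        return np.full(np.shape(omega), val, dtype=complex)


@dataclass(frozen=True)
class TabulatedIndex:
    """Frequency-dependent complex index, linearly interpolated in omega."""

    omega: np.ndarray
    n: np.ndarray
    kappa: np.ndarray

    def at(self, omega) -> complex | np.ndarray:
        n = np.interp(omega, self.omega, self.n)
        k = np.interp(omega, self.omega, self.kappa)
        out = n - 1j * k
        return complex(out) if np.ndim(omega) == 0 else out


@dataclass(frozen=True)
class Layer:
    """A single layer: complex index plus thickness in metres.

    Thickness ``inf`` marks a semi-infinite medium (layers 1 and 3).
    """

    index: ComplexIndex | TabulatedIndex
    thickness: float = SEMI_INFINITE

    def __post_init__(self) -> None:
        if not (self.thickness > 0):
            raise ValueError(f"layer thickness must be positive, got {self.thickness}")


@dataclass
class LayerStack:
    """Three-layer stack: incidence medium / sample / substrate.

    Layer 1 is the incidence medium (lossless), layer 2 the sample under
    study, layer 3 the known reference substrate.  ``walkoff`` holds the
    per-echo coupling factors A_wo,m (order m = 1 is the front-face
    reflection); ``None`` means all unity, exact for normal incidence.
    """

    layers: Sequence[Layer]
    theta1: float = 0.0
    polarisation: str = "s"
    walkoff: Sequence[complex] | None = None

    def __post_init__(self) -> None:
        self.layers = list(self.layers)
        if len(self.layers) != 3:
            raise ValueError(f"exactly 3 layers required, got {len(self.layers)}")
        idx1 = self.layers[0].index
        if isinstance(idx1, ComplexIndex) and idx1.kappa != 0:
            raise ValueError("layer 1 (incidence medium) must be lossless (kappa = 0)")
        if not (0 <= self.theta1 < np.pi / 2):
            raise ValueError(f"theta1 must be in [0, pi/2), got {self.theta1}")
        if self.polarisation not in ("s", "p"):
            raise ValueError(f"polarisation must be 's' or 'p', got {self.polarisation!r}")

    @property
    def n1(self):
        return self.layers[0].index

    @property
    def n2(self):
        return self.layers[1].index

    @property
    def n3(self):
        return self.layers[2].index


@dataclass
class KKSettings:
    """Settings for the SSKK phase-offset retrieval loop.

    Parameters
    ----------
    omega1 : float or None
        Anchor angular frequency (rad/s). ``None`` uses the band centre.
        Snapped to the nearest band grid point.
    epsilon : float
        Stopping tolerance on the relative improvement of the best
        consistency score between refinement levels.
    max_iterations : int
        Cap on refinement levels.
    offset_range : (float, float)
        Candidate plane-offset bracket in metres, default +/- 1 mm.
    n_candidates : int
        Candidates per refinement level.
    shrink : float
        Bracket shrink factor per refinement level.
    n_air : float
        Refractive index of the incidence medium used in the offset->phase
        map Delta_theta = omega * n_air * 2 dL / c.
    extrapolation : str
        Out-of-band continuation of ln|r| and theta for the dispersion
        integrals: "taper" (hold below band; half-octave cosine taper to the
        band mean above it) or "constant" (hold on both sides).
    omega_max_factor : float
        Upper truncation of the dispersion integrals, as a multiple of the
        band's upper edge.
    """

    omega1: float | None = None
    epsilon: float = 0.01
    max_iterations: int = 12
    offset_range: tuple[float, float] = (-1e-3, 1e-3)
    n_candidates: int = 256
    shrink: float = 4.0
    n_air: float = 1.0
    extrapolation: str = "taper"
    omega_max_factor: float = 8.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.n_candidates < 3:
            raise ValueError("need at least 3 offset candidates")
        if self.offset_range[0] >= self.offset_range[1]:
            raise ValueError("offset_range must be (lo, hi) with lo < hi")
        if self.extrapolation not in ("taper", "constant"):
            raise ValueError(f"unknown extrapolation mode {self.extrapolation!r}")


@dataclass
class PhaseOffsetResult:
    """Outcome of the SSKK plane-offset retrieval."""

    delta_L: float
    omega: np.ndarray
    delta_theta: np.ndarray
    corrected_phase: np.ndarray
    iterations: int
    consistency_history: list[float]
    converged: bool = True
    boundary_warning: bool = False
    omega1: float = 0.0


@dataclass
class RetrievalGrid:
    """Search grid for the per-frequency (n, kappa) scan."""

    n_values: np.ndarray = field(
        default_factory=lambda: np.arange(1.0, 4.0 + 1e-12, 0.01)
    )
    kappa_values: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 1.0 + 1e-12, 0.005)
    )
    refine_levels: int = 2

    def __post_init__(self) -> None:
        self.n_values = np.asarray(self.n_values, dtype=float)
        self.kappa_values = np.asarray(self.kappa_values, dtype=float)
        for name, g in (("n_values", self.n_values), ("kappa_values", self.kappa_values)):
            if g.size < 2:
                raise ValueError(f"{name} needs >= 2 points")
            if np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.refine_levels < 0:
            raise ValueError("refine_levels must be >= 0")


# ---------------------------------------------------------------------------
# spectral transforms


def _make_window(name: str, n: int, alpha: float = 0.1) -> np.ndarray:
    if name in ("rect", "rectangular", "boxcar", "none"):
        return np.ones(n)
    if name == "tukey":
        return tukey(n, alpha=alpha)
    raise ValueError(f"unknown window {name!r}")


def to_spectrum(w: Waveform, window: str = "tukey", alpha: float = 0.1) -> Spectrum:
    """Discrete Fourier transform of a waveform onto the one-sided grid.

    The window (default Tukey, cosine fraction 0.1, to suppress truncation
    ringing) is applied before the transform.  Values approximate the
    continuous Fourier integral: ``rfft * dt``.
    """
    win = _make_window(window, w.n_samples, alpha)
    value = np.fft.rfft(w.amplitude * win) * w.dt
    omega = 2 * np.pi * np.fft.rfftfreq(w.n_samples, w.dt)
    # remove the linear phase of the grid origin so spectra of traces whose
    # time axes start at t0 != 0 refer to absolute time
    value = value * np.exp(-1j * omega * w.time[0])
    return Spectrum(omega, value)


def from_spectrum(s: Spectrum, n_samples: int, dt: float, t0: float = 0.0) -> Waveform:
    """Inverse of :func:`to_spectrum` with a rectangular window."""
    omega = 2 * np.pi * np.fft.rfftfreq(n_samples, dt)
    if s.omega.shape != omega.shape or not np.allclose(s.omega, omega):
        raise ValueError("spectrum grid does not match the requested time grid")
    value = s.value * np.exp(1j * omega * t0)
    amp = np.fft.irfft(value, n=n_samples) / dt
    time = t0 + dt * np.arange(n_samples)
    return Waveform(time, amp)


def band_select(s: Spectrum, fmin: float, fmax: float) -> Spectrum:
    """Restrict a spectrum to ordinary frequencies [fmin, fmax] in Hz."""
    if fmin >= fmax:
        raise ValueError(f"fmin must be < fmax, got {fmin} >= {fmax}")
    lo, hi = 2 * np.pi * fmin, 2 * np.pi * fmax
    keep = (s.omega >= lo) & (s.omega <= hi)
    if not np.any(keep):
        raise ValueError(
            f"band [{fmin:.3g}, {fmax:.3g}] Hz has no overlap with the grid"
        )
    return Spectrum(s.omega[keep], s.value[keep])


def unwrap_phase(s: Spectrum) -> np.ndarray:
    """Continuous phase of the spectrum in radians.

    Adjacent jumps are below pi; the value at the lowest grid frequency lies
    in (-pi, pi].
    """
    if s.omega.size == 0:
        raise ValueError("empty spectrum")
    return np.unwrap(np.angle(s.value))


# ---------------------------------------------------------------------------
# waveform text files (two columns: time in ps, amplitude; '#' comments)


def read_waveform(path, label: str = "") -> Waveform:
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time ps, amplitude)")
    return Waveform(data[:, 0] * PS, data[:, 1], label=label or str(path))


def write_waveform(path, w: Waveform) -> None:
    header = f"{w.label}\ncolumns: time_ps amplitude"
    np.savetxt(path, np.column_stack([w.time / PS, w.amplitude]), header=header)
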