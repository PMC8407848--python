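"""Analytic Fresnel / Fabry-Perot reflection model of the three-layer stack,
and the synthetic waveform generator built on it.

The stack is air (layer 1) / thin sample (layer 2) / thick substrate
(layer 3).  The sample field is the front-face reflection plus the series of
internal etalon echoes

    E_samp = [A_1 R12 + sum_{m>=2} A_m T12 P2^{2(m-1)} R23^{m-1} R21^{m-2} T21] E0,

the reference field is the bare-substrate reflection P1^2 R13 E0 where P1 is
the one-way air propagation over the plane offset dL.  Per-echo walk-off
factors A_m are unity at normal incidence; when all are unity the series is
geometric and is summed in closed form.

Substrate echoes are not modelled: layer 3 is taken thick enough that its
Fabry-Perot reflections fall outside the measurement window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    C_LIGHT,
    PS,
    THZ,
    ComplexIndex,
    Layer,
    LayerStack,
    Spectrum,
    Waveform,
)

__all__ = [
    "PulseSpec",
    "SyntheticScene",
    "snell_angle",
    "fresnel_r",
    "fresnel_t",
    "propagation",
    "transfer_function",
    "etalon_reflectivity",
    "sample_reflectivity",
    "reference_reflectivity",
    "synthesize_waveforms",
    "bone_on_glass",
]


def _nval(index, omega):
    """Complex index value: accepts ComplexIndex/TabulatedIndex or raw numbers."""
    if hasattr(index, "at"):
        return index.at(omega)
    return np.asarray(index, dtype=complex) if np.ndim(index) else complex(index)


def snell_angle(n1, n2, theta1: float):
    """Refraction angle from Snell's law; complex-valued past the critical angle."""
    s = _nval(n1, 0.0) * np.sin(theta1) / _nval(n2, 0.0)
    return np.arcsin(np.asarray(s, dtype=complex))


def _cos_refracted(ni, nj, thetai):
    """cos(theta_j) = sqrt(1 - (ni sin(thetai) / nj)^2), on the branch for
    which the transmitted wave decays into medium j (Im(nj cos) <= 0 with the
    n - i*kappa convention)."""
    ct = np.sqrt(1.0 - (ni * np.sin(thetai) / nj) ** 2 + 0j)
    flip = np.imag(nj * ct) > 1e-15 * np.abs(nj * ct)
    return np.where(flip, -ct, ct)


def fresnel_r(ni, nj, thetai: float, pol: str = "s"):
    """Fresnel reflection coefficient for the i->j interface."""
    ni = _nval(ni, 0.0)
    nj = _nval(nj, 0.0)
    ci = np.cos(thetai)
    cj = _cos_refracted(ni, nj, thetai)
    if pol == "s":
        num, den = ni * ci - nj * cj, ni * ci + nj * cj
    elif pol == "p":
        num, den = ni * cj - nj * ci, ni * cj + nj * ci
    else:
        raise ValueError(f"polarisation must be 's' or 'p', got {pol!r}")
    r = num / den
    return complex(r) if np.ndim(r) == 0 else r


def fresnel_t(nk, nl, thetak: float, pol: str = "s"):
    """Fresnel transmission coefficient for the k->l interface.

    s: T = 1 + R;  p: T = (1 + R) cos(theta_k)/cos(theta_l).
    """
    r = fresnel_r(nk, nl, thetak, pol)
    if pol == "s":
        t = 1.0 + r
    else:
        nk_ = _nval(nk, 0.0)
        nl_ = _nval(nl, 0.0)
        cl = _cos_refracted(nk_, nl_, thetak)
        t = (1.0 + r) * np.cos(thetak) / cl
    return complex(t) if np.ndim(t) == 0 else t


def propagation(nq, omega, L: float, thetaq=0.0):
    """One-way propagation factor exp(-i n_tilde omega L_eff / c) with the
    oblique-incidence path length L_eff = L / cos(theta_q)."""
    if np.any(np.asarray(L) < 0):
        raise ValueError("propagation length must be >= 0")
    nq = _nval(nq, omega)
    leff = L / np.cos(thetaq)
    p = np.exp(-1j * nq * np.asarray(omega) * leff / C_LIGHT)
    return complex(p) if np.ndim(p) == 0 else p


def _stack_coeffs(stack: LayerStack, omega):
    """Interface coefficients of the three-layer stack at angular frequency
    omega (vectorised over omega)."""
    pol = stack.polarisation
    n1 = _nval(stack.n1, omega)
    n2 = _nval(stack.n2, omega)
    n3 = _nval(stack.n3, omega)
    th1 = stack.theta1
    th2 = snell_angle(n1, n2, th1)
    r12 = fresnel_r(n1, n2, th1, pol)
    r13 = fresnel_r(n1, n3, th1, pol)
    r23 = fresnel_r(n2, n3, th2, pol)
    r21 = fresnel_r(n2, n1, th2, pol)
    t12 = fresnel_t(n1, n2, th1, pol)
    t21 = fresnel_t(n2, n1, th2, pol)
    return n2, th2, r12, r13, r23, r21, t12, t21


def etalon_reflectivity(n2c, omega, L2, *, n1, n3, theta1=0.0, pol="s", walkoff=None, n_terms=None):
    """Reflectivity of the layered sample at its front surface,
    R12 + Fabry-Perot echo series, broadcast over ``n2c`` and ``omega``.

    ``n2c`` is the complex layer-2 index (n - i*kappa); arrays broadcast.
    Closed-form geometric sum when ``n_terms`` is None and all walk-off
    factors are unity; otherwise a truncated term-by-term sum.
    """
    th2 = snell_angle(n1, n2c, theta1)
    r12 = fresnel_r(n1, n2c, theta1, pol)
    r23 = fresnel_r(n2c, n3, th2, pol)
    r21 = fresnel_r(n2c, n1, th2, pol)
    t12 = fresnel_t(n1, n2c, theta1, pol)
    t21 = fresnel_t(n2c, n1, th2, pol)
    p2 = propagation(n2c, omega, L2, th2)
    ratio = p2**2 * r23 * r21

    if n_terms is None:
        if walkoff is not None and any(a != 1 for a in walkoff):
            raise ValueError(
                "closed-form sum requires all walk-off factors = 1; "
                "use n_terms for per-order walk-off"
            )
        if np.any(np.abs(ratio) >= 1):
            raise ValueError(
                "divergent Fabry-Perot series: |P2^2 R23 R21| >= 1 (unphysical gain)"
            )
        return r12 + t12 * t21 * p2**2 * r23 / (1.0 - ratio)

    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    a_wo = np.ones(n_terms, dtype=complex)
    if walkoff is not None:
        k = min(len(walkoff), n_terms)
        a_wo[:k] = np.asarray(walkoff, dtype=complex)[:k]
    total = a_wo[0] * r12
    if n_terms > 1:
        echo = t12 * t21 * p2**2 * r23  # m = 2 term
        total = total + a_wo[1] * echo
        for m in range(3, n_terms + 1):
            echo = echo * ratio
            total = total + a_wo[m - 1] * echo
    return total


def transfer_function(stack: LayerStack, omega, L2: float, n_terms: int | None = None):
    """Transfer function H(omega) = E_samp / E_ref of the three-layer stack
    with the reference plane brought to the sample plane (P1 = 1, the
    convention after Kramers-Kronig correction).

    ``n_terms=None`` sums the Fabry-Perot series in closed form (requires
    unit walk-off factors); an integer sums that many echo terms.
    """
    r13 = fresnel_r(_nval(stack.n1, omega), _nval(stack.n3, omega), stack.theta1,
                    stack.polarisation)
    r_samp = etalon_reflectivity(
        _nval(stack.n2, omega), omega, L2,
        n1=_nval(stack.n1, omega), n3=_nval(stack.n3, omega),
        theta1=stack.theta1, pol=stack.polarisation,
        walkoff=stack.walkoff, n_terms=n_terms,
    )
    return r_samp / r13


def sample_reflectivity(stack: LayerStack, omega, L2: float, n_terms: int | None = None):
    """E_samp / E0 at the sample plane (front-face + Fabry-Perot echoes)."""
    return etalon_reflectivity(
        _nval(stack.n2, omega), omega, L2,
        n1=_nval(stack.n1, omega), n3=_nval(stack.n3, omega),
        theta1=stack.theta1, pol=stack.polarisation,
        walkoff=stack.walkoff, n_terms=n_terms,
    )


def reference_reflectivity(stack: LayerStack, omega, delta_L: float):
    """E_ref / E0: bare-substrate reflection from a plane sitting ``delta_L``
    behind the sample plane, P1^2 R13 with round-trip air propagation."""
    n1 = _nval(stack.n1, omega)
    n3 = _nval(stack.n3, omega)
    r13 = fresnel_r(n1, n3, stack.theta1, stack.polarisation)
    p1 = propagation(n1, omega, delta_L, stack.theta1)
    return p1**2 * r13


# ---------------------------------------------------------------------------
# synthetic scenes


@dataclass
class PulseSpec:
    """Gaussian probe pulse: band edges are the -20 dB points of the
    frequency-domain magnitude (the measurement band), flat spectral phase
    apart from the delay ``t0_ps`` centring the pulse in the window."""

    f_min_thz: float = 0.3
    f_max_thz: float = 1.0
    amplitude: float = 1.0
    t_span_ps: float = 120.0
    dt_ps: float = 0.05
    t0_ps: float = 15.0
    edge_db: float = -20.0

    def __post_init__(self) -> None:
        if not (0 < self.f_min_thz < self.f_max_thz):
            raise ValueError("need 0 < f_min < f_max")
        nyq_thz = 1.0 / (2 * self.dt_ps)  # ps <-> THz are reciprocal units
        if nyq_thz < 4 * self.f_max_thz:
            raise ValueError(
                f"sampling interval {self.dt_ps} ps gives Nyquist {nyq_thz:.3g} THz "
                f"< 4 x upper band edge {self.f_max_thz} THz"
            )
        if self.t_span_ps <= self.t0_ps:
            raise ValueError("time span must exceed the pulse delay")

    @property
    def n_samples(self) -> int:
        return int(round(self.t_span_ps / self.dt_ps))

    def time_grid(self) -> np.ndarray:
        """Time samples in seconds, starting at t = 0."""
        return np.arange(self.n_samples) * self.dt_ps * PS

    def spectrum(self) -> Spectrum:
        """Incident-field spectrum E0(omega) on the one-sided grid of the
        time window."""
        n = self.n_samples
        dt = self.dt_ps * PS
        omega = 2 * np.pi * np.fft.rfftfreq(n, dt)
        f0 = 0.5 * (self.f_min_thz + self.f_max_thz) * THZ
        half_bw = 0.5 * (self.f_max_thz - self.f_min_thz) * THZ
        # -edge_db dB at the band edges: exp(-half_bw^2/(2 sigma^2)) = 10^(edge_db/20)
        sigma = half_bw / np.sqrt(-2.0 * np.log(10.0 ** (self.edge_db / 20.0)))
        mag = self.amplitude * np.exp(-((omega / (2 * np.pi) - f0) ** 2) / (2 * sigma**2))
        value = mag * np.exp(-1j * omega * self.t0_ps * PS)
        return Spectrum(omega, value,
                        band=(2 * np.pi * self.f_min_thz * THZ,
                              2 * np.pi * self.f_max_thz * THZ))


@dataclass
class SyntheticScene:
    """A measurement scene: layer stack, reference-plane offset behind the
    sample plane (metres), and optional additive Gaussian noise."""

    stack: LayerStack
    reference_offset: float = 0.0
    noise_rms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_offset < 0:
            raise ValueError("reference_offset must be >= 0")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")


def synthesize_waveforms(scene: SyntheticScene, pulse: PulseSpec) -> tuple[Waveform, Waveform]:
    """Time-domain sample and reference traces for a synthetic scene.

    The sample trace is the inverse transform of the etalon reflectivity
    applied to the pulse; the reference trace reflects from the bare
    substrate a distance ``reference_offset`` behind the sample plane.
    Both share one time grid; noise (if any) is Gaussian with the scene's
    seed, drawn independently for the two traces.
    """
    e0 = pulse.spectrum()
    omega = e0.omega
    L2 = scene.stack.layers[1].thickness
    if not np.isfinite(L2):
        raise ValueError("layer 2 must have a finite thickness")
    r_s = sample_reflectivity(scene.stack, omega, L2)
    r_r = reference_reflectivity(scene.stack, omega, scene.reference_offset)

    dt = pulse.dt_ps * PS
    n = pulse.n_samples
    time = pulse.time_grid()
    amp_s = np.fft.irfft(e0.value * r_s, n=n) / dt
    amp_r = np.fft.irfft(e0.value * r_r, n=n) / dt
    if scene.noise_rms > 0:
        rng = np.random.default_rng(scene.seed)
        amp_s = amp_s + rng.normal(0.0, scene.noise_rms, n)
        amp_r = amp_r + rng.normal(0.0, scene.noise_rms, n)
    return (
        Waveform(time, amp_s, label="sample"),
        Waveform(time, amp_r, label="reference"),
    )


def bone_on_glass(
    L2: float = 100e-6,
    *,
    n_bone: float = 1.8,
    kappa_bone: float = 0.08,
    n_glass: float = 2.6,
    kappa_glass: float = 0.15,
    theta1: float = 0.0,
    polarisation: str = "s",
) -> LayerStack:
    """The air / bone / glass validation stack: bone 1.8 - 0.08i on glass
    2.6 - 0.15i, the dielectric values of the glass-backed bone structures
    the method targets."""
    return LayerStack(
        layers=[
            Layer(ComplexIndex(1.0, 0.0)),
            Layer(ComplexIndex(n_bone, kappa_bone), thickness=L2),
            Layer(ComplexIndex(n_glass, kappa_glass)),
        ],
        theta1=theta1,
        polarisation=polarisation,
    )
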