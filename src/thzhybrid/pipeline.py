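"""End-to-end hybrid retrieval: Kramers-Kronig plane-offset correction first,
Fabry-Perot dielectric extraction second.

The measured transfer function is formed twice: once on a wide analysis
grid (everything the reference spectrum supports above its leakage floor)
for the dispersion integrals, and once on the scoring band for the final
per-frequency (n, kappa) scan with the corrected phase substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    C_LIGHT,
    KKSettings,
    LayerStack,
    PhaseOffsetResult,
    RetrievalGrid,
    Spectrum,
    Waveform,
    band_select,
    to_spectrum,
    unwrap_phase,
)
from .kk import offset_to_thickness, retrieve_phase_offset
from .retrieval import NKResult, measured_H, retrieve_nk

__all__ = ["HybridResult", "run_hybrid", "analysis_transfer_function"]


@dataclass
class HybridResult:
    """Bundle of every intermediate of the hybrid pipeline."""

    offset: PhaseOffsetResult
    thickness: float
    H_raw: Spectrum
    H_corrected: Spectrum
    nk: NKResult
    flags: dict = field(default_factory=dict)


def analysis_transfer_function(
    sample: Waveform,
    reference: Waveform,
    band: tuple[float, float],
    analysis_band: tuple[float, float] | None = None,
    rel_floor: float = 1e-3,
    window: str = "tukey",
) -> Spectrum:
    """Transfer function tabulated on the widest trustworthy grid.

    The grid spans where the reference magnitude stays above ``rel_floor``
    of its peak (windowing-leakage floor), clipped to ``analysis_band`` if
    given; the usable measurement band is recorded in ``Spectrum.band`` for
    downstream scoring.
    """
    s = to_spectrum(sample, window=window)
    r = to_spectrum(reference, window=window)
    mag = np.abs(r.value)
    good = mag >= rel_floor * mag.max()
    if analysis_band is not None:
        good &= (s.omega >= 2 * np.pi * analysis_band[0]) & (
            s.omega <= 2 * np.pi * analysis_band[1]
        )
    # largest contiguous run containing the band centre
    centre = np.pi * (band[0] + band[1])
    idx = np.flatnonzero(good)
    if idx.size < 8:
        raise ValueError("reference spectrum supports too few usable frequencies")
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    run = min(
        (r_ for r_ in splits if r_.size >= 8),
        key=lambda r_: abs(0.5 * (s.omega[r_[0]] + s.omega[r_[-1]]) - centre),
    )
    sel = slice(run[0], run[-1] + 1)
    lo, hi = 2 * np.pi * band[0], 2 * np.pi * band[1]
    if s.omega[sel][0] > lo or s.omega[sel][-1] < hi:
        raise ValueError("usable reference spectrum does not cover the band")
    return Spectrum(s.omega[sel], s.value[sel] / r.value[sel], band=(lo, hi))


def run_hybrid(
    sample: Waveform,
    reference: Waveform,
    stack: LayerStack,
    kk: KKSettings | None = None,
    grid: RetrievalGrid | None = None,
    band: tuple[float, float] = (0.3e12, 1.0e12),
    analysis_band: tuple[float, float] | None = None,
    thickness: float | None = None,
    w_amp: float = 1.0,
    w_phase: float = 1.0,
    window: str = "tukey",
) -> HybridResult:
    """Full hybrid retrieval on a sample/reference waveform pair.

    Stages: transfer function -> SSKK plane-offset retrieval -> thickness ->
    corrected-phase transfer function -> per-frequency (n, kappa) scan.
    ``thickness`` overrides the Kramers-Kronig-derived layer-2 thickness
    when the geometry is known independently.
    """
    kk = kk or KKSettings()
    try:
        h_wide = analysis_transfer_function(
            sample, reference, band, analysis_band, window=window
        )
    except ValueError as e:
        raise ValueError(f"[transfer-function stage] {e}") from e

    offset = retrieve_phase_offset(h_wide, kk)
    L2 = thickness if thickness is not None else offset_to_thickness(offset)

    h_band = measured_H(sample, reference, band, window=window)
    theta_corr = unwrap_phase(h_band) - (
        2.0 * kk.n_air * h_band.omega / C_LIGHT
    ) * offset.delta_L
    h_corr = Spectrum(h_band.omega, np.abs(h_band.value) * np.exp(1j * theta_corr))

    flags = {
        "kk_converged": offset.converged,
        "kk_boundary": offset.boundary_warning,
    }
    if L2 <= 0:
        # no resolvable layer: report the raw-Fresnel limiting case
        flags["no_sample_layer"] = True
        nk = NKResult(
            h_corr.omega,
            np.full(h_corr.omega.size, np.nan),
            np.full(h_corr.omega.size, np.nan),
            np.full(h_corr.omega.size, np.nan),
            np.zeros(h_corr.omega.size, dtype=bool),
        )
    else:
        try:
            nk = retrieve_nk(h_corr, stack, L2, grid, w_amp, w_phase)
        except ValueError as e:
            raise ValueError(f"[retrieval stage] {e}") from e
        flags["nk_boundary_frequencies"] = int(nk.boundary_flag.sum())
    return HybridResult(offset, L2, h_band, h_corr, nk, flags)
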