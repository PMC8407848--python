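# Methods

## Conventions

Fields evolve as exp(+iωt); a lossy medium has ñ = n − iκ so the one-way
propagation factor P(ω, L) = exp(−i ñ ω L_eff / c), with L_eff = L/cos θ at
oblique incidence, decays for κ > 0. Spectra are one-sided; real signals
supply the negative frequencies by conjugate symmetry. Frequencies are
angular (rad/s) internally; files and the CLI use THz and ps. In this
convention a causal response is analytic in the lower half of the complex
frequency plane, which fixes the relative sign of the two anchored
dispersion relations: the phase-from-amplitude relation carries +2/π, the
amplitude-from-phase relation −2/π. (Printing both with the same sign, as
is common, is inconsistent in any single convention: a pure delay — flat
amplitude, linear phase — would otherwise violate one of them. The
Lorentz-oscillator round-trip test in the suite pins the signs down.)

## Forward model

The scene is a three-layer stack: semi-infinite incidence medium (air),
sample layer of thickness L₂, semi-infinite substrate with known
dielectrics. The sample reflection is the front-face Fresnel coefficient
plus the etalon series

    E_samp/E₀ = A₁R₁₂ + Σ_{m≥2} A_m T₁₂ P₂^{2(m−1)} R₂₃^{m−1} R₂₁^{m−2} T₂₁ ,

summed in closed geometric form when all per-echo walk-off factors A_m are
unity (exact at normal incidence) and term-by-term otherwise — per-order
walk-off breaks the geometric structure, which is why both modes exist and
are cross-checked to 1e-10. The reference is the bare-substrate reflection
from a plane ΔL behind the sample surface, P₁²R₁₃E₀ with P₁ the one-way air
propagation over ΔL. Substrate-internal echoes are not modelled: the
substrate is assumed thick enough that they fall outside the measurement
window. No Gaussian-beam divergence, focusing optics or surface-roughness
scattering is modelled; the field is a linearly polarised plane wave.

The synthetic probe is Gaussian in spectral magnitude with flat phase apart
from a delay centring the pulse in the window. Band edges (default 0.3 and
1.0 THz) are the −20 dB points; defaults are a 120 ps window sampled at
0.05 ps (Nyquist 10 THz, ≥ 4× margin over the band top; ~8.3 GHz frequency
resolution, 84 bins in band). Additive Gaussian noise is optional and
seeded. Waveforms are transformed with a Tukey window (cosine fraction 0.1)
by default; a rectangular window is available and used by the oracle tests.

## SSKK plane-offset retrieval

A reference-plane offset ΔL multiplies the measured transfer function by
exp(+i·2ωΔL/c) in this convention. The retrieval scans candidate offsets,
corrects the phase by the single scalar ΔL (a per-frequency search would be
ill-posed; the offset is a plane displacement), and scores each candidate
by self-consistency: r_guess = exp(ln|H| + iθ_cand) against r_corrected,
whose phase is the SSKK transform of ln|H| and whose log-amplitude is the
SSKK transform of θ_cand, both anchored at ω₁ (default: band centre,
snapped to the nearest bin). The score is the RMS complex difference over
the usable band. The loop is coarse-to-fine: 256 candidates over ±1 mm,
bracket shrunk 4× around the running minimum per level, stopping when the
best score improves by less than ε = 0.01 between levels; a final
three-point parabolic interpolation of the (smooth, noise-free near its
minimum) score polishes ΔL below the last grid step. Equal scores resolve
to the smaller |ΔL|. Non-convergence is flagged, not raised; a minimum on
the candidate-range edge warns that the range is too narrow.

Two numerical points matter:

* **Phase branch.** The anchored relations apply to a phase that vanishes
  at DC. Reflection off a denser-than-air surface is negative-real at DC
  (a constant π), so the loop operates on the transfer function H — a
  ratio of two such reflectivities, in which the π cancels — rather than
  on the sample reflectivity itself.
* **Semi-infinite integrals from band-limited data.** The principal-value
  integrals run over [0, ∞) but the data are tabulated on a finite grid.
  The kernel is split by partial fractions into single-pole integrals
  I(a) = P∫ f/(ω′²−a²) dω′, each evaluated by singularity subtraction with
  the closed-form PV of the bare pole; the whole chain (continuation,
  quadrature, anchoring) is precomputed as one matrix per kernel, so the
  candidate scan is a few matrix products. The integrals use **every
  tabulated frequency** of the measured spectrum — by default everything
  where the reference magnitude stays above 10⁻³ of its peak (0.1–1.6 THz
  for the default pulse), wider than the 0.3–1 THz scoring band — because
  out-of-band etalon oscillations of ln|H| are real information: discarding
  them biases ΔL by several μm at L₂ = 100 μm. Beyond the tabulated grid
  the functions are held constant below, cosine-tapered over half an octave
  to the band mean above, and the remaining [0, grid-start) sliver and
  (grid-end, ∞) tail are added in closed form (the ω′θ(ω′) tail is
  log-divergent; its finite part is taken — the divergent constant cancels
  in the anchored differences). With these corrections a flat amplitude
  maps to exactly zero phase and the retrieval is anchor-independent to
  ≲ 0.2 μm across the central 80 % of the band.

Residual ΔL bias on noise-free synthetic scenes is ≈ 1 μm for a 100 μm
etalon layer (missing out-of-band oscillation information plus the small
non-causality of idealised constant-κ media) and falls well below that for
optically thick or very thin layers. For the sample-on-substrate geometry
the recovered ΔL is the layer thickness.

## Per-frequency (n, κ) scan

The measured H (with the KK-corrected phase substituted) is fit at each
band frequency independently by exhaustive scan over n ∈ [1, 4] step 0.01
and κ ∈ [0, 1] step 0.005 (config-overridable), then two local refinement
levels shrinking the step 5× each, minimising

    err(n, κ) = sqrt( w_a(|H_g|−|H_m|)² + w_p(arg H_g − arg H_m)² ),

with w_a = w_p = 1 (the weighting is exposed in config; equal weights are
the neutral choice). P₁ is unity inside H_g: the KK correction has brought
the reference plane to the sample plane. The model phase is tracked
continuously along the frequency axis per candidate, matching the branch
of the unwrapped measured phase, so a 2π-offset root is scored 2π away
rather than as a perfect fit.

**Root degeneracy.** Once the layer's optical phase thickness is large
enough (above ≈ 0.8 THz for 100 μm of n = 1.8), the single-frequency
problem is genuinely multimodal: distinct (n, κ) pairs reproduce the same
complex H, and under any data error the global minimum can hop to the wrong
root. The fit itself uses no smoothness prior — each frequency is
minimised independently, keeping the estimator unbiased — but when several
local minima lie within tie_tol = 5e-3 of the best (i.e. all fit the data
essentially exactly), the root closest to the previous frequency's
solution is chosen; at the first band frequency and for exact ties the
smallest n, then smallest κ, wins. tie_tol = 0 reduces the scan to the
plain argmin (the brute-force-equivalence test runs in that mode). The
tolerance only needs to cover the basin-minimum spread of exact roots
(quadrature level), not the data error, which is why it is small; a large
value would sweep flat high-κ plateaus into the tie set.

Minima pinned to the level-0 grid boundary are flagged per frequency and
summarised in a warning.

## Thickness-limit study

`thickness_limit_study` sweeps the layer thickness downward (default: 16
logarithmic points from 100 μm to 0.1 μm) and reports the smallest
thickness at which max relative error of (n, κ) over the band stays within
tolerance (5 %). Each point is a full synthesize → transfer function →
scan round trip with an **aligned reference and the simulated thickness
known exactly** — the conditions of a solver-based forward study, which
isolate the Fabry-Pérot model's thickness limit from plane-offset
retrieval. The phase-consistency route cannot resolve a plane offset to
5 % of 0.1 μm (0.005 μm) from band-limited data, so feeding KK-derived
thickness into this sweep would measure the offset-retrieval floor, not
the model limit. The end-to-end pipeline (`run_hybrid`) conversely defaults
to the KK-derived thickness, which is the hybrid flow used on real scenes.
This is deliberately an inverse-crime validation: the data generator and
the fitted model share the same physics, so the study bounds numerical
fidelity (windowing, grid resolution, branch selection), not robustness to
model error.

## Imaging

Each unmasked pixel of a raster cube is processed independently against
one shared reference trace (a designated bare-substrate pixel or an
external waveform); per-row references are rejected in this release.
Pixels with peak-to-peak field below 1 % of the cube maximum are skipped
and flagged (empty/embedding-medium pixels). Map values at requested
frequencies use the nearest band bin, recorded in the output metadata.
Flags (masked, low-SNR, KK non-convergence/boundary, grid boundary)
propagate to the output maps; results are independent of pixel order.

## What the synthetic generator does and does not emulate

It reproduces the geometry and physics the retrieval assumes: plane-wave
Fresnel/etalon reflection from a uniform three-layer stack, a displaced
reference plane, a band-limited Gaussian pulse, optional white noise. It
does not emulate frequency-dependent material dispersion (constant n, κ
per layer by default — note a strictly constant κ is itself mildly
non-causal and contributes a sub-μm ΔL bias), beam divergence, surface
roughness or scattering, detector response, or delay-line jitter. Passing
tests therefore demonstrate correctness of the algorithmic chain under its
own assumptions, and the quoted tolerances (band-average index to 0.02 /
0.01, offset to 2 μm, thickness limit 0.1 μm) are statements about that
regime, not about arbitrary experimental data.

## Defaults worth knowing

| parameter | default | units | why |
|---|---|---|---|
| pulse band | 0.3–1.0 | THz | measurement band of the target instrument class |
| window span / step | 120 / 0.05 | ps | ≥4× Nyquist margin; 8.3 GHz resolution |
| ε (KK stop) | 0.01 | — | relative improvement of best score between levels |
| offset range / candidates | ±1 / 256 | mm / — | covers any realistic misalignment; <0.1 μm final step |
| bracket shrink | 4 | — | geometric coarse-to-fine refinement |
| analysis band | 0.1–1.6 | THz | reference spectrum above its leakage floor |
| n grid | 1.0–4.0 step 0.01 | — | spans tissue, mineral and glass values |
| κ grid | 0–1.0 step 0.005 | — | same |
| refinement levels | 2 (×5 shrink) | — | final resolution 4·10⁻⁴ / 2·10⁻⁴ |
| tie_tol | 5e-3 | — | exact-root degeneracy window (see above) |
| walk-off A_m | 1 | — | exact for normal incidence; per-order values accepted, no calibration routine |
| low-SNR pixel cut | 1 % | of cube max | skip empty/embedding pixels |

## Known limitations

* ΔL carries a ≈ 1 μm bias for strongly etalon-structured spectra; the
  per-frequency dielectrics at the extreme band edges inherit errors up to
  ~0.02–0.04 there, while band averages stay well inside 0.02 / 0.01.
* Frequency-dependent (tabulated) substrate indices are supported in the
  stack types, but the bundled scenes use constant values.
* The per-frequency scan needs the substrate dielectrics on the band; no
  self-calibration of the reference is attempted.
* No error propagation / uncertainty quantification of the KK loop is
  provided.
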