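"""Singly-subtractive Kramers-Kronig (SSKK) retrieval of the reference-plane
offset.

A plane offset dL between the sample and reference reflection planes adds a
spurious frequency-linear phase Delta_theta(omega) = omega * n_air * 2 dL / c
to the measured reflection coefficient r(omega) = |r| exp(i theta).  Causality
ties ln|r| and theta together through the anchored dispersion integrals

    ln|r(w)| - ln|r(w1)| = -(2(w^2-w1^2)/pi) PV I[ w' theta(w') ],
    theta(w)/w - theta(w1)/w1 = (2(w^2-w1^2)/pi) PV I[ ln|r(w')| ],

with kernel 1/((w'^2-w^2)(w'^2-w1^2)) and anchor w1 inside the measured band.
The relative sign of the pair is fixed by the exp(+i omega t) time convention
used throughout this package (n_tilde = n - i kappa, response analytic in the
lower half-plane); literature statements in the conjugate convention flip it.
They apply to a branch of the phase that vanishes at DC, which is why the
offset search operates on the transfer function H = E_samp/E_ref (the
constant pi of reflection off a denser medium cancels in the ratio).
A pure delay ramp is inconsistent with these relations, so scanning candidate
offsets for maximum self-consistency recovers dL.

Numerics: the double-pole kernel is split by partial fractions into
differences of single-pole principal-value integrals I(a) = PV int f/(w'^2-a^2),
each computed by singularity subtraction with the closed-form PV of the bare
pole.  Both SSKK transforms are then exact linear maps of the tabulated band
values, precomputed as matrices so the offset scan is a handful of matmuls.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import C_LIGHT, KKSettings, PhaseOffsetResult, Spectrum, unwrap_phase

__all__ = [
    "SSKKOperator",
    "pv_integral",
    "sskk_phase",
    "sskk_lnamp",
    "consistency_error",
    "retrieve_phase_offset",
    "offset_to_thickness",
]


def _pole_pv_closed_form(a: np.ndarray, w_lo: float, w_hi: float) -> np.ndarray:
    """PV integral of 1/(w'^2 - a^2) over [w_lo, w_hi] containing the pole a."""
    return (1.0 / (2 * a)) * (
        np.log((w_hi - a) / (w_hi + a)) - np.log(np.abs(w_lo - a) / (w_lo + a))
    )


def _single_pole_pv(omega_grid: np.ndarray, f: np.ndarray, a: float) -> float:
    """PV int f(w')/(w'^2 - a^2) dw' over the tabulated grid, pole at a.

    Singularity subtraction: the integrand with f(a) removed is regular and
    integrated by the trapezoid rule; the bare pole gets its closed form.
    """
    h = omega_grid[1] - omega_grid[0]
    tw = np.full(omega_grid.size, h)
    tw[0] = tw[-1] = h / 2
    fa = float(np.interp(a, omega_grid, f))
    denom = omega_grid**2 - a**2
    reg = np.zeros_like(f)
    k = int(np.argmin(np.abs(omega_grid - a)))
    on_grid = abs(omega_grid[k] - a) < 1e-9 * h
    mask = np.ones(omega_grid.size, dtype=bool)
    if on_grid:
        mask[k] = False
    reg[mask] = (f[mask] - fa) / denom[mask]
    if on_grid and 0 < k < omega_grid.size - 1:
        # removable singularity: limit f'(a)/(2a) via central difference
        reg[k] = (f[k + 1] - f[k - 1]) / (2 * h) / (2 * a)
    return float(np.dot(tw, reg)) + fa * float(
        _pole_pv_closed_form(np.array(a), omega_grid[0], omega_grid[-1])
    )


def pv_integral(omega_grid: np.ndarray, f: np.ndarray, omega: float, omega1: float) -> float:
    """Cauchy principal value of int f(w') / ((w'^2-w^2)(w'^2-w1^2)) dw'
    over the tabulated range, both singular points inside the grid.

    Partial fractions reduce the double pole to a difference of single-pole
    PV integrals; near-coincident omega and omega1 fall back to a finite
    difference of I(a) in a^2.
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    f = np.asarray(f, dtype=float)
    h = omega_grid[1] - omega_grid[0]
    for name, a in (("omega", omega), ("omega1", omega1)):
        if not (omega_grid[0] <= a <= omega_grid[-1]):
            raise ValueError(f"{name}={a:.6g} lies outside the tabulated grid")
    if abs(omega**2 - omega1**2) > (h * max(omega, omega1)):
        i_w = _single_pole_pv(omega_grid, f, omega)
        i_w1 = _single_pole_pv(omega_grid, f, omega1)
        return (i_w - i_w1) / (omega**2 - omega1**2)
    # degenerate anchor: derivative dI/d(a^2) by central difference
    a = 0.5 * (omega + omega1)
    d = max(h, 1e-6 * a)
    i_p = _single_pole_pv(omega_grid, f, a + d)
    i_m = _single_pole_pv(omega_grid, f, a - d)
    return (i_p - i_m) / ((a + d) ** 2 - (a - d) ** 2)


class SSKKOperator:
    """Precomputed linear SSKK transforms on a uniform in-band grid.

    The band functions ln|r| and theta are continued outside the measured
    band (held constant below it; above it either held or cosine-tapered
    over half an octave towards the band mean), the dispersion integrals are
    truncated at ``omega_max_factor`` times the upper band edge, and the
    whole chain -- continuation, pole quadrature, anchoring -- collapses
    into two matrices applied to the band values.
    """

    def __init__(
        self,
        omega_grid: np.ndarray,
        settings: KKSettings | None = None,
        band: tuple[float, float] | None = None,
    ):
        settings = settings or KKSettings()
        self.settings = settings
        omega_grid = np.asarray(omega_grid, dtype=float)
        if omega_grid.size < 4:
            raise ValueError("grid must contain at least 4 frequencies")
        d = np.diff(omega_grid)
        h = float(np.median(d))
        if np.any(np.abs(d - h) > 1e-6 * h):
            raise ValueError("SSKK operator requires a uniform frequency grid")
        if omega_grid[0] <= 0:
            raise ValueError("grid must start at a positive frequency")
        self.omega = omega_grid
        self.h = h
        n = omega_grid.size

        # scoring band: subset of the tabulated grid (the tabulated points
        # outside it still feed the dispersion integrals)
        if band is None:
            band_mask = np.ones(n, dtype=bool)
        else:
            band_mask = (omega_grid >= band[0] - 1e-6 * h) & (
                omega_grid <= band[1] + 1e-6 * h
            )
            if band_mask.sum() < 4:
                raise ValueError("band must contain at least 4 grid points")
        self.band_mask = band_mask
        self.omega_band = omega_grid[band_mask]
        nb = self.omega_band.size

        # anchor: nearest in-band grid point
        w1 = settings.omega1 if settings.omega1 is not None else 0.5 * (
            self.omega_band[0] + self.omega_band[-1]
        )
        if not (self.omega_band[0] <= w1 <= self.omega_band[-1]):
            raise ValueError("anchor omega1 must lie inside the band")
        self.i1 = int(np.argmin(np.abs(self.omega_band - w1)))
        if self.i1 in (0, nb - 1):
            warnings.warn("anchor omega1 sits on the band edge: poorly conditioned")
        self.omega1 = float(self.omega_band[self.i1])

        # extended grid aligned with the tabulated grid; reaches w' = 0
        # exactly when the tabulated grid is a subset of a DFT grid
        n_below = int(np.floor(omega_grid[0] / h * (1 + 1e-12)))
        omega_max = settings.omega_max_factor * omega_grid[-1]
        n_above = int(np.ceil((omega_max - omega_grid[-1]) / h))
        ext = omega_grid[0] + h * np.arange(-n_below, n + n_above)
        self.ext = ext
        m = ext.size
        k0 = n_below  # index of first tabulated point in ext

        # continuation operator E: tabulated values -> extended grid
        E = np.zeros((m, n))
        E[:k0, 0] = 1.0
        E[k0:k0 + n, :] = np.eye(n)
        hi = omega_grid[-1]
        above = np.arange(k0 + n, m)
        mean_row = band_mask.astype(float) / band_mask.sum()
        if settings.extrapolation == "constant":
            E[above, -1] = 1.0
        else:  # half-octave cosine taper from the edge value to the band mean
            w_end = hi * np.sqrt(2.0)
            x = np.clip((ext[above] - hi) / (w_end - hi), 0.0, 1.0)
            wgt = 0.5 * (1.0 + np.cos(np.pi * x))
            E[above, -1] = wgt
            E[above, :] += (1.0 - wgt)[:, None] * mean_row[None, :]
        self._E = E

        # single-pole PV quadrature matrix W: extended values -> I(a) at the
        # in-band evaluation points
        tw = np.full(m, h)
        tw[0] = tw[-1] = h / 2
        a = self.omega_band
        D = ext[None, :] ** 2 - a[:, None] ** 2
        W = np.zeros((nb, m))
        rows = np.arange(nb)
        cols = k0 + np.flatnonzero(band_mask)  # band points sit on the ext grid
        with np.errstate(divide="ignore", invalid="ignore"):
            W[:] = tw[None, :] / D
        W[rows, cols] = 0.0
        # subtraction of f(a): -f_a * sum_{j != k} tw_j / D + f_a * closed-form PV
        row_sums = W.sum(axis=1)
        cpv = _pole_pv_closed_form(a, ext[0], ext[-1])
        W[rows, cols] += cpv - row_sums
        # removable point: integrand limit f'(a)/(2a), central difference
        W[rows, cols - 1] += -tw[cols] / (2 * h) / (2 * a)
        W[rows, cols + 1] += tw[cols] / (2 * h) / (2 * a)

        # composed tabulated-to-band operators
        self._K_lnamp = W @ E                      # I[ln|r|](a_i)
        self._K_wtheta = (W * ext[None, :]) @ E    # I[w' theta(w')](a_i)

        # the dispersion integrals run over [0, inf): add closed-form
        # corrections for the sliver [0, ext_0] (integrand held at the
        # lowest tabulated value) and the tail (Omega_max, inf) (integrand
        # held at the continuation asymptote).  For the w' theta(w') kernel
        # the tail is log-divergent; its finite part is taken -- the
        # divergent constant is common to all evaluation points and drops
        # out of the anchored differences I(w) - I(w1).
        lo_row = E[0]                                   # continuation at ext_0
        asym_row = mean_row if settings.extrapolation == "taper" else E[-1]
        w_lo, w_hi = ext[0], ext[-1]
        if w_lo > 1e-12 * h:
            sliver1 = (1 / (2 * a)) * np.log((a - w_lo) / (a + w_lo))
            sliver_w = 0.5 * np.log((a**2 - w_lo**2) / a**2)
            self._K_lnamp += np.outer(sliver1, lo_row)
            self._K_wtheta += np.outer(sliver_w, lo_row)
        tail1 = -(1 / (2 * a)) * np.log((w_hi - a) / (w_hi + a))
        tail_w = -0.5 * np.log(1.0 - (a / w_hi) ** 2)
        self._K_lnamp += np.outer(tail1, asym_row)
        self._K_wtheta += np.outer(tail_w, asym_row)

    # -- transforms --------------------------------------------------------

    def phase_from_lnamp(self, lnamp: np.ndarray, theta_anchor: float) -> np.ndarray:
        """theta at the band points from ln|r| tabulated on the full grid,
        anchored to theta(w1) = theta_anchor."""
        i = self._K_lnamp @ lnamp
        return self.omega_band * (
            theta_anchor / self.omega1 + (2.0 / np.pi) * (i - i[self.i1])
        )

    def lnamp_from_phase(self, theta: np.ndarray, lnamp_anchor) -> np.ndarray:
        """ln|r| at the band points from theta tabulated on the full grid,
        anchored to ln|r(w1)| = lnamp_anchor.

        ``theta`` may be (n,) or (n_cand, n); the anchor broadcasts.
        """
        j = theta @ self._K_wtheta.T
        j1 = j[..., self.i1, None] if theta.ndim > 1 else j[self.i1]
        return np.asarray(lnamp_anchor) - (2.0 / np.pi) * (j - j1)

    def consistency_errors(self, lnamp: np.ndarray, theta_cands: np.ndarray) -> np.ndarray:
        """Self-consistency score for one or many candidate phases.

        Builds r_guess = exp(ln|r| + i theta) and r_corrected from the pair
        of SSKK transforms (each anchored on the candidate's own values at
        w1) and returns the L2 norm of the difference over the scoring band,
        normalised by band size.  Inputs are tabulated on the full grid.
        """
        theta_cands = np.atleast_2d(theta_cands)
        bm = self.band_mask
        ib1 = np.flatnonzero(bm)[self.i1]  # anchor index on the full grid
        lnamp_kk = self.lnamp_from_phase(theta_cands, lnamp[ib1])
        i = self._K_lnamp @ lnamp
        theta_kk = self.omega_band[None, :] * (
            theta_cands[:, ib1, None] / self.omega1
            + (2.0 / np.pi) * (i - i[self.i1])[None, :]
        )
        r_guess = np.exp(lnamp[None, bm] + 1j * theta_cands[:, bm])
        r_corr = np.exp(lnamp_kk + 1j * theta_kk)
        return np.sqrt(np.mean(np.abs(r_guess - r_corr) ** 2, axis=1))


# -- module-level wrappers --------------------------------------------------


def sskk_phase(
    omega_band: np.ndarray,
    ln_amp: np.ndarray,
    omega1: float,
    theta1_anchor: float,
    settings: KKSettings | None = None,
) -> np.ndarray:
    """Phase from log-amplitude via the anchored dispersion integral."""
    settings = settings or KKSettings()
    settings = KKSettings(**{**settings.__dict__, "omega1": omega1})
    op = SSKKOperator(omega_band, settings)
    return op.phase_from_lnamp(np.asarray(ln_amp, dtype=float), theta1_anchor)


def sskk_lnamp(
    omega_band: np.ndarray,
    theta: np.ndarray,
    omega1: float,
    lnamp_anchor: float,
    settings: KKSettings | None = None,
) -> np.ndarray:
    """Log-amplitude from phase via the mirror dispersion integral."""
    settings = settings or KKSettings()
    settings = KKSettings(**{**settings.__dict__, "omega1": omega1})
    op = SSKKOperator(omega_band, settings)
    return op.lnamp_from_phase(np.asarray(theta, dtype=float), lnamp_anchor)


def consistency_error(
    omega_band: np.ndarray,
    ln_amp: np.ndarray,
    theta_candidate: np.ndarray,
    settings: KKSettings | None = None,
    op: SSKKOperator | None = None,
) -> float:
    """L2 self-consistency score of an (ln|r|, theta) pair over the band."""
    omega_band = np.asarray(omega_band, dtype=float)
    if omega_band.size < 4:
        raise ValueError("degenerate band: need at least 4 frequencies")
    if op is None:
        op = SSKKOperator(omega_band, settings)
    return float(
        op.consistency_errors(
            np.asarray(ln_amp, dtype=float), np.asarray(theta_candidate, dtype=float)
        )[0]
    )


def _parabolic_vertex(x: np.ndarray, s: np.ndarray, j: int) -> float | None:
    """Vertex of the parabola through points (x[j-1..j+1], s[j-1..j+1])."""
    if j <= 0 or j >= x.size - 1:
        return None
    x1, x2, x3 = x[j - 1], x[j], x[j + 1]
    s1, s2, s3 = s[j - 1], s[j], s[j + 1]
    num = (x2 - x1) ** 2 * (s2 - s3) - (x2 - x3) ** 2 * (s2 - s1)
    den = (x2 - x1) * (s2 - s3) - (x2 - x3) * (s2 - s1)
    if den == 0:
        return None
    v = x2 - 0.5 * num / den
    if not (min(x1, x3) <= v <= max(x1, x3)):
        return None
    return float(v)


def retrieve_phase_offset(r_meas: Spectrum, settings: KKSettings | None = None) -> PhaseOffsetResult:
    """Recover the reference-plane offset dL by scanning candidate phase
    ramps for maximum SSKK self-consistency.

    For each candidate dL the corrected phase theta_meas - omega*n_air*2dL/c
    is scored with the SSKK self-consistency error; a coarse-to-fine
    bracketing (bracket shrink ``settings.shrink`` per level) refines around
    the running minimum until the relative improvement of the best score
    drops below ``settings.epsilon``.  A final three-point parabolic
    interpolation of the smooth score polishes dL below the last grid step.

    ``r_meas`` should be tabulated on the widest trustworthy grid (see
    :func:`thzhybrid.pipeline.analysis_transfer_function`): the dispersion
    integrals use every tabulated point, while the consistency norm is
    restricted to ``r_meas.band``.  Its phase must be on the branch that
    vanishes at DC -- use the transfer function itself, not the raw
    reflectivity of a denser-than-air sample (which carries a constant pi).
    """
    settings = settings or KKSettings()
    omega = r_meas.omega
    lnamp = np.log(np.abs(r_meas.value))
    theta_meas = unwrap_phase(r_meas)
    op = SSKKOperator(omega, settings, band=r_meas.band)
    ramp = 2.0 * settings.n_air * omega / C_LIGHT  # phase per metre of offset

    lo0, hi0 = settings.offset_range
    lo, hi = lo0, hi0
    best_dl = None
    best_score = np.inf
    history: list[float] = []
    boundary = False
    converged = False
    iterations = 0
    last_cands = last_scores = None

    for level in range(settings.max_iterations):
        cands = np.linspace(lo, hi, settings.n_candidates)
        if best_dl is not None and not np.any(np.isclose(cands, best_dl)):
            cands = np.sort(np.append(cands, best_dl))
        thetas = theta_meas[None, :] - ramp[None, :] * cands[:, None]
        scores = op.consistency_errors(lnamp, thetas)
        smin = scores.min()
        ties = np.flatnonzero(scores <= smin * (1 + 1e-12))
        i = ties[np.argmin(np.abs(cands[ties]))]  # tie-break: smaller |dL|
        iterations = level + 1
        last_cands, last_scores = cands, scores

        if level == 0 and i in (0, cands.size - 1):
            boundary = True
            warnings.warn("offset grid likely too narrow: minimum at bracket edge")

        improved = scores[i] < best_score
        rel_imp = (
            (best_score - scores[i]) / best_score if np.isfinite(best_score) and best_score > 0
            else np.inf
        )
        if improved:
            best_score = float(scores[i])
            best_dl = float(cands[i])
        history.append(best_score)

        if level > 0 and rel_imp < settings.epsilon:
            converged = True
            break

        half = (hi0 - lo0) / 2.0 / settings.shrink ** (level + 1)
        lo = max(lo0, best_dl - half)
        hi = min(hi0, best_dl + half)

    # parabolic polish on the finest level
    order = np.argsort(last_cands)
    xs, ss = last_cands[order], last_scores[order]
    j = int(np.argmin(ss))
    vertex = _parabolic_vertex(xs, ss, j)
    if vertex is not None:
        theta_v = theta_meas - ramp * vertex
        s_v = float(op.consistency_errors(lnamp, theta_v)[0])
        if s_v <= best_score:
            best_dl, best_score = vertex, s_v
            history.append(best_score)

    delta_theta = ramp * best_dl
    return PhaseOffsetResult(
        delta_L=best_dl,
        omega=omega,
        delta_theta=delta_theta,
        corrected_phase=theta_meas - delta_theta,
        iterations=iterations,
        consistency_history=history,
        converged=converged,
        boundary_warning=boundary,
        omega1=op.omega1,
    )


def offset_to_thickness(result: PhaseOffsetResult, atol: float = 1e-8) -> float:
    """Reinterpret the recovered plane offset as the layer-2 thickness.

    Valid for the sample-on-reference geometry in which the bare reference
    surface is the sample's back face, so the plane offset equals the sample
    thickness.  Small negative offsets within ``atol`` are clamped to zero.
    """
    dl = result.delta_L
    if dl < -atol:
        raise ValueError(f"negative plane offset {dl:.3e} m cannot be a thickness")
    if dl <= atol:
        warnings.warn("no sample layer: recovered offset is zero within tolerance")
        return 0.0
    return dl
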