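"""Trapezoidal-cosine OGSE gradient waveforms and their encoding spectra.

An oscillating-gradient spin-echo (OGSE) acquisition encodes diffusion with
two symmetric groups of trapezoidal cosine lobes separated by a mixing
interval that accommodates the refocusing pulse.  Each encoding block carries
``N`` oscillation cycles at a nominal input frequency ``f0``: a leading
quarter-cycle lobe, ``2N - 1`` alternating half-cycle lobes, and a trailing
quarter-cycle lobe, with opposite-sign plateaus joined by linear transitions.
The refocusing pulse is absorbed into the effective-gradient formalism: the
physically played second block is the inverted copy of the first, so the
*effective* gradient repeats the first block and the dephasing trajectory
``q(t)`` consists of two identical bursts.

The operational frequency of a waveform is not the input frequency but the
location of the maximum of the encoding power spectrum ``|q_w|^2``, which the
two-burst interference structure shifts and sharpens; the mixing time is the
design variable that controls that interference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import next_fast_len, rfft, rfftfreq

__all__ = [
    "GAMMA",
    "WaveformSpec",
    "GradientWaveform",
    "EncodingSpectrum",
    "EffectiveTime",
    "build_waveform",
    "compute_spectrum",
    "solve_amplitude_for_b",
    "optimize_mixing_time",
    "effective_diffusion_time",
]

#: Gyromagnetic ratio of the proton, rad s^-1 T^-1.
GAMMA = 2.6752e8

# Internal unit system: time in ms, gradient in mT/m.
# q = _GAMMA_MS_MT * integral(G dt)  ->  rad/mm
_GAMMA_MS_MT = GAMMA * 1e-6 * 1e-3 * 1e3 * 1e-3  # = 0.26752 rad/mm per (mT/m * ms)
# b = _B_SCALE * integral(q^2 dt)  with q in rad/mm, t in ms  ->  ms/um^2
_B_SCALE = 1e-6

#: Zero-padding target for spectra: equivalent duration in ms, giving a
#: frequency resolution of 1/8000 ms = 0.125 Hz.
_PAD_DURATION_MS = 8000.0


@dataclass(frozen=True)
class WaveformSpec:
    """Parametric description of one trapezoidal-cosine OGSE waveform.

    Parameters
    ----------
    input_frequency : float
        Nominal oscillation frequency ``f0`` in Hz.
    n_oscillations : int
        Number of oscillation cycles ``N`` per encoding block.
    mixing_time : float
        Gap ``tM`` between the two encoding blocks, ms.
    ramp_time : float
        Gradient rise time ``tR``, ms.  Fixed by design at 1.6 ms
        independent of amplitude.
    gradient_amplitude : float
        Plateau gradient amplitude ``G``, mT/m.
    max_gradient : float
        Hardware gradient bound, mT/m.
    max_slew : float
        Hardware slew-rate bound, T/m/s.
    raster : float
        Sampling step, ms.
    """

    input_frequency: float
    n_oscillations: int
    mixing_time: float
    ramp_time: float = 1.6
    gradient_amplitude: float = 1.0
    max_gradient: float = 500.0
    max_slew: float = 300.0
    raster: float = 0.01
    label: str | None = None

    def __post_init__(self) -> None:
        if self.input_frequency <= 0:
            raise ValueError("input_frequency must be positive")
        if self.n_oscillations < 1 or self.n_oscillations != int(self.n_oscillations):
            raise ValueError("n_oscillations must be a positive integer")
        if self.mixing_time < 0:
            raise ValueError("mixing_time must be non-negative")
        if self.ramp_time <= 0:
            raise ValueError("ramp_time must be positive")
        if self.gradient_amplitude > self.max_gradient:
            raise ValueError(
                f"gradient_amplitude {self.gradient_amplitude:.1f} mT/m exceeds "
                f"max_gradient {self.max_gradient:.1f} mT/m"
            )
        if self.quarter_plateau <= 0:
            raise ValueError(
                f"input frequency {self.input_frequency:g} Hz is too high for "
                f"ramp time {self.ramp_time:g} ms: quarter-lobe plateau "
                f"p1 = 1/(4 f0) - 1.5 tR = {self.quarter_plateau:.3f} ms <= 0"
            )
        # slew during the plateau-to-plateau transition: 2G over 2 tR
        slew = self.gradient_amplitude / self.ramp_time  # mT/m/ms == T/m/s
        if slew > self.max_slew:
            raise ValueError(
                f"slew rate {slew:.1f} T/m/s exceeds max_slew {self.max_slew:.1f}"
            )

    @property
    def quarter_plateau(self) -> float:
        """Plateau time of the quarter-cycle lobes, ``p1 = 1/(4 f0) - 1.5 tR`` (ms)."""
        return 1000.0 / (4.0 * self.input_frequency) - 1.5 * self.ramp_time

    @property
    def half_plateau(self) -> float:
        """Plateau time of the half-cycle lobes, ``p2 = 1/(2 f0) - 2 tR`` (ms)."""
        return 1000.0 / (2.0 * self.input_frequency) - 2.0 * self.ramp_time

    @property
    def block_duration(self) -> float:
        """Per-block duration ``N/f0 + tR`` (ms)."""
        return 1000.0 * self.n_oscillations / self.input_frequency + self.ramp_time

    @property
    def total_duration(self) -> float:
        """Total encoding time ``T = 2 (N/f0 + tR) + tM`` (ms)."""
        return 2.0 * self.block_duration + self.mixing_time

    @property
    def name(self) -> str:
        return self.label or f"{self.input_frequency:g}Hz-N{self.n_oscillations}"


@dataclass(frozen=True)
class GradientWaveform:
    """Sampled effective gradient of one OGSE waveform.

    The effective gradient already accounts for the refocusing pulse: both
    encoding blocks appear with the same sign and the gradient is identically
    zero during the mixing interval.  The exact piecewise-linear breakpoints
    are retained so that q(t) can be integrated analytically (q is piecewise
    quadratic), keeping the refocusing balance exact to rounding rather than
    to raster resolution.
    """

    spec: WaveformSpec
    times: np.ndarray          # ms, uniform grid spanning [0, T]
    effective_gradient: np.ndarray  # mT/m
    total_duration: float      # ms
    block_duration: float      # ms
    breakpoints: tuple[np.ndarray, np.ndarray] = None  # (t, G) polyline nodes

    def __post_init__(self) -> None:
        if self.times.shape != self.effective_gradient.shape:
            raise ValueError("times and effective_gradient must have equal length")


@dataclass(frozen=True)
class EncodingSpectrum:
    """Dephasing trajectory q(t) and its power spectrum for one waveform.

    Attributes
    ----------
    q_of_t : ndarray
        Sampled ``q(t) = gamma * integral G(t') dt'`` in rad/mm.
    b_value : float
        Diffusion weighting ``b = integral q(t)^2 dt`` in ms/um^2.
    frequencies : ndarray
        Spectral grid in Hz (non-negative half; q is real so the spectrum is
        symmetric).
    power : ndarray
        ``|q_w|^2`` on that grid.
    peak_frequency : float
        Parabolic-refined argmax of the power spectrum, Hz.
    v_omega : float
        Dispersion factor ``V_w = (1/b) * integral dnu |q_nu|^2 sqrt(nu)``
        with cyclic frequency nu in 1/ms; units ms^(-1/2).  This converts the
        sqrt(frequency) diffusivity dispersion of short-range structural
        disorder into an apparent diffusivity shift for the realised
        waveform.  The cyclic-frequency convention is the one under which the
        reported tissue parameter medians reproduce the observed
        gray-matter kurtosis increase across the one-oscillation series; an
        angular convention would only rescale the disorder coefficient by
        sqrt(2 pi).
    """

    waveform: GradientWaveform
    q_of_t: np.ndarray
    b_value: float
    frequencies: np.ndarray
    power: np.ndarray
    peak_frequency: float
    v_omega: float

    @property
    def label(self) -> str:
        return self.waveform.spec.name

    @property
    def times(self) -> np.ndarray:
        return self.waveform.times


@dataclass(frozen=True)
class EffectiveTime:
    """Effective diffusion time of an OGSE waveform in the slow-exchange limit."""

    regime: str   # "fixed_T" or "fixed_N"
    value: float  # ms


def _block_breakpoints(spec: WaveformSpec, t0: float) -> tuple[list[tuple[float, float]], float]:
    """Piecewise-linear breakpoints of one encoding block starting at t0.

    Lobe sequence: quarter (+), 2N-1 alternating halves, trailing quarter of
    sign opposite to the last half lobe.  Opposite-sign plateaus are joined by
    linear transitions of duration 2 tR.
    """
    g = spec.gradient_amplitude
    tr = spec.ramp_time
    p1 = spec.quarter_plateau
    p2 = spec.half_plateau
    plateaus = [p1] + [p2] * (2 * spec.n_oscillations - 1) + [p1]
    pts: list[tuple[float, float]] = [(t0, 0.0)]
    t = t0 + tr
    sign = 1.0
    pts.append((t, sign * g))
    for i, p in enumerate(plateaus):
        t += p
        pts.append((t, sign * g))
        if i < len(plateaus) - 1:
            sign = -sign
            t += 2.0 * tr
            pts.append((t, sign * g))
    t += tr
    pts.append((t, 0.0))
    return pts, t


def build_waveform(spec: WaveformSpec) -> GradientWaveform:
    """Construct the sampled effective gradient for a waveform specification.

    The second block is the time-shifted copy of the first: the physical
    gradient of the second block is played with inverted polarity and the
    180-degree refocusing pulse (modelled purely as a sign flip) restores it,
    so both effective blocks have the same sign and each block's signed area
    is zero (q returns to zero at each block's end).

    Raises
    ------
    ValueError
        If the spec is invalid (negative plateau at too-high frequency, slew
        violation, amplitude above the hardware bound).
    """
    dt = spec.raster
    b1, t_end1 = _block_breakpoints(spec, 0.0)
    b2, t_end2 = _block_breakpoints(spec, t_end1 + spec.mixing_time)
    tp = np.array([p[0] for p in b1 + b2])
    gp = np.array([p[1] for p in b1 + b2])
    n = int(math.ceil(t_end2 / dt - 1e-9)) + 1
    times = np.arange(n) * dt
    grad = np.interp(times, tp, gp)
    return GradientWaveform(
        spec=spec,
        times=times,
        effective_gradient=grad,
        total_duration=t_end2,
        block_duration=t_end1,
        breakpoints=(tp, gp),
    )


def _polyline_q(times: np.ndarray, tp: np.ndarray, gp: np.ndarray) -> np.ndarray:
    """Exact cumulative integral of a piecewise-linear gradient at sample times.

    q is piecewise quadratic; evaluating it analytically keeps the zero net
    dephasing of each balanced block exact to rounding, independent of how
    the breakpoints fall relative to the raster.
    """
    t = np.clip(times, tp[0], tp[-1])  # hold q constant beyond the last node
    node_q = np.concatenate([[0.0], np.cumsum(0.5 * (gp[1:] + gp[:-1]) * np.diff(tp))])
    idx = np.clip(np.searchsorted(tp, t, side="right") - 1, 0, len(tp) - 2)
    t0, t1 = tp[idx], tp[idx + 1]
    g0, g1 = gp[idx], gp[idx + 1]
    frac = np.where(t1 > t0, (t - t0) / np.where(t1 > t0, t1 - t0, 1.0), 0.0)
    g_here = g0 + (g1 - g0) * frac
    return node_q[idx] + 0.5 * (g0 + g_here) * (t - t0)


def _q_trajectory(waveform: GradientWaveform, gamma: float) -> np.ndarray:
    """q(t) in rad/mm by exact integration of the breakpoint polyline."""
    scale = gamma / GAMMA * _GAMMA_MS_MT
    if waveform.breakpoints is not None:
        tp, gp = waveform.breakpoints
        return _polyline_q(waveform.times, tp, gp) * scale
    g = waveform.effective_gradient
    dt = waveform.spec.raster
    q = np.empty_like(g)
    q[0] = 0.0
    np.cumsum((g[1:] + g[:-1]) * (0.5 * dt), out=q[1:])
    return q * scale


def compute_spectrum(waveform: GradientWaveform, gamma: float = GAMMA) -> EncodingSpectrum:
    """Compute q(t), the b-value, the power spectrum, its peak and V_w.

    The spectrum is a zero-padded discrete Fourier transform of q(t) with a
    frequency resolution of 0.125 Hz; the peak location is refined by 3-point
    parabolic interpolation.

    Raises
    ------
    ValueError
        If q does not return to zero at the end of the waveform (broken
        refocusing balance).
    """
    dt = waveform.spec.raster
    q = _q_trajectory(waveform, gamma)
    qmax = float(np.max(np.abs(q)))
    if qmax > 0 and abs(q[-1]) > 1e-6 * qmax:
        raise ValueError(
            f"q(T) = {q[-1]:.3e} rad/mm does not return to zero "
            f"(max |q| = {qmax:.3e}): refocusing balance is broken"
        )
    b_time = float(np.trapezoid(q * q, dx=dt)) * _B_SCALE

    n = next_fast_len(int(math.ceil(_PAD_DURATION_MS / dt)))
    qw = rfft(q, n=n) * dt
    freqs_hz = rfftfreq(n, d=dt) * 1000.0
    power = np.abs(qw) ** 2

    i = int(np.argmax(power))
    if 0 < i < len(power) - 1:
        y0, y1, y2 = power[i - 1], power[i], power[i + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    df = freqs_hz[1] - freqs_hz[0]
    peak = float(freqs_hz[i] + delta * df)

    nu = freqs_hz / 1000.0  # cyclic frequency, 1/ms
    v_omega = float(np.sum(power * np.sqrt(nu)) / np.sum(power))
    return EncodingSpectrum(
        waveform=waveform,
        q_of_t=q,
        b_value=b_time,
        frequencies=freqs_hz,
        power=power,
        peak_frequency=peak,
        v_omega=v_omega,
    )


def spectral_b_value(spectrum: EncodingSpectrum) -> float:
    """b-value from the spectral integral (Parseval route), ms/um^2.

    ``b = integral dw/2pi |q_w|^2`` over both frequency signs; used to check
    consistency with the time-domain integral.
    """
    df_ms = (spectrum.frequencies[1] - spectrum.frequencies[0]) / 1000.0
    p = spectrum.power
    total = (p[0] + 2.0 * np.sum(p[1:])) * df_ms
    return float(total) * _B_SCALE


def solve_amplitude_for_b(spec: WaveformSpec, b_target: float) -> float:
    """Gradient amplitude (mT/m) achieving a target b-value (ms/um^2).

    The lobe timing is amplitude-independent (fixed ramp time), so b scales
    exactly as G^2 and the solution is closed-form from the unit-amplitude
    b-value.

    Raises
    ------
    ValueError
        If the required amplitude exceeds the hardware bound.
    """
    if b_target <= 0:
        raise ValueError("b_target must be positive")
    unit = replace(spec, gradient_amplitude=1.0)
    b_unit = compute_spectrum(build_waveform(unit)).b_value
    g = math.sqrt(b_target / b_unit)
    if g > spec.max_gradient:
        raise ValueError(
            f"b = {b_target:g} ms/um^2 requires G = {g:.1f} mT/m, exceeding "
            f"the hardware bound {spec.max_gradient:.0f} mT/m by "
            f"{g - spec.max_gradient:.1f} mT/m"
        )
    return g


def _single_block_power(spec: WaveformSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Power spectrum of one encoding block's q-burst and the block duration.

    The full-waveform spectrum factorises exactly as
    ``|Q(f)|^2 = |B(f)|^2 * 2 (1 + cos(2 pi f Delta))`` with ``Delta`` the
    block start-to-start separation, because the effective gradient is two
    identical bursts.  This makes mixing-time searches O(grid) instead of one
    FFT per candidate.
    """
    dt = spec.raster
    pts, t_end = _block_breakpoints(spec, 0.0)
    tp = np.array([p[0] for p in pts])
    gp = np.array([p[1] for p in pts])
    n_samp = int(math.ceil(t_end / dt - 1e-9)) + 1
    times = np.arange(n_samp) * dt
    q = _polyline_q(times, tp, gp)
    n = next_fast_len(int(math.ceil(_PAD_DURATION_MS / dt)))
    qw = rfft(q, n=n) * dt
    freqs_hz = rfftfreq(n, d=dt) * 1000.0
    power = np.abs(qw) ** 2
    # truncate where the envelope is negligible; the fringe factor is bounded by 4
    cutoff = np.max(power) * 1e-10
    keep = np.nonzero(power > cutoff)[0]
    hi = int(keep[-1]) + 2 if len(keep) else len(power)
    return freqs_hz[:hi], power[:hi], t_end


def _peak_to_side_lobe(power: np.ndarray) -> float:
    """Ratio of the main-lobe peak to the largest side-lobe maximum.

    The main lobe is delimited by the first local minima flanking the global
    maximum of the power spectrum; the side-lobe amplitude is the largest
    value outside that interval.
    """
    i = int(np.argmax(power))
    lo = i
    while lo > 0 and power[lo - 1] < power[lo]:
        lo -= 1
    hi = i
    while hi < len(power) - 1 and power[hi + 1] < power[hi]:
        hi += 1
    side = 0.0
    if lo > 0:
        side = float(np.max(power[:lo]))
    if hi < len(power) - 1:
        side = max(side, float(np.max(power[hi + 1:])))
    if side == 0.0:
        return math.inf
    return float(power[i]) / side


def mixing_time_objective(spec: WaveformSpec, mixing_times: np.ndarray) -> np.ndarray:
    """Peak-to-side-lobe ratio of |q_w|^2 for each candidate mixing time."""
    freqs, env, block = _single_block_power(replace(spec, mixing_time=0.0))
    f_ms = freqs / 1000.0  # cycles/ms
    out = np.empty(len(mixing_times))
    for k, tm in enumerate(mixing_times):
        delta = block + tm
        fringe = 2.0 * (1.0 + np.cos(2.0 * np.pi * f_ms * delta))
        out[k] = _peak_to_side_lobe(env * fringe)
    return out


def optimize_mixing_time(
    spec: WaveformSpec,
    search_range: tuple[float, float] = (7.4, 45.0),
    resolution: float = 0.1,
) -> float:
    """Optimal mixing time by the peak-to-side-lobe criterion (ms).

    A grid search over the scanner-feasible range maximises the ratio of the
    main spectral peak of ``|q_w|^2`` to its largest side lobe.  The returned
    value is the best *interior* local maximum of the ratio on the grid: at
    short mixing times the interference fringes of low-frequency waveforms
    merge into one wide main lobe and the raw ratio diverges toward the lower
    search bound, which does not correspond to a usable single-fringe
    spectrum.  Ties break toward smaller mixing time.  If the grid has no
    interior local maximum, the global grid maximum is returned.
    """
    lo, hi = search_range
    if hi < lo:
        raise ValueError(f"empty mixing-time search range [{lo}, {hi}]")
    grid = lo + resolution * np.arange(int(math.floor((hi - lo) / resolution + 1e-9)) + 1)
    if len(grid) == 0:
        raise ValueError("mixing-time search grid is empty")
    vals = mixing_time_objective(spec, grid)
    best_idx: int | None = None
    for k in range(1, len(grid) - 1):
        if vals[k] >= vals[k - 1] and vals[k] >= vals[k + 1]:
            if best_idx is None or vals[k] > vals[best_idx]:
                best_idx = k
    if best_idx is None:
        best_idx = int(np.argmax(vals))
    return float(grid[best_idx])


def effective_diffusion_time(
    regime: str,
    omega_p: float,
    total_duration: float | None = None,
    n_oscillations: int | None = None,
) -> EffectiveTime:
    """Effective diffusion time of an OGSE waveform in the slow-exchange limit.

    Parameters
    ----------
    regime : {"fixed_T", "fixed_N"}
        Whether frequency is varied at constant total time T or constant
        oscillation count N.
    omega_p : float
        Peak angular frequency in rad/ms.
    total_duration : float
        T in ms (fixed_T regime).
    n_oscillations : int
        N (fixed_N regime).

    Notes
    -----
    fixed_T:  ``D_eff = T (1 - (15/4) / (w_p^2 T^2))``
    fixed_N:  ``D_eff = (2 pi N / w_p) (1 - (15 / (16 pi^2)) / N^2)``
    """
    if omega_p <= 0:
        raise ValueError("omega_p must be positive")
    if regime == "fixed_T":
        if total_duration is None or total_duration <= 0:
            raise ValueError("fixed_T regime requires a positive total_duration")
        value = total_duration * (1.0 - 3.75 / (omega_p**2 * total_duration**2))
        if value <= 0:
            raise ValueError(
                f"omega_p * T = {omega_p * total_duration:.3f} is too small: "
                "the effective diffusion time is non-positive"
            )
    elif regime == "fixed_N":
        if n_oscillations is None or n_oscillations < 1:
            raise ValueError("fixed_N regime requires n_oscillations >= 1")
        value = (2.0 * np.pi * n_oscillations / omega_p) * (
            1.0 - 15.0 / (16.0 * np.pi**2 * n_oscillations**2)
        )
    else:
        raise ValueError(f"unknown regime {regime!r}; expected 'fixed_T' or 'fixed_N'")
    return EffectiveTime(regime=regime, value=float(value))
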