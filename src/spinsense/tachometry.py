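"""Rotational-speed estimation from phone sensor traces.

Two complementary tachometers are implemented, mirroring how a phone can
measure the speed of a spinning disc with no extra electronics:

* **acoustic** — a hole in the disc emits one pressure event per revolution;
  a short (default 100 ms) microphone window sampled at 48 kHz is
  autocorrelated and the fundamental period read off the strongest
  autocorrelation peak.
* **magnetic** — a small magnet on the disc sweeps past the phone's
  magnetometer once per revolution; the latest 256 samples of the 50 Hz
  field signal are Fourier transformed and the peak bin (excluding DC)
  gives the rotation frequency.

The magnetometer's low sampling rate caps its unaliased range at
``rate/2`` Hz (1500 RPM at 50 Hz); above that the spectrum folds and the
estimator can only report the alias. Both estimators refine their raw
peak by three-point parabolic interpolation and carry a validity flag so
that :func:`fuse_estimates` can combine them over their useful ranges
(magnetic 0–1500 RPM, acoustic above 1000 RPM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InvalidArgument

__all__ = [
    "SensorTrace",
    "SamplingSpec",
    "SpinEstimate",
    "nyquist_limit",
    "estimate_rpm_acoustic",
    "estimate_rpm_magnetic",
    "fuse_estimates",
    "track_rpm",
]

#: Lags shorter than rate/MAX_DETECTABLE_HZ samples are excluded from the
#: autocorrelation search; caps the detectable fundamental at 200 Hz
#: (12000 RPM), far above any disc speed, while skipping the zero-lag lobe.
MAX_DETECTABLE_HZ = 200.0

#: Magnetic estimates within this fraction of the Nyquist RPM are flagged
#: invalid (observed breakdown of the magnetometer approaching 1500 RPM).
NYQUIST_GUARD = 0.05

#: Overlap band (RPM) in which both tachometers are trusted and fused.
FUSION_OVERLAP = (1000.0, 1500.0)


@dataclass(frozen=True)
class SensorTrace:
    """A uniformly sampled 1-D sensor signal.

    Parameters
    ----------
    samples
        Signal values — microtesla for magnetometer traces, normalized
        amplitude in [-1, 1] for audio.
    sampling_rate
        Samples per second (Hz); must be positive.
    kind
        ``"audio"`` or ``"magnetic"``; selects the matching estimator.
    """

    samples: np.ndarray
    sampling_rate: float
    kind: Literal["audio", "magnetic"]

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise InvalidArgument("sampling_rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise InvalidArgument("trace needs at least 2 samples in 1-D")
        if self.kind not in ("audio", "magnetic"):
            raise InvalidArgument(f"unknown trace kind {self.kind!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class SamplingSpec:
    """Nyquist bound of a sensor: f_sampling >= 2 * f_signal,max."""

    sampling_rate: float
    max_signal_frequency: float
    max_measurable_rpm: float


@dataclass(frozen=True)
class SpinEstimate:
    """A single rotational-speed estimate.

    ``rpm = 60 * frequency`` always holds. ``resolution_rpm`` is the RPM
    step corresponding to one quantization step of the underlying method
    (one FFT bin, or one sample of autocorrelation lag). ``peak_strength``
    is the method's unitless quality score (normalized autocorrelation
    value, or spectral peak over median-magnitude ratio); estimates whose
    score falls below the method's quality floor carry ``valid=False``.
    """

    rpm: float
    frequency: float
    method: Literal["acoustic", "magnetic", "fused"]
    resolution_rpm: float
    valid: bool
    peak_strength: float = 0.0


def _invalid(method: str, resolution_rpm: float = 1.0) -> SpinEstimate:
    return SpinEstimate(
        rpm=0.0,
        frequency=0.0,
        method=method,
        resolution_rpm=resolution_rpm,
        valid=False,
        peak_strength=0.0,
    )


def nyquist_limit(sampling_rate: float) -> SamplingSpec:
    """Maximum unaliased signal frequency (and RPM) at a sampling rate.

    A periodic signal must be sampled at more than twice its highest
    frequency component; a 50 Hz magnetometer can therefore follow
    rotation only below 25 Hz, i.e. 1500 RPM.
    """
    if sampling_rate <= 0:
        raise InvalidArgument("sampling_rate must be positive")
    f_max = sampling_rate / 2.0
    return SamplingSpec(
        sampling_rate=sampling_rate,
        max_signal_frequency=f_max,
        max_measurable_rpm=60.0 * f_max,
    )


def _parabolic_refine(y_minus: float, y0: float, y_plus: float) -> float:
    """Sub-step offset of a peak from three equally spaced ordinates.

    Returns the vertex offset in [-0.5, 0.5]; 0 when the parabola is
    degenerate (flat top).
    """
    denom = y_minus - 2.0 * y0 + y_plus
    if denom == 0:
        return 0.0
    delta = 0.5 * (y_minus - y_plus) / denom
    return float(np.clip(delta, -0.5, 0.5))


#: Fraction of the window beyond which autocorrelation lags are not
#: searched (too few overlapping samples to trust the unbiased estimate).
_MAX_LAG_FRACTION = 0.8

#: An autocorrelation peak within this fraction of the strongest peak is
#: a period candidate; the shortest such lag wins (guards against octave
#: errors toward period multiples).
_PEAK_TOLERANCE = 0.8

#: Highest harmonic order modelled by the least-squares refinement.
_MAX_HARMONICS = 24


def _refine_fundamental(
    x: np.ndarray, rate: float, f0: float, max_harmonics: int = _MAX_HARMONICS
) -> float:
    """Refine a fundamental-frequency estimate by harmonic least squares.

    Golden-section minimization of the residual of fitting an intercept
    plus cosine/sine pairs at harmonics of f over f in [0.97, 1.03]*f0.
    For a noiseless periodic signal whose harmonics are all modelled the
    minimizer is the exact fundamental, immune to the window-truncation
    bias that displaces raw autocorrelation peaks.
    """
    n = x.size
    t = np.arange(n) / rate

    def residual(f: float) -> float:
        k = np.arange(1, max(1, min(max_harmonics, int(0.45 * rate / f))) + 1)
        phases = 2.0 * np.pi * np.outer(t, k * f)
        A = np.hstack([np.ones((n, 1)), np.cos(phases), np.sin(phases)])
        coef, *_ = np.linalg.lstsq(A, x, rcond=None)
        return float(((x - A @ coef) ** 2).sum())

    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = 0.97 * f0, 1.03 * f0
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = residual(c), residual(d)
    for _ in range(30):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = residual(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = residual(d)
    return 0.5 * (a + b)


def estimate_rpm_acoustic(
    trace: SensorTrace,
    window_ms: float = 100.0,
    quality_floor: float = 0.3,
    refine: bool = True,
) -> SpinEstimate:
    """Estimate RPM from the autocorrelation of an audio window.

    The latest ``window_ms`` of the trace is mean-removed and
    autocorrelated; the unbiased normalized autocorrelation (taper
    divided out) is searched for its first major peak beyond the
    zero-lag lobe — the shortest lag within 80 % of the strongest peak,
    which pins the fundamental rather than a period multiple. The peak
    is refined by three-point parabolic interpolation and then, when
    ``refine`` is set, polished by harmonic least squares
    (:func:`_refine_fundamental`), which removes the residual bias a
    window holding only a few revolutions imposes on the raw peak;
    ``rpm = 60 * rate / lag``. Windows whose best normalized peak falls
    below ``quality_floor`` (default 0.3) are returned with
    ``valid=False`` — silence and aperiodic noise are rejected rather
    than raised.
    """
    if trace.kind != "audio":
        raise InvalidArgument("estimate_rpm_acoustic requires an audio trace")
    n_win = int(round(window_ms * 1e-3 * trace.sampling_rate))
    if n_win < 4:
        raise InvalidArgument("window too short")
    if n_win > trace.samples.size:
        raise InvalidArgument(
            f"window of {n_win} samples longer than trace ({trace.samples.size})"
        )
    x = trace.samples[-n_win:].astype(float)
    x = x - x.mean()
    rate = trace.sampling_rate

    # autocorrelation via FFT, then the taper divided out (unbiased)
    nfft = int(2 ** np.ceil(np.log2(2 * n_win)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec), nfft)[:n_win].real
    if r[0] <= 1e-300:
        return _invalid("acoustic")
    max_lag = int(_MAX_LAG_FRACTION * n_win)
    lags = np.arange(max_lag)
    nacf = (r[:max_lag] / (n_win - lags)) / (r[0] / n_win)

    min_lag = max(2, int(np.ceil(rate / MAX_DETECTABLE_HZ)))
    if min_lag >= max_lag - 1:
        return _invalid("acoustic")
    seg = nacf[min_lag : max_lag - 1]
    local_max = np.nonzero((seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:]))[0]
    if local_max.size == 0:
        return _invalid("acoustic")
    local_max = local_max + 1 + min_lag
    strongest = float(nacf[local_max].max())
    peak = int(local_max[nacf[local_max] >= _PEAK_TOLERANCE * strongest].min())
    strength = float(nacf[peak])

    lag = peak + _parabolic_refine(nacf[peak - 1], nacf[peak], nacf[peak + 1])
    freq = rate / lag
    if refine:
        freq = _refine_fundamental(x, rate, freq)
    rpm = 60.0 * freq
    # RPM change for a one-sample lag error at this operating point
    resolution = 60.0 * rate / peak - 60.0 * rate / (peak + 1)
    valid = strength >= quality_floor
    return SpinEstimate(
        rpm=rpm,
        frequency=freq,
        method="acoustic",
        resolution_rpm=resolution,
        valid=valid,
        peak_strength=strength,
    )


def estimate_rpm_magnetic(
    trace: SensorTrace,
    n_fft: int = 256,
    quality_ratio: float = 5.0,
) -> SpinEstimate:
    """Estimate RPM from the FFT peak of a magnetometer window.

    The latest ``n_fft`` samples are mean-removed (rectangular window)
    and the magnitude spectrum's highest non-DC bin, refined by parabolic
    interpolation over the adjacent bin magnitudes, gives the rotation
    frequency. ``resolution_rpm = 60 * rate / n_fft`` (11.7 RPM for 256
    points at 50 Hz). The estimate is invalid when the peak magnitude is
    below ``quality_ratio`` times the median non-DC magnitude (no clear
    line in the spectrum) or when the refined RPM enters the Nyquist
    guard band (within 5 % of ``60 * rate / 2``), where the magnetometer
    is known to break down.
    """
    if trace.kind != "magnetic":
        raise InvalidArgument("estimate_rpm_magnetic requires a magnetic trace")
    if n_fft < 8:
        raise InvalidArgument("n_fft must be at least 8")
    if trace.samples.size < n_fft:
        raise InvalidArgument(
            f"trace has {trace.samples.size} samples, fewer than n_fft={n_fft}"
        )
    rate = trace.sampling_rate
    resolution = 60.0 * rate / n_fft
    x = trace.samples[-n_fft:].astype(float)
    x = x - x.mean()
    mags = np.abs(np.fft.rfft(x))
    if mags.size < 3:
        return _invalid("magnetic", resolution)
    nondc = mags[1:]
    peak = int(np.argmax(nondc)) + 1
    strength_abs = float(mags[peak])
    med = float(np.median(nondc))
    if strength_abs <= 1e-300:
        return _invalid("magnetic", resolution)
    strength = strength_abs / med if med > 0 else np.inf

    lo = mags[peak - 1]
    hi = mags[peak + 1] if peak + 1 < mags.size else 0.0
    bin_refined = peak + _parabolic_refine(lo, mags[peak], hi)
    freq = bin_refined * rate / n_fft
    rpm = 60.0 * freq

    guard_rpm = (1.0 - NYQUIST_GUARD) * nyquist_limit(rate).max_measurable_rpm
    valid = bool(strength >= quality_ratio and rpm <= guard_rpm)
    return SpinEstimate(
        rpm=rpm,
        frequency=freq,
        method="magnetic",
        resolution_rpm=resolution,
        valid=valid,
        peak_strength=strength if np.isfinite(strength) else strength_abs,
    )


def fuse_estimates(acoustic: SpinEstimate, magnetic: SpinEstimate) -> SpinEstimate:
    """Combine simultaneous acoustic and magnetic estimates.

    The magnetic tachometer works best from 0 to 1500 RPM and the
    acoustic one above 1000 RPM. A single valid estimate passes through
    unchanged. When both are valid inside the overlap band
    [1000, 1500] RPM, the fused value is the inverse-resolution-weighted
    mean; otherwise the sensor whose range covers the reading wins
    (magnetic below 1000 RPM, acoustic above 1500 RPM).
    """
    if acoustic.valid and not magnetic.valid:
        return acoustic
    if magnetic.valid and not acoustic.valid:
        return magnetic
    if not acoustic.valid and not magnetic.valid:
        return _invalid("fused")

    lo, hi = FUSION_OVERLAP
    both_in_overlap = lo <= acoustic.rpm <= hi and lo <= magnetic.rpm <= hi
    if both_in_overlap:
        w_a = 1.0 / acoustic.resolution_rpm
        w_m = 1.0 / magnetic.resolution_rpm
        rpm = (w_a * acoustic.rpm + w_m * magnetic.rpm) / (w_a + w_m)
        return SpinEstimate(
            rpm=rpm,
            frequency=rpm / 60.0,
            method="fused",
            resolution_rpm=1.0 / (w_a + w_m),
            valid=True,
            peak_strength=min(acoustic.peak_strength, magnetic.peak_strength),
        )
    midpoint = 0.5 * (acoustic.rpm + magnetic.rpm)
    return magnetic if midpoint < lo else acoustic


def track_rpm(
    trace: SensorTrace,
    hop: float,
    window_ms: float = 100.0,
    n_fft: int = 256,
) -> list[tuple[float, SpinEstimate]]:
    """Sliding-window RPM track: one estimate per ``hop`` seconds.

    The estimator matching ``trace.kind`` is applied to consecutive
    windows (audio: ``window_ms``; magnetic: ``n_fft`` samples); each
    entry is timestamped with the window's end time. A trace shorter
    than one window yields an empty list.
    """
    if hop <= 0:
        raise InvalidArgument("hop must be positive")
    rate = trace.sampling_rate
    hop_n = int(round(hop * rate))
    if hop_n < 1:
        raise InvalidArgument("hop smaller than one sample period")
    if trace.kind == "audio":
        win_n = int(round(window_ms * 1e-3 * rate))
        estimate = lambda t: estimate_rpm_acoustic(t, window_ms=window_ms)
    else:
        win_n = n_fft
        estimate = lambda t: estimate_rpm_magnetic(t, n_fft=n_fft)

    out: list[tuple[float, SpinEstimate]] = []
    end = win_n
    while end <= trace.samples.size:
        window = SensorTrace(trace.samples[end - win_n : end], rate, trace.kind)
        out.append((end / rate, estimate(window)))
        end += hop_n
    return out
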