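"""Seeded synthetic generators for every input the package consumes.

Generators are phenomenological stand-ins for the physical platform, with
ground truth known by construction:

* magnetometer traces — one smooth Gaussian field pulse per disc
  revolution (a magnet passing the sensor) on a constant baseline,
  sampled at the phone's 50 Hz magnetometer rate by default;
* rotor audio — a band-limited pulse train (one acoustic event per
  revolution from a sound hole) or a harmonic tone, at 48 kHz;
* channel images — a U-shaped metering channel whose radially outward
  (closed) end is filled with dark packed red cells covering a requested
  percentage of the channel area, on a background with optional
  illumination tilt, stray marks and noise;
* sedimentation series — images whose dark fraction relaxes
  exponentially from 100 % (whole blood) toward the final hematocrit;
* calibration data — absorbance linear in concentration with Gaussian
  replicate noise.

All randomness flows through an explicit integer seed; identical
arguments and seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .elisa import CalibrationPoint
from .errors import InvalidArgument
from .hct import DiscImage, HematocritResult
from .tachometry import SensorTrace

__all__ = [
    "RotationProfile",
    "MagnetModel",
    "AudioModel",
    "ChannelImageSpec",
    "u_channel_mask",
    "make_magnetometer_trace",
    "make_audio_trace",
    "make_channel_image",
    "make_sedimentation_series",
    "make_calibration_data",
]


@dataclass(frozen=True)
class RotationProfile:
    """A piecewise-constant disc speed schedule.

    ``segments`` is an ordered list of ``(start_time_s, rpm)`` pairs;
    each speed holds from its start time until the next segment begins.
    Start times must be strictly increasing, the first must be 0, and
    all speeds nonnegative. Rotation frequency in Hz is ``rpm / 60``.
    """

    segments: tuple[tuple[float, float], ...]

    def __init__(self, segments):
        segs = tuple((float(t), float(r)) for t, r in segments)
        if not segs:
            raise InvalidArgument("profile needs at least one segment")
        if segs[0][0] != 0.0:
            raise InvalidArgument("first segment must start at t=0")
        starts = [t for t, _ in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise InvalidArgument("segment start times must be strictly increasing")
        if any(r < 0 for _, r in segs):
            raise InvalidArgument("rpm must be nonnegative")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def constant(cls, rpm: float) -> "RotationProfile":
        return cls([(0.0, rpm)])

    def rpm_at(self, t) -> np.ndarray:
        """Speed (RPM) at time(s) ``t``; zero before t=0."""
        t = np.asarray(t, dtype=float)
        starts = np.array([s for s, _ in self.segments])
        rpms = np.array([r for _, r in self.segments])
        idx = np.searchsorted(starts, t, side="right") - 1
        out = np.where(idx >= 0, rpms[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)

    def frequency_at(self, t) -> np.ndarray:
        return self.rpm_at(t) / 60.0

    def phase_at(self, t) -> np.ndarray:
        """Cumulative revolutions completed by time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        starts = np.array([s for s, _ in self.segments])
        freqs = np.array([r / 60.0 for _, r in self.segments])
        # revolutions accumulated at each segment boundary
        seg_dur = np.diff(starts)
        cum = np.concatenate([[0.0], np.cumsum(freqs[:-1] * seg_dur)])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, None)
        phase = cum[idx] + freqs[idx] * (t - starts[idx])
        return np.where(t < 0, 0.0, phase)


@dataclass(frozen=True)
class MagnetModel:
    """Field waveform of the embedded magnet at the phone's magnetometer.

    One Gaussian bump per revolution rides on ``baseline_field``;
    ``pulse_width_fraction`` is the Gaussian sigma as a fraction of one
    revolution period (default 0.1, i.e. a pulse about 10 % of the
    period wide).
    """

    baseline_field: float = 40.0  # µT, typical ambient geomagnetic field
    pulse_amplitude: float = 25.0  # µT
    pulse_width_fraction: float = 0.1
    noise_sd: float = 0.5  # µT

    def __post_init__(self):
        if not 0.0 < self.pulse_width_fraction < 0.5:
            raise InvalidArgument("pulse_width_fraction must be in (0, 0.5)")
        if self.noise_sd < 0:
            raise InvalidArgument("noise_sd must be nonnegative")


@dataclass(frozen=True)
class AudioModel:
    """Rotor audio timbre.

    ``pulse_train`` (default) emulates one acoustic event per revolution
    from the sound hole, synthesized band-limited as the first
    ``n_harmonics`` cosine harmonics of the rotation frequency with a
    linearly decaying spectral envelope (a real pressure pulse rolls off
    toward high frequency, so the fundamental is the strongest line);
    ``harmonic_tone`` gives a clean 1/k-weighted harmonic stack for unit
    tests. Amplitudes are normalized so the waveform stays within
    ``[-amplitude, amplitude]``.
    """

    waveform_kind: str = "pulse_train"
    amplitude: float = 0.8
    n_harmonics: int = 20
    noise_sd: float = 0.01

    def __post_init__(self):
        if self.waveform_kind not in ("pulse_train", "harmonic_tone"):
            raise InvalidArgument(f"unknown waveform_kind {self.waveform_kind!r}")
        if not 0.0 < self.amplitude <= 1.0:
            raise InvalidArgument("amplitude must be in (0, 1]")
        if self.n_harmonics < 1:
            raise InvalidArgument("n_harmonics must be >= 1")
        if self.noise_sd < 0:
            raise InvalidArgument("noise_sd must be nonnegative")


def _check_rate_duration(sampling_rate: float, duration: float) -> int:
    if sampling_rate <= 0:
        raise InvalidArgument("sampling_rate must be positive")
    if duration <= 0:
        raise InvalidArgument("duration must be positive")
    n = int(round(duration * sampling_rate))
    if n < 2:
        raise InvalidArgument("duration too short for this sampling rate")
    return n


def make_magnetometer_trace(
    profile: RotationProfile,
    model: MagnetModel = MagnetModel(),
    sampling_rate: float = 50.0,
    duration: float = 5.12,
    seed: int = 0,
) -> SensorTrace:
    """Synthesize a magnetometer trace for a rotation profile.

    Each revolution contributes one Gaussian field pulse centred where
    the cumulative phase crosses an integer; samples taken while the
    disc is at rest carry only the baseline (plus noise). The default
    duration 5.12 s yields exactly 256 samples at 50 Hz.
    """
    n = _check_rate_duration(sampling_rate, duration)
    t = np.arange(n) / sampling_rate
    phase = profile.phase_at(t)
    freq = np.asarray(profile.frequency_at(t))
    # wrapped distance (in revolutions) to the nearest pulse centre
    d = (phase + 0.5) % 1.0 - 0.5
    bump = model.pulse_amplitude * np.exp(-0.5 * (d / model.pulse_width_fraction) ** 2)
    samples = model.baseline_field + np.where(freq > 0, bump, 0.0)
    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, model.noise_sd, n)
    return SensorTrace(samples, sampling_rate, "magnetic")


def make_audio_trace(
    profile: RotationProfile,
    model: AudioModel = AudioModel(),
    sampling_rate: float = 48000.0,
    duration: float = 0.1,
    seed: int = 0,
) -> SensorTrace:
    """Synthesize rotor audio for a rotation profile.

    The default window matches the acoustic tachometer's acquisition:
    100 ms at 48 kHz. Rest periods are silent apart from noise.
    """
    n = _check_rate_duration(sampling_rate, duration)
    t = np.arange(n) / sampling_rate
    phase = profile.phase_at(t)
    freq = np.asarray(profile.frequency_at(t))
    k = np.arange(1, model.n_harmonics + 1)
    if model.waveform_kind == "pulse_train":
        # band-limited impulse train with triangular spectral envelope;
        # pulse apex reaches `amplitude`
        weights = 1.0 - (k - 1) / model.n_harmonics
        waves = np.cos(2.0 * np.pi * np.outer(k, phase)) * weights[:, None]
        samples = model.amplitude * waves.sum(axis=0) / weights.sum()
    else:
        weights = 1.0 / k
        waves = np.sin(2.0 * np.pi * np.outer(k, phase)) * weights[:, None]
        samples = model.amplitude * waves.sum(axis=0) / weights.sum()
    samples = np.where(freq > 0, samples, 0.0)
    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, model.noise_sd, n)
    return SensorTrace(samples, sampling_rate, "audio")


def u_channel_mask(
    shape: tuple[int, int] = (180, 120),
    arm_width: int = 18,
    top: int = 20,
    bend_height: int = 22,
    margin: int = 24,
) -> np.ndarray:
    """Boolean mask of a U-shaped metering channel.

    Two vertical arms joined by a bottom bend; the bend is the radially
    outward, closed end where red cells pack. The default geometry gives
    roughly 5.6 k channel pixels in a 180x120 image.
    """
    h, w = shape
    left = margin
    right = w - margin - arm_width
    bend_bottom = h - top
    bend_top = bend_bottom - bend_height
    if right <= left + arm_width or bend_top <= top:
        raise InvalidArgument("mask geometry does not fit in the image")
    mask = np.zeros(shape, dtype=bool)
    mask[top:bend_top, left : left + arm_width] = True
    mask[top:bend_top, right : right + arm_width] = True
    mask[bend_top:bend_bottom, left : right + arm_width] = True
    return mask


@dataclass(frozen=True)
class ChannelImageSpec:
    """Recipe for a synthetic metering-channel image.

    Intensities are in [0, 1]; the packed-cell region is rendered at
    ``dark_level``, plasma at ``plasma_level``, background at
    ``background_level``. ``illumination_gradient`` is the maximum
    fractional intensity tilt across the image width;
    ``stray_mark_density`` is dark single-pixel marks per 10^4
    background pixels; ``hct_fraction`` is the percentage of channel
    pixels rendered dark, packed from the closed end.
    """

    image_size: tuple[int, int] = (180, 120)
    channel_mask: np.ndarray | None = None
    hct_fraction: float = 40.0
    dark_level: float = 0.15
    plasma_level: float = 0.75
    background_level: float = 0.9
    illumination_gradient: float = 0.0
    stray_mark_density: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.hct_fraction <= 100.0:
            raise InvalidArgument("hct_fraction must be in [0, 100]")
        if not self.dark_level < self.plasma_level:
            raise InvalidArgument("dark_level must be below plasma_level")
        if self.noise_sd < 0 or self.stray_mark_density < 0:
            raise InvalidArgument("noise_sd and stray_mark_density must be >= 0")
        if self.channel_mask is not None:
            m = np.asarray(self.channel_mask, dtype=bool)
            if m.shape != tuple(self.image_size):
                raise InvalidArgument("channel_mask shape must match image_size")
            if not m.any():
                raise InvalidArgument("channel_mask is empty")
            object.__setattr__(self, "channel_mask", m)

    def resolved_mask(self) -> np.ndarray:
        if self.channel_mask is not None:
            return self.channel_mask
        return u_channel_mask(tuple(self.image_size))


def make_channel_image(
    spec: ChannelImageSpec, seed: int = 0
) -> tuple[DiscImage, HematocritResult]:
    """Render a channel image and its exact ground truth.

    The dark packed-cell region fills the channel from the radially
    outward closed end (largest row index first) up to ``hct_fraction``
    percent of the channel pixels, rounded to a whole pixel; the ground
    truth records the exact rendered fraction and the midpoint threshold
    that separates the two rendered levels.
    """
    mask = spec.resolved_mask()
    n_channel = int(mask.sum())
    if n_channel == 0:
        raise InvalidArgument("channel mask is empty")
    h, w = mask.shape

    pixels = np.full(mask.shape, spec.background_level, dtype=float)
    pixels[mask] = spec.plasma_level

    n_dark = int(round(spec.hct_fraction / 100.0 * n_channel))
    if n_dark > 0:
        rows, cols = np.nonzero(mask)
        # pack from the closed (radially outward) end: largest row first
        order = np.lexsort((cols, -rows))
        dark_idx = order[:n_dark]
        pixels[rows[dark_idx], cols[dark_idx]] = spec.dark_level

    rng = np.random.default_rng(seed)
    if spec.stray_mark_density > 0:
        bg_rows, bg_cols = np.nonzero(~mask)
        n_marks = int(round(spec.stray_mark_density * bg_rows.size / 1e4))
        if n_marks > 0:
            pick = rng.choice(bg_rows.size, size=min(n_marks, bg_rows.size), replace=False)
            pixels[bg_rows[pick], bg_cols[pick]] = spec.dark_level / 2.0

    if spec.illumination_gradient > 0:
        g = spec.illumination_gradient
        ramp = (1.0 - g) + g * np.arange(w) / max(w - 1, 1)
        pixels = pixels * ramp[None, :]

    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)

    truth = HematocritResult(
        hct_percent=100.0 * n_dark / n_channel,
        threshold=0.5 * (spec.dark_level + spec.plasma_level),
        dark_pixels=n_dark,
        total_pixels=n_channel,
    )
    return DiscImage(pixels=pixels, channel_mask=mask), truth


def make_sedimentation_series(
    final_hct: float,
    times: list[float],
    time_constant: float = 50.0,
    spec: ChannelImageSpec = ChannelImageSpec(),
    seed: int = 0,
) -> list[tuple[float, DiscImage, HematocritResult]]:
    """Image series of red cells compacting in the channel over time.

    At t=0 the whole channel is dark (unseparated whole blood); the
    apparent dark fraction relaxes as
    ``final_hct + (100 - final_hct) * exp(-t / time_constant)``. The
    default 50 s time constant makes the fraction change rapidly within
    the first minute and settle to within 1 % of the final value by
    about 200 s, matching the observed sedimentation timescale. Returns
    ``(time, image, ground_truth)`` triples.
    """
    if time_constant <= 0:
        raise InvalidArgument("time_constant must be positive")
    times = [float(t) for t in times]
    if any(t < 0 for t in times):
        raise InvalidArgument("times must be nonnegative")
    if any(b < a for a, b in zip(times, times[1:])):
        raise InvalidArgument("times must be nondecreasing")
    if not 0.0 <= final_hct <= 100.0:
        raise InvalidArgument("final_hct must be in [0, 100]")

    child_seeds = np.random.SeedSequence(seed).generate_state(max(len(times), 1)) >> 1
    out = []
    for i, t in enumerate(times):
        frac = final_hct + (100.0 - final_hct) * np.exp(-t / time_constant)
        spec_t = replace(spec, hct_fraction=float(frac))
        img, truth = make_channel_image(spec_t, seed=int(child_seeds[i]))
        out.append((t, img, truth))
    return out


def make_calibration_data(
    concentrations: list[float],
    slope: float = 0.002,
    intercept: float = 0.05,
    noise_sd: float = 0.01,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[CalibrationPoint]:
    """Linear absorbance-vs-concentration data with replicate noise.

    Defaults emulate a colorimetric sandwich assay read at 450 nm over
    the 0–200 ng/mL range: absorbance = intercept + slope * conc +
    N(0, noise_sd) per replicate.
    """
    if noise_sd < 0:
        raise InvalidArgument("noise_sd must be nonnegative")
    if n_replicates < 1:
        raise InvalidArgument("n_replicates must be >= 1")
    concs = [float(c) for c in concentrations]
    if any(c < 0 for c in concs):
        raise InvalidArgument("concentrations must be nonnegative")
    rng = np.random.default_rng(seed)
    points = []
    for c in concs:
        for rep in range(n_replicates):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            points.append(
                CalibrationPoint(
                    concentration=c,
                    absorbance=intercept + slope * c + noise,
                    replicate=rep,
                )
            )
    return points
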