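"""Synthetic MEG-like signal simulator.

Real gold-standard HFO data is clinical and private, so every downstream
stage is exercised on simulated recordings: a 1/f ("pink") neural background
plus a white sensor-noise floor, with Gaussian-windowed oscillatory bursts
injected in the ripple (80-250 Hz) or fast-ripple (250-500 Hz) band.

Amplitudes are in arbitrary-but-consistent units; the white-noise floor is
specified as an amplitude spectral density (nominally fT/sqrt(Hz)) and the
pink background as its amplitude spectral density at 1 Hz. Absolute sensor
calibration is irrelevant to classification and not attempted.

Every operation is a pure function of (config, seed): each draws from its own
named random stream derived from the seed, so adding operations never
perturbs existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from hfodet.core import HFO, NC, ConfigError, LabeledSegment, Recording, derive_rng
from hfodet.sigio import bandpass, band_power, FilterSpec

RIPPLE_BAND = (80.0, 250.0)
FAST_RIPPLE_BAND = (250.0, 500.0)
BAND_NAMES = {"ripple": RIPPLE_BAND, "fast_ripple": FAST_RIPPLE_BAND}

#: HFOs are conventionally required to show at least this many oscillation cycles.
MIN_CYCLES = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated acquisition and gold-standard set.

    Defaults emulate the target acquisition: 2,400 Hz sampling, 306 sensors,
    2-s windows (4,800 samples), a ~4 fT/sqrt(Hz) sensor noise floor under a
    dominant 1/f neural background, and balanced HFO/NC segment sets from 20
    patients (660 per class).
    """

    sampling_rate_hz: float = 2400.0
    n_channels: int = 306
    window_s: float = 2.0
    noise_floor: float = 4.0  # white-noise amplitude spectral density, units/sqrt(Hz)
    pink_exponent: float = 1.0  # beta of the 1/f**beta background PSD
    pink_scale: float = 300.0  # background amplitude spectral density at 1 Hz
    burst_band: tuple[float, float] = RIPPLE_BAND
    burst_duration_ms: tuple[float, float] = (30.0, 100.0)
    burst_snr_db: float = 10.0  # burst power over same-band background power, on the burst support
    n_hfo: int = 660
    n_nc: int = 660
    n_patients: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.burst_band
        if not (0 < lo < hi):
            raise ConfigError("burst_band must satisfy 0 < low < high")
        if self.sampling_rate_hz <= 2 * hi:
            raise ConfigError(
                f"sampling_rate_hz ({self.sampling_rate_hz}) must exceed twice the "
                f"burst band upper edge ({hi} Hz)"
            )
        dlo, dhi = self.burst_duration_ms
        if not (0 < dlo <= dhi):
            raise ConfigError("burst_duration_ms must be a positive interval")
        if dhi >= 1000.0 * self.window_s:
            raise ConfigError("burst duration must fit inside one window")
        if self.n_hfo < 0 or self.n_nc < 0:
            raise ConfigError("n_hfo and n_nc must be >= 0")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")
        if self.window_s <= 0 or self.noise_floor < 0 or self.pink_scale < 0:
            raise ConfigError("window_s must be positive; noise amplitudes non-negative")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.sampling_rate_hz))


def study_defaults(seed: int = 0) -> SimulationConfig:
    """The full-size study configuration: 660+660 segments from 20 patients."""
    return SimulationConfig(seed=seed)


def quick_test(seed: int = 0) -> SimulationConfig:
    """A small smoke-test configuration: 40+40 segments from 4 patients."""
    return SimulationConfig(n_hfo=40, n_nc=40, n_patients=4, n_channels=8, seed=seed)


def make_background(config: SimulationConfig, n_samples: int, seed: int) -> np.ndarray:
    """One channel of background: 1/f**beta noise plus the white sensor floor.

    The pink component is synthesized in the frequency domain with one-sided
    PSD ``pink_scale**2 / f**beta`` (expected-power normalization, zero DC);
    the white component has PSD ``noise_floor**2``, i.e. standard deviation
    ``noise_floor * sqrt(fs / 2)`` per sample.
    """
    if n_samples < 2:
        raise ConfigError("n_samples must be >= 2")
    rng = derive_rng(seed, "background")
    fs = config.sampling_rate_hz
    n = int(n_samples)

    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    # E|Z_k|^2 = S(f_k) * fs * n / 2 makes the one-sided periodogram match S.
    amp[nz] = np.sqrt(config.pink_scale**2 / freqs[nz] ** config.pink_exponent * fs * n / 2.0)
    z = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    z[0] = 0.0
    pink = np.fft.irfft(z, n=n)

    white = rng.standard_normal(n) * (config.noise_floor * np.sqrt(fs / 2.0))
    return pink + white


def make_hfo_burst(config: SimulationConfig, seed: int, amplitude: float = 1.0) -> np.ndarray:
    """A Gaussian-windowed sinusoid burst (Morlet-like), unit peak amplitude.

    Carrier frequency ~ U(burst_band); duration ~ U(burst_duration_ms).
    Draws with fewer than four oscillation cycles are rejected, matching the
    conventional minimum-cycle definition of an HFO. The returned vector
    covers only the burst support; peak amplitude is set later by SNR scaling.
    """
    lo, hi = config.burst_band
    if hi >= config.sampling_rate_hz / 2.0:
        raise ConfigError("burst band must lie below Nyquist")
    rng = derive_rng(seed, "burst")
    dlo, dhi = config.burst_duration_ms
    if hi * dhi / 1000.0 < MIN_CYCLES:
        raise ConfigError(
            "burst_band and burst_duration_ms admit no draw with "
            f">= {MIN_CYCLES:g} oscillation cycles"
        )
    for _ in range(1000):
        freq = rng.uniform(lo, hi)
        dur_s = rng.uniform(dlo, dhi) / 1000.0
        if freq * dur_s >= MIN_CYCLES:
            break
    else:  # pragma: no cover - unreachable given the feasibility check above
        raise ConfigError("failed to draw a burst with enough cycles")
    phase = rng.uniform(0, 2 * np.pi)

    m = max(int(round(dur_s * config.sampling_rate_hz)), 2)
    t = (np.arange(m) - (m - 1) / 2.0) / config.sampling_rate_hz
    window = np.exp(-0.5 * (t / (dur_s / 6.0)) ** 2)  # +-3 sigma support
    return amplitude * window * np.sin(2 * np.pi * freq * t + phase)


def _scaled_burst_in_background(
    config: SimulationConfig, background: np.ndarray, seed: int
) -> tuple[np.ndarray, int, int]:
    """Embed one SNR-scaled burst into a copy of ``background``.

    The burst is scaled so that its mean-square power over its own support
    equals ``10**(snr_db/10)`` times the background's mean-square power in
    ``burst_band`` over the same support (band power measured by zero-phase
    band-pass filtering). Returns (samples, onset_index, offset_index).
    """
    burst = make_hfo_burst(config, seed)
    m = burst.size
    n = background.size
    if m >= n:
        raise ConfigError("burst longer than the segment")
    rng = derive_rng(seed, "burst-placement")
    start = int(rng.integers(0, n - m + 1))

    fspec = FilterSpec(config.burst_band[0], config.burst_band[1])
    bg_band = bandpass(background, fspec, config.sampling_rate_hz)
    bg_ms = float(np.mean(bg_band[start : start + m] ** 2))
    bg_ms = max(bg_ms, 1e-300)
    burst_ms = float(np.mean(burst**2))
    scale = np.sqrt(10 ** (config.burst_snr_db / 10.0) * bg_ms / burst_ms)

    out = background.copy()
    out[start : start + m] += scale * burst
    return out, start, start + m


def gold_standard_labels(config: SimulationConfig) -> list[str]:
    """Label sequence of the gold-standard set (HFO/NC interleaved)."""
    labels = []
    for i in range(max(config.n_hfo, config.n_nc)):
        if i < config.n_hfo:
            labels.append(HFO)
        if i < config.n_nc:
            labels.append(NC)
    return labels


def background_seed(config: SimulationConfig, index: int) -> int:
    """Seed of the background stream behind gold-standard segment ``index``.

    Exposed so that a matched pure-background control can be regenerated for
    any HFO segment.
    """
    return int(derive_rng(config.seed, "gold-standard", index).integers(0, 2**31 - 1))


def make_gold_standard(config: SimulationConfig) -> list[LabeledSegment]:
    """Balanced labeled segment sets: HFO windows with one burst each, NC pure background.

    Patient identity is assigned round-robin within each class, so per-patient
    counts (and per-patient class balance, when n_hfo == n_nc) are exact.
    """
    if config.n_hfo + config.n_nc < 1:
        raise ConfigError("need at least one segment")
    n = config.window_samples
    labels = gold_standard_labels(config)
    per_class_counter = {HFO: 0, NC: 0}
    segments: list[LabeledSegment] = []
    for i, label in enumerate(labels):
        seed_i = background_seed(config, i)
        bg = make_background(config, n, seed_i)
        if label == HFO:
            samples, _, _ = _scaled_burst_in_background(config, bg, seed_i)
        else:
            samples = bg
        j = per_class_counter[label]
        per_class_counter[label] += 1
        patient = f"P{(j % config.n_patients) + 1:02d}"
        channel = f"MEG{(i % config.n_channels) + 1:04d}"
        segments.append(
            LabeledSegment(
                samples=samples,
                patient_id=patient,
                channel_id=channel,
                start_s=i * config.window_s,
                label=label,
                segment_id=f"G{i:06d}",
            )
        )
    return segments


def make_recording(
    config: SimulationConfig, duration_s: float, event_rate_per_min: float, seed: int
) -> tuple[Recording, pd.DataFrame]:
    """A multichannel recording with bursts at Poisson times on random channels.

    Returns the recording and an event table with columns
    ``channel_id, onset_s, offset_s, band`` (seconds, half-open intervals,
    0-based channel indices). Every event lies fully inside the recording.
    """
    if duration_s < config.window_s:
        raise ConfigError(f"duration_s ({duration_s}) must be >= window_s ({config.window_s})")
    if event_rate_per_min < 0:
        raise ConfigError("event_rate_per_min must be >= 0")
    fs = config.sampling_rate_hz
    n = int(round(duration_s * fs))
    data = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        ch_seed = int(derive_rng(seed, "recording-channel", c).integers(0, 2**31 - 1))
        data[c] = make_background(config, n, ch_seed)

    rng = derive_rng(seed, "recording-events")
    n_events = int(rng.poisson(event_rate_per_min * duration_s / 60.0))
    band_name = next(
        (name for name, band in BAND_NAMES.items() if band == tuple(config.burst_band)),
        f"{config.burst_band[0]:g}-{config.burst_band[1]:g}Hz",
    )
    rows = []
    for e in range(n_events):
        ch = int(rng.integers(0, config.n_channels))
        ev_seed = int(rng.integers(0, 2**31 - 1))
        burst = make_hfo_burst(config, ev_seed)
        m = burst.size
        start = int(rng.integers(0, n - m + 1))
        fspec = FilterSpec(config.burst_band[0], config.burst_band[1])
        bg_band = bandpass(data[ch, start : start + m], fspec, fs)
        bg_ms = max(float(np.mean(bg_band**2)), 1e-300)
        scale = np.sqrt(10 ** (config.burst_snr_db / 10.0) * bg_ms / float(np.mean(burst**2)))
        data[ch, start : start + m] += scale * burst
        rows.append(
            {
                "channel_id": ch,
                "onset_s": start / fs,
                "offset_s": (start + m) / fs,
                "band": band_name,
            }
        )
    events = pd.DataFrame(rows, columns=["channel_id", "onset_s", "offset_s", "band"])
    recording = Recording(
        data=data,
        sampling_rate_hz=fs,
        channel_ids=[f"MEG{c + 1:04d}" for c in range(config.n_channels)],
        patient_id="SIM",
    )
    return recording, events


def hfo_band_power(segment: LabeledSegment, config: SimulationConfig) -> float:
    """Band power of a segment within the configured burst band (oracle helper)."""
    return band_power(segment.samples, config.sampling_rate_hz, tuple(config.burst_band))
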