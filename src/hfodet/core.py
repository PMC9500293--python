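"""Shared domain types and errors.

Conventions used throughout the package: sample indices are 0-based, time
intervals are half-open ``[start, end)`` in seconds, and class labels are the
strings ``"HFO"`` (pathological high-frequency oscillation), ``"NC"`` (normal
control) and ``"UNKNOWN"`` (unlabeled candidate).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

HFO = "HFO"
NC = "NC"
UNKNOWN = "UNKNOWN"
LABELS = (HFO, NC, UNKNOWN)


class HfodetError(Exception):
    """Base class for package errors."""


class FormatError(HfodetError):
    """A file could not be parsed; the message names the offending field."""


class ConfigError(HfodetError):
    """An invalid configuration or model specification."""


def derive_rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    """Return a seeded generator for one named random stream.

    Each operation draws from its own stream keyed by ``(seed, stream name,
    extra indices)`` so that adding operations or reordering calls never
    perturbs existing fixtures.
    """
    key = zlib.crc32(stream.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, key, *[int(e) & 0x7FFFFFFF for e in extra]])


@dataclass
class Recording:
    """A multichannel real-valued time series from one patient."""

    data: np.ndarray  # (n_channels, n_samples)
    sampling_rate_hz: float
    channel_ids: list[str]
    patient_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigError("Recording.data must be a channels x samples matrix")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ConfigError(
                f"channel_ids length {len(self.channel_ids)} != channel count {self.data.shape[0]}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class LabeledSegment:
    """One fixed-length single-channel signal window — the unit of detection.

    ``samples`` covers the half-open interval ``[start_s, start_s + window)``
    on channel ``channel_id`` of patient ``patient_id``.
    """

    samples: np.ndarray
    patient_id: str
    channel_id: str
    start_s: float
    label: str = UNKNOWN
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.label not in LABELS:
            raise ConfigError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.start_s < 0:
            raise ConfigError("start_s must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def y(self) -> int:
        """Binary target: 1 for HFO, 0 otherwise."""
        return 1 if self.label == HFO else 0
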