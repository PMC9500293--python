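"""Recording I/O, segmentation, band-pass filtering, and candidate screening.

The pipeline mirrors standard HFO practice: cut a long multichannel recording
into fixed 2-s windows, band-pass them into the ripple (80-250 Hz) and
fast-ripple (250-500 Hz) bands, and keep only windows whose spectral content
is dominated by high-frequency power.

EDF support: reading delegates to :mod:`mne`; writing uses a minimal built-in
16-bit EDF encoder (one physical-min/max pair per channel, blank physical
dimension so readers return the stored values unscaled).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from hfodet.core import UNKNOWN, ConfigError, FormatError, LabeledSegment, Recording

# Candidate screen integrates power over 80-500 Hz relative to 1-500 Hz.
SCREEN_BAND = (80.0, 500.0)
TOTAL_BAND = (1.0, 500.0)
DEFAULT_RATIO_THRESHOLD = 0.1


@dataclass(frozen=True)
class FilterSpec:
    """A band-pass filter specification (Butterworth, zero-phase)."""

    low_hz: float
    high_hz: float
    order: int = 4

    def validate(self, sampling_rate_hz: float) -> None:
        nyq = sampling_rate_hz / 2.0
        if not (0 < self.low_hz < self.high_hz < nyq):
            raise ConfigError(
                f"band [{self.low_hz}, {self.high_hz}] Hz must satisfy "
                f"0 < low < high < Nyquist ({nyq} Hz)"
            )
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")


BAND_PRESETS = {
    "ripple": FilterSpec(80.0, 250.0),
    "fast_ripple": FilterSpec(250.0, 500.0),
    "screen": FilterSpec(SCREEN_BAND[0], SCREEN_BAND[1]),
}


def resolve_filter(spec: "FilterSpec | str | None") -> FilterSpec | None:
    if spec is None or isinstance(spec, FilterSpec):
        return spec
    if spec in ("none", "raw"):
        return None
    try:
        return BAND_PRESETS[spec]
    except KeyError:
        raise ConfigError(f"unknown filter preset {spec!r}; choose from {sorted(BAND_PRESETS)}") from None


def bandpass(samples: np.ndarray, spec: FilterSpec | str, sampling_rate_hz: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass of one segment (or a stack of them).

    Forward-backward filtering (``sosfiltfilt``) preserves burst timing within
    the window; the output has the same length as the input.
    """
    fspec = resolve_filter(spec)
    fspec.validate(sampling_rate_hz)
    x = np.asarray(samples, dtype=float)
    sos = signal.butter(
        fspec.order, [fspec.low_hz, fspec.high_hz], btype="bandpass", fs=sampling_rate_hz, output="sos"
    )
    return signal.sosfiltfilt(sos, x, axis=-1)


def band_power(samples: np.ndarray, sampling_rate_hz: float, band: tuple[float, float]) -> float:
    """Mean-square power of ``samples`` within ``band``, by periodogram integration."""
    freqs, pxx = signal.periodogram(np.asarray(samples, dtype=float), fs=sampling_rate_hz)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    return float(np.sum(pxx[mask]) * df)


# ---------------------------------------------------------------------------
# EDF read/write
# ---------------------------------------------------------------------------

_EDF_MAX_RECORD_BYTES = 61440  # EDF caps one data record at 61440 bytes


def _edf_field(value: str, width: int) -> bytes:
    s = value.encode("ascii", errors="replace")
    if len(s) > width:
        s = s[:width]
    return s.ljust(width)


def write_edf(recording: Recording, path: "str | os.PathLike") -> None:
    """Write a recording as a 16-bit EDF file.

    Physical min/max are set per channel from the data range; the physical
    dimension is left blank so values round-trip unscaled (to within 16-bit
    quantization). Record duration shrinks below 1 s when needed to respect
    the EDF record-size cap for wide channel counts.
    """
    data = recording.data
    fs = recording.sampling_rate_hz
    nch = recording.n_channels
    # Largest record duration from a preferred list that keeps fs*dur integral
    # and the record under the EDF byte cap.
    rec_dur = None
    for cand in (1.0, 0.5, 0.25, 0.2, 0.1, 0.05, 0.025, 0.02, 0.01, 0.005):
        spr = fs * cand
        if abs(spr - round(spr)) > 1e-9:
            continue
        if round(spr) * 2 * nch <= _EDF_MAX_RECORD_BYTES and round(spr) >= 1:
            rec_dur = cand
            break
    if rec_dur is None:
        raise FormatError(f"cannot fit {nch} channels at {fs} Hz into an EDF record")
    spr = int(round(fs * rec_dur))
    nrec = int(np.ceil(data.shape[1] / spr))
    padded = np.pad(data, ((0, 0), (0, nrec * spr - data.shape[1])))

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax <= pmin
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    hdr = bytearray()
    hdr += _edf_field("0", 8)
    hdr += _edf_field(f"{recording.patient_id} X X X", 80)
    hdr += _edf_field("Startdate 01-JAN-2000 X X X", 80)
    hdr += _edf_field("01.01.00", 8)
    hdr += _edf_field("00.00.00", 8)
    hdr += _edf_field(str(256 * (nch + 1)), 8)
    hdr += _edf_field("", 44)
    hdr += _edf_field(str(nrec), 8)
    hdr += _edf_field(f"{rec_dur:g}", 8)
    hdr += _edf_field(str(nch), 4)
    for cid in recording.channel_ids:
        hdr += _edf_field(cid, 16)
    for _ in range(nch):
        hdr += _edf_field("", 80)  # transducer
    for _ in range(nch):
        hdr += _edf_field("", 8)  # physical dimension: blank, unscaled units
    for v in pmin:
        hdr += _edf_field(f"{v:.6g}"[:8], 8)
    for v in pmax:
        hdr += _edf_field(f"{v:.6g}"[:8], 8)
    for _ in range(nch):
        hdr += _edf_field(str(dmin), 8)
    for _ in range(nch):
        hdr += _edf_field(str(dmax), 8)
    for _ in range(nch):
        hdr += _edf_field("", 80)  # prefiltering
    for _ in range(nch):
        hdr += _edf_field(str(spr), 8)
    for _ in range(nch):
        hdr += _edf_field("", 32)

    # Re-read the 8-char ASCII physical bounds so the digital scaling matches
    # exactly what a reader will reconstruct from the header.
    pmin_q = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_q = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    pmax_q = np.where(pmax_q <= pmin_q, pmin_q + 1.0, pmax_q)
    scale = (pmax_q - pmin_q) / (dmax - dmin)

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        for r in range(nrec):
            block = padded[:, r * spr : (r + 1) * spr]
            dig = np.round((block - pmin_q[:, None]) / scale[:, None] + dmin)
            dig = np.clip(dig, dmin, dmax).astype("<i2")
            fh.write(dig.tobytes())


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise FormatError(f"could not parse EDF file {path}: {exc}") from exc
    data = raw.get_data()
    patient_id = path.stem
    sub = (raw.info.get("subject_info") or {}).get("his_id")
    if sub:
        patient_id = str(sub).split()[0]
    return Recording(
        data=data,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_ids=list(raw.ch_names),
        patient_id=patient_id,
    )


def _read_delimited(path: Path, sampling_rate_hz: float | None) -> Recording:
    if sampling_rate_hz is None or sampling_rate_hz <= 0:
        raise FormatError("delimited input needs an explicit positive sampling_rate_hz")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse delimited file {path}: {exc}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise FormatError(f"delimited file {path} contains no data columns")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise FormatError(f"delimited file {path}: non-numeric column among {list(df.columns)}")
    return Recording(
        data=df.to_numpy().T,
        sampling_rate_hz=float(sampling_rate_hz),
        channel_ids=[str(c) for c in df.columns],
        patient_id=path.stem,
    )


def read_recording(
    path: "str | os.PathLike",
    format: str = "auto",
    sampling_rate_hz: float | None = None,
) -> Recording:
    """Read a recording from EDF or a delimited text file.

    Delimited files hold one column per channel with a header row of channel
    ids and require ``sampling_rate_hz`` (the format carries no rate).
    """
    p = Path(path)
    if not p.is_file():
        raise FormatError(f"no such file: {p}")
    if p.stat().st_size == 0:
        raise FormatError(f"empty file: {p}")
    fmt = format.lower()
    if fmt == "auto":
        fmt = "edf" if p.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        return _read_edf(p)
    if fmt == "delimited":
        return _read_delimited(p, sampling_rate_hz)
    raise ConfigError(f"unknown format {format!r}; choose 'edf' or 'delimited'")


# ---------------------------------------------------------------------------
# Segmentation and screening
# ---------------------------------------------------------------------------


def segment_recording(
    recording: Recording, window_s: float = 2.0, overlap_fraction: float = 0.0
) -> list[LabeledSegment]:
    """Cut every channel into fixed windows; labels start as UNKNOWN.

    With window length ``W`` samples and ``step = round(W * (1 - overlap))``,
    each channel yields ``floor((T - W) / step) + 1`` windows; trailing samples
    that do not fill a window are dropped. A recording shorter than one window
    yields an empty list.
    """
    if not (0 <= overlap_fraction < 1):
        raise ConfigError("overlap_fraction must lie in [0, 1)")
    w = int(round(window_s * recording.sampling_rate_hz))
    if w < 1:
        raise ConfigError("window_s too short for this sampling rate")
    t = recording.n_samples
    if t < w:
        return []
    step = int(round(w * (1.0 - overlap_fraction)))
    step = max(step, 1)
    count = (t - w) // step + 1
    out: list[LabeledSegment] = []
    for ci, cid in enumerate(recording.channel_ids):
        for j in range(count):
            s0 = j * step
            out.append(
                LabeledSegment(
                    samples=recording.data[ci, s0 : s0 + w],
                    patient_id=recording.patient_id,
                    channel_id=cid,
                    start_s=s0 / recording.sampling_rate_hz,
                    label=UNKNOWN,
                    segment_id=f"{recording.patient_id}:{cid}:{j:06d}",
                )
            )
    return out


def count_windows(n_samples: int, sampling_rate_hz: float, window_s: float, overlap_fraction: float = 0.0) -> int:
    """Number of windows one channel of ``n_samples`` yields (same rule as above)."""
    w = int(round(window_s * sampling_rate_hz))
    if n_samples < w:
        return 0
    step = max(int(round(w * (1.0 - overlap_fraction))), 1)
    return (n_samples - w) // step + 1


def high_frequency_ratio(samples: np.ndarray, sampling_rate_hz: float) -> float:
    """Fraction of 1-500 Hz power that lies in the 80-500 Hz screen band."""
    total = band_power(samples, sampling_rate_hz, TOTAL_BAND)
    if total <= 0:
        return 0.0
    return band_power(samples, sampling_rate_hz, SCREEN_BAND) / total


def screen_candidates(
    segments: list[LabeledSegment],
    sampling_rate_hz: float,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> tuple[list[LabeledSegment], list[LabeledSegment]]:
    """Split segments into (kept, dropped) by high-frequency power ratio.

    A segment is kept iff power(80-500 Hz) / power(1-500 Hz) >= threshold;
    low-frequency-dominated windows are dropped before classification.
    """
    if not (0 <= ratio_threshold <= 1):
        raise ConfigError("ratio_threshold must lie in [0, 1]")
    kept, dropped = [], []
    for seg in segments:
        if high_frequency_ratio(seg.samples, sampling_rate_hz) >= ratio_threshold:
            kept.append(seg)
        else:
            dropped.append(seg)
    return kept, dropped


# ---------------------------------------------------------------------------
# Segment table serialization
# ---------------------------------------------------------------------------

SEGMENT_CSV_COLUMNS = ["segment_id", "patient_id", "channel_id", "start_s", "label"]


def segments_to_frame(segments: list[LabeledSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in segments],
            "patient_id": [s.patient_id for s in segments],
            "channel_id": [s.channel_id for s in segments],
            "start_s": [s.start_s for s in segments],
            "label": [s.label for s in segments],
        }
    )


def write_segments_csv(segments: list[LabeledSegment], path: "str | os.PathLike") -> None:
    segments_to_frame(segments).to_csv(path, index=False)


def write_segments_h5(segments: list[LabeledSegment], path: "str | os.PathLike") -> None:
    """Store segment waveforms plus provenance in one HDF5 container."""
    import h5py

    lengths = {s.n_samples for s in segments}
    if len(lengths) > 1:
        raise ConfigError(f"segments have mixed lengths {sorted(lengths)}")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("samples", data=np.stack([s.samples for s in segments]).astype(np.float32))
        meta = segments_to_frame(segments)
        for col in SEGMENT_CSV_COLUMNS:
            vals = meta[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            fh.create_dataset(col, data=vals)


def read_segments_h5(path: "str | os.PathLike") -> list[LabeledSegment]:
    import h5py

    with h5py.File(path, "r") as fh:
        samples = np.asarray(fh["samples"], dtype=float)
        cols = {}
        for col in SEGMENT_CSV_COLUMNS:
            raw = np.asarray(fh[col])
            cols[col] = [v.decode() if isinstance(v, bytes) else v for v in raw]
    return [
        LabeledSegment(
            samples=samples[i],
            patient_id=str(cols["patient_id"][i]),
            channel_id=str(cols["channel_id"][i]),
            start_s=float(cols["start_s"][i]),
            label=str(cols["label"][i]),
            segment_id=str(cols["segment_id"][i]),
        )
        for i in range(samples.shape[0])
    ]
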