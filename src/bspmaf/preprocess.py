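"""Signal conditioning: referencing, filtering, segmentation and augmentation.

The pipeline mirrors standard BSPM practice: unipolar channels are referenced
against the Wilson central terminal (mean of three reference electrodes),
band-pass filtered at 1-40 Hz with a zero-phase Butterworth filter, cut into
2-s segments, and the minority (recurrence) class is augmented with 175-sample
overlapping windows.  Baseline-wander noise at a configurable SNR can be
injected to emulate ambulatory recording conditions; the noise is a synthetic
band-limited (< 0.5 Hz) process.

Windows are 0-based and half-open: ``[start, start + L)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateInputError,
    InvalidParameterError,
)
from .synthetic import LABEL_RECURRENCE, BspmRecording, ElectrodeLayout


@dataclass
class Segment:
    """One fixed-length window of a recording with provenance."""

    data: np.ndarray  # channels x L, mV (or normalized units)
    fs: float
    patient_id: str
    start_sample: int
    label: str
    channel_names: list[str]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class NoiseSpec:
    """Baseline-wander injection settings (SNR in dB, seeded)."""

    snr_db: float = 12.0
    kind: str = "baseline-wander"
    seed: int = 0

    def validate(self) -> None:
        if self.kind != "baseline-wander":
            raise InvalidParameterError(f"unsupported noise kind {self.kind!r}")
        if not np.isfinite(self.snr_db):
            raise InvalidParameterError("snr_db must be finite")


def apply_wct_reference(
    recording: BspmRecording, layout: ElectrodeLayout
) -> BspmRecording:
    """Subtract the Wilson central terminal and drop the reference channels.

    The WCT is the sample-wise mean of the three reference-electrode traces;
    every recording channel is re-referenced against it.
    """
    try:
        ref_rows = [recording.channel_names.index(r) for r in layout.ref_names]
    except ValueError as exc:
        raise ConfigurationError("recording lacks the reference channels") from exc
    keep = [i for i in range(recording.data.shape[0]) if i not in ref_rows]
    wct = recording.data[ref_rows].mean(axis=0)
    return replace(
        recording,
        data=recording.data[keep] - wct,
        channel_names=[recording.channel_names[i] for i in keep],
    )


def bandpass_filter(
    recording: BspmRecording, low_hz: float = 1.0, high_hz: float = 40.0, order: int = 4
) -> BspmRecording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    if not 0 < low_hz < high_hz < recording.fs / 2:
        raise InvalidParameterError(
            f"invalid band [{low_hz}, {high_hz}] for fs={recording.fs}"
        )
    sos = scipy.signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=recording.fs, output="sos"
    )
    return replace(recording, data=scipy.signal.sosfiltfilt(sos, recording.data, axis=1))


def normalize_amplitude(segment: Segment) -> Segment:
    """Global per-segment min-max normalization to [0, 1].

    The minimum and maximum are taken over all channels jointly so the
    inter-channel voltage topography — the content of an isopotential map — is
    preserved.  A constant segment maps to 0.5 everywhere.
    """
    if segment.data.size == 0:
        raise DataError("empty segment")
    if not np.isfinite(segment.data).all():
        raise DataError("segment contains NaN/Inf")
    lo, hi = segment.data.min(), segment.data.max()
    if hi == lo:
        return replace(segment, data=np.full_like(segment.data, 0.5))
    return replace(segment, data=(segment.data - lo) / (hi - lo))


def _windows(recording: BspmRecording, seconds: float, stride: int) -> list[Segment]:
    window = int(round(seconds * recording.fs))
    n = recording.n_samples
    out = []
    for start in range(0, n - window + 1, stride):
        out.append(
            Segment(
                data=recording.data[:, start : start + window].copy(),
                fs=recording.fs,
                patient_id=recording.patient_id,
                start_sample=start,
                label=recording.label,
                channel_names=list(recording.channel_names),
            )
        )
    return out


def segment_recording(recording: BspmRecording, seconds: float = 2.0) -> list[Segment]:
    """Cut into consecutive non-overlapping windows; the remainder is dropped."""
    if seconds <= 0:
        raise InvalidParameterError("seconds must be positive")
    return _windows(recording, seconds, int(round(seconds * recording.fs)))


def overlap_augment(
    recording: BspmRecording, seconds: float = 2.0, shift_samples: int = 175
) -> list[Segment]:
    """Sliding windows at a fixed stride (default 175 samples).

    Yields ``floor((L - window) / shift) + 1`` windows for recordings of at
    least one window length.
    """
    if shift_samples < 1:
        raise InvalidParameterError("shift_samples must be >= 1")
    if seconds <= 0:
        raise InvalidParameterError("seconds must be positive")
    return _windows(recording, seconds, int(shift_samples))


def add_baseline_wander(recording: BspmRecording, spec: NoiseSpec) -> BspmRecording:
    """Add band-limited (< 0.5 Hz) baseline-wander noise at ``spec.snr_db``.

    Independent low-frequency noise is synthesized per channel and scaled by a
    single global factor so that 10*log10(P_signal / P_noise) equals the
    requested SNR over the whole recording.
    """
    spec.validate()
    p_signal = float(np.mean(recording.data**2))
    if p_signal == 0.0:
        raise DegenerateInputError("zero-power signal: SNR scaling undefined")
    rng = np.random.default_rng(spec.seed)
    # exactly band-limited process: white noise with all components above
    # 0.5 Hz removed in the Fourier domain (no filter edge transients)
    white = rng.standard_normal(recording.data.shape)
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(recording.n_samples, 1.0 / recording.fs)
    spectrum[:, freqs > 0.5] = 0.0
    noise = np.fft.irfft(spectrum, n=recording.n_samples, axis=1)
    p_noise = float(np.mean(noise**2))
    if p_noise == 0.0:
        raise DegenerateInputError("degenerate noise draw")
    scale = np.sqrt(p_signal / (p_noise * 10.0 ** (spec.snr_db / 10.0)))
    return replace(recording, data=recording.data + scale * noise)


def build_segment_dataset(
    recordings: list[BspmRecording],
    seconds: float = 2.0,
    shift_samples: int = 175,
    balance: bool = True,
) -> list[Segment]:
    """Segment a labeled cohort, overlap-augmenting the minority class.

    Majority-class recordings contribute non-overlapping windows only.  The
    minority (recurrence) class is windowed at ``shift_samples`` stride and the
    pooled minority windows are evenly subsampled so the class counts balance
    (the minority never exceeds the majority count).
    """
    majority: list[Segment] = []
    minority: list[Segment] = []
    for rec in recordings:
        if rec.label == LABEL_RECURRENCE:
            minority.extend(
                overlap_augment(rec, seconds, shift_samples)
                if balance
                else segment_recording(rec, seconds)
            )
        else:
            majority.extend(segment_recording(rec, seconds))
    if balance and minority and len(minority) > max(len(majority), 1):
        idx = np.linspace(0, len(minority) - 1, len(majority)).round().astype(int)
        minority = [minority[i] for i in np.unique(idx)]
    return majority + minority
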