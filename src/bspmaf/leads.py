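"""Approximate limb leads, mean cardiac electrical axis and activation ordering.

Two bipolar surrogates of the Einthoven limb leads are derived from vest
channels: lead I = U29 - U93 (left minus right upper chest) and
lead III = U37 - U29 (lower-left minus upper-left chest).  Summed signed QRS
amplitudes of the two leads give the frontal-plane mean electrical axis via
the Einthoven projection

    alpha = atan2(U_I + 2 * U_III, sqrt(3) * U_I)

which places lead I at 0 deg (toward the patient's left) and lead III at
120 deg.  The activation-sequence analysis ranks the QRS arrival times at six
reference channels laid out along the cardiac axis and reports per-beat
orderings and delays relative to the canonical order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    EmptyInputError,
    InvalidParameterError,
)
from .synthetic import BspmRecording

CANONICAL_REFERENCE_CHANNELS = (93, 112, 3, 5, 25, 36)


@dataclass
class LeadSignal:
    samples: np.ndarray  # mV
    lead_name: str
    fs: float


@dataclass
class ActivationOrder:
    """Per-beat QRS arrival orderings at the reference channels.

    ``orders`` holds one tuple of channel labels per beat (earliest first);
    ``delays_ms`` the per-beat delay of out-of-order channels (0 when the beat
    follows the canonical order); ``order_counts`` the number of beats per
    distinct ordering; ``delay_bins`` beat counts in the {0, 1-3 ms, >3 ms}
    delay categories.
    """

    channel_labels: tuple[int, ...]
    peak_times: np.ndarray  # beats x channels, sample indices
    orders: list[tuple[int, ...]]
    delays_ms: np.ndarray  # per beat, >= 0
    order_counts: dict[tuple[int, ...], int]
    delay_bins: dict[str, int]


def derive_leads(
    recording: BspmRecording,
    ch_I_pos: int | str = 29,
    ch_I_neg: int | str = 93,
    ch_III_pos: int | str = 37,
    ch_III_neg: int | str = 29,
) -> tuple[LeadSignal, LeadSignal]:
    """Lead I = U(ch_I_pos) - U(ch_I_neg); lead III = U(ch_III_pos) - U(ch_III_neg)."""
    try:
        u = {c: recording.channel(c) for c in (ch_I_pos, ch_I_neg, ch_III_pos, ch_III_neg)}
    except ValueError as exc:
        raise ConfigurationError(f"channel missing from recording: {exc}") from exc
    lead_i = LeadSignal(u[ch_I_pos] - u[ch_I_neg], "I", recording.fs)
    lead_iii = LeadSignal(u[ch_III_pos] - u[ch_III_neg], "III", recording.fs)
    return lead_i, lead_iii


def remove_baseline_lowpass(lead: LeadSignal, cutoff_hz: float = 3.0) -> LeadSignal:
    """Subtract the baseline estimated by a first-order Butterworth low-pass."""
    if not 0 < cutoff_hz < lead.fs / 2:
        raise InvalidParameterError(f"invalid cutoff {cutoff_hz} for fs={lead.fs}")
    sos = scipy.signal.butter(1, cutoff_hz, "lowpass", fs=lead.fs, output="sos")
    baseline = scipy.signal.sosfiltfilt(sos, lead.samples)
    return replace(lead, samples=lead.samples - baseline)


def detect_qrs_peaks(
    lead: LeadSignal, refractory_ms: float = 250.0, threshold_frac: float = 0.6
) -> np.ndarray:
    """Indices of QRS peaks: |amplitude| threshold at 0.6x a rolling maximum.

    The rolling maximum uses 2-s blocks; candidate peaks closer than the
    refractory period are suppressed (largest first).
    """
    x = np.abs(lead.samples)
    n = len(x)
    if n == 0:
        raise EmptyInputError("empty lead")
    block = max(int(2.0 * lead.fs), 1)
    n_blocks = max(n // block, 1)
    local_max = np.array([x[i * block : (i + 1) * block].max() for i in range(n_blocks)])
    thr = threshold_frac * np.median(local_max)
    distance = max(int(refractory_ms / 1000.0 * lead.fs), 1)
    peaks, _ = scipy.signal.find_peaks(x, height=thr, distance=distance)
    return peaks


def sum_qrs_amplitudes(lead: LeadSignal, beats: np.ndarray | None = None) -> float:
    """Sum of signed QRS peak amplitudes over the detected (or given) beats.

    Positive R peaks add to the sum and dominant negative deflections
    subtract, so the sum carries the lead's mean polarity.
    """
    if beats is None:
        beats = detect_qrs_peaks(lead)
    if len(beats) == 0:
        raise EmptyInputError("no beats found")
    return float(np.sum(lead.samples[np.asarray(beats, dtype=int)]))


def cardiac_axis_angle(u_i: float, u_iii: float) -> float:
    """Frontal-plane mean electrical axis (degrees in (-180, 180]).

    Uses the Einthoven projection: with lead I along 0 deg and lead III along
    120 deg, the mean QRS vector direction is
    atan2(U_I + 2*U_III, sqrt(3)*U_I).  Scale-invariant in (U_I, U_III).
    """
    if u_i == 0.0 and u_iii == 0.0:
        raise DegenerateInputError("axis undefined for U_I = U_III = 0")
    return math.degrees(math.atan2(u_i + 2.0 * u_iii, math.sqrt(3.0) * u_i))


def recording_axis(
    recording: BspmRecording,
    ch_I_pos: int | str = 29,
    ch_I_neg: int | str = 93,
    ch_III_pos: int | str = 37,
    ch_III_neg: int | str = 29,
) -> tuple[float, float, float]:
    """Convenience: derive leads, de-trend, and return (U_I, U_III, angle_deg).

    Beats are detected once on lead I and the same beat windows index both
    leads, as the axis construction requires paired amplitudes.
    """
    lead_i, lead_iii = derive_leads(recording, ch_I_pos, ch_I_neg, ch_III_pos, ch_III_neg)
    lead_i = remove_baseline_lowpass(lead_i)
    lead_iii = remove_baseline_lowpass(lead_iii)
    beats = detect_qrs_peaks(lead_i)
    if len(beats) == 0:
        raise EmptyInputError("no beats found")
    # per-beat signed extremum within +-60 ms of the lead-I peak
    half = int(0.06 * recording.fs)

    def signed_sum(lead: LeadSignal) -> float:
        total = 0.0
        for b in beats:
            w = lead.samples[max(b - half, 0) : b + half + 1]
            total += w[np.argmax(np.abs(w))]
        return total

    u_i, u_iii = signed_sum(lead_i), signed_sum(lead_iii)
    return u_i, u_iii, cardiac_axis_angle(u_i, u_iii)


def activation_sequence(
    recording: BspmRecording,
    reference_channels: tuple[int, ...] = CANONICAL_REFERENCE_CHANNELS,
    window_ms: float = 120.0,
) -> ActivationOrder:
    """Rank QRS arrival times at the reference channels, beat by beat.

    Beats are located on the mean absolute signal across the reference
    channels; within +-``window_ms`` of each beat the per-channel arrival is
    the time of the absolute-amplitude extremum.  Ties in arrival time are
    broken by position in ``reference_channels``.  The per-beat delay is the
    largest pairwise arrival-time inversion against the canonical order, in
    ms, binned as {0, 1-3 ms, >3 ms}.
    """
    chans = np.stack([recording.channel(c) for c in reference_channels])
    composite = LeadSignal(np.abs(chans).mean(axis=0), "composite", recording.fs)
    beats = detect_qrs_peaks(composite)
    if len(beats) == 0:
        raise EmptyInputError("no detectable beats")

    half = int(window_ms / 1000.0 * recording.fs)
    n = chans.shape[1]
    peak_times = np.zeros((len(beats), len(reference_channels)), dtype=int)
    orders: list[tuple[int, ...]] = []
    delays = np.zeros(len(beats))
    for bi, b in enumerate(beats):
        lo, hi = max(b - half, 0), min(b + half + 1, n)
        seg = np.abs(chans[:, lo:hi])
        arrival = lo + seg.argmax(axis=1)
        peak_times[bi] = arrival
        rank = sorted(range(len(reference_channels)), key=lambda k: (arrival[k], k))
        orders.append(tuple(reference_channels[k] for k in rank))
        inv = 0.0
        for i in range(len(arrival)):
            for j in range(i + 1, len(arrival)):
                inv = max(inv, float(arrival[i] - arrival[j]))
        delays[bi] = inv / recording.fs * 1000.0

    order_counts: dict[tuple[int, ...], int] = {}
    for o in orders:
        order_counts[o] = order_counts.get(o, 0) + 1
    bins = {
        "0": int(np.sum(delays == 0)),
        "1-3 ms": int(np.sum((delays > 0) & (delays <= 3.0))),
        ">3 ms": int(np.sum(delays > 3.0)),
    }
    return ActivationOrder(
        channel_labels=tuple(reference_channels),
        peak_times=peak_times,
        orders=orders,
        delays_ms=delays,
        order_counts=order_counts,
        delay_bins=bins,
    )
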