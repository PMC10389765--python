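"""Phase segmentation and per-modality signal conditioning.

All filters are applied forward-backward (zero-phase) so that feature
windows stay aligned across modalities.  The conditioning chain is:

* EMG: 4th-order Butterworth band-pass, 20-450 Hz (the surface-EMG
  convention; the recording system's own pass-band is wider).
* CoP: Savitzky-Golay smoothing, window 7 samples, polynomial order 3 —
  the common stabilogram choice; endpoints use the polynomial fit on the
  truncated window.
* EEG: anti-aliased decimation 4096 -> 1024 Hz, then a zero-phase
  1-45 Hz band-pass.  Channels that are flat or whose typical amplitude
  is an extreme outlier (> ``bad_channel_sd`` robust SDs above the
  channel-median amplitude) are replaced by the mean of the remaining
  good channels and flagged in the series metadata.  This simple
  amplitude gate stands in for interactive artifact screening; it is a
  declared simplification, switchable off via ``bad_channel_sd=None``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .session import (
    PhaseLabel,
    PhaseSchedule,
    Session,
    TimeSeries,
    ValidationError,
)

__all__ = [
    "PhaseSegmentSet",
    "segment_phases",
    "segment_timeseries",
    "filter_emg",
    "smooth_cop",
    "preprocess_eeg",
]

EMG_BAND = (20.0, 450.0)
SG_WINDOW = 7
SG_POLYORDER = 3
EEG_BAND = (1.0, 45.0)
EEG_TARGET_RATE = 1024.0
BAD_CHANNEL_SD = 5.0


@dataclass
class PhaseSegmentSet:
    """Per-modality map ``PhaseLabel -> TimeSeries`` slice."""

    segments: dict  # {modality: {PhaseLabel: TimeSeries}}

    def get(self, modality: str, phase: PhaseLabel | str) -> TimeSeries:
        return self.segments[modality][PhaseLabel(phase)]

    def phases(self, modality: str) -> list[PhaseLabel]:
        return list(self.segments[modality])


def segment_timeseries(ts: TimeSeries, schedule: PhaseSchedule) -> dict:
    """Slice one signal into ``{PhaseLabel: TimeSeries}`` by sample index
    ``[floor(rate*start), floor(rate*end))``."""
    out = {}
    for label, start, end in schedule.entries:
        i1 = int(np.floor(ts.rate * end))
        if i1 > ts.n_samples:
            raise ValidationError(
                f"phase {label} ends at {end} s but the recording holds only "
                f"{ts.duration_s:.2f} s"
            )
        out[label] = ts.slice_seconds(start, end)
    return out


def segment_phases(session: Session, schedule: PhaseSchedule) -> PhaseSegmentSet:
    """Slice every modality of a session into its scheduled phases."""
    return PhaseSegmentSet(
        {m: segment_timeseries(session.modality(m), schedule)
         for m in Session.MODALITIES}
    )


def filter_emg(emg: TimeSeries, band: tuple[float, float] = EMG_BAND) -> TimeSeries:
    """Zero-phase 4th-order Butterworth band-pass per channel."""
    if emg.rate < 1000.0:
        raise ValidationError(
            f"EMG band-pass {band} Hz undefined at rate {emg.rate} Hz"
        )
    sos = signal.butter(4, band, btype="bandpass", fs=emg.rate, output="sos")
    vals = signal.sosfiltfilt(sos, np.asarray(emg.values, dtype=float), axis=0)
    return replace(emg, values=vals, meta=dict(emg.meta))


def smooth_cop(cop: TimeSeries, window: int = SG_WINDOW,
               polyorder: int = SG_POLYORDER) -> TimeSeries:
    """Savitzky-Golay smoothing of the sway trajectory, per channel."""
    if cop.n_samples < window:
        raise ValidationError(
            f"need at least {window} samples for Savitzky-Golay smoothing, "
            f"got {cop.n_samples}"
        )
    vals = signal.savgol_filter(np.asarray(cop.values, dtype=float),
                                window_length=window, polyorder=polyorder,
                                axis=0, mode="interp")
    return replace(cop, values=vals, meta=dict(cop.meta))


def preprocess_eeg(eeg: TimeSeries, band: tuple[float, float] = EEG_BAND,
                   target_rate: float = EEG_TARGET_RATE,
                   bad_channel_sd: float | None = BAD_CHANNEL_SD) -> TimeSeries:
    """Decimate to 1024 Hz, band-pass 1-45 Hz, gate bad channels.

    The decimation factor is ``rate / target_rate`` and must be an
    integer (4 for the native 4096 Hz).  Bad channels (flat, or robust
    amplitude > ``bad_channel_sd`` SDs above the channel median) are
    replaced by the mean of the remaining channels; their labels are
    recorded in ``meta["bad_channels"]``.  More than 50 % bad channels
    aborts.
    """
    factor = eeg.rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValidationError(
            f"rate {eeg.rate} Hz is not an integer multiple of {target_rate} Hz"
        )
    vals = np.asarray(eeg.values, dtype=float)
    factor = int(round(factor))
    if factor > 1:
        vals = signal.decimate(vals, factor, axis=0, ftype="fir",
                               zero_phase=True)
    sos = signal.butter(4, band, btype="bandpass", fs=target_rate, output="sos")
    vals = signal.sosfiltfilt(sos, vals, axis=0)

    meta = dict(eeg.meta)
    bad: list[str] = []
    if bad_channel_sd is not None:
        amp = np.median(np.abs(vals), axis=0)
        med = np.median(amp)
        # MAD-scaled robust SD so one extreme channel cannot mask itself
        sd = 1.4826 * np.median(np.abs(amp - med))
        flat = np.ptp(vals, axis=0) == 0
        outlier = amp > med + bad_channel_sd * sd if sd > 0 else np.zeros_like(flat)
        bad_mask = flat | outlier
        if bad_mask.sum() > 0.5 * eeg.n_channels:
            raise ValidationError(
                f"{bad_mask.sum()} of {eeg.n_channels} channels flagged bad"
            )
        if bad_mask.any():
            good_mean = vals[:, ~bad_mask].mean(axis=1)
            vals[:, bad_mask] = good_mean[:, None]
            bad = [eeg.channel_labels[i] for i in np.flatnonzero(bad_mask)]
    meta["bad_channels"] = bad
    return TimeSeries(vals, target_rate, list(eeg.channel_labels),
                      eeg.units, meta)
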