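"""Absolute EEG band power per electrode and topographic group comparison.

Band powers are Welch PSD integrals over the canonical bands
delta (0-4], theta (4-8], alpha (8-13], beta (13-30] Hz, computed on the
preprocessed (1024 Hz, 1-45 Hz) phase segment with 2 s Hann windows and
50 % overlap (0.5 Hz resolution).  Bands share their edge frequencies,
so the trapezoidal band integrals add up exactly to the integral over
(0, 30].

The topographic comparison runs a two-sided Mann-Whitney U-test per
electrode on the absolute band power, then applies Benjamini-Hochberg
FDR across the 64 electrodes within one (band, phase) family; an
electrode is flagged significant when its adjusted p-value is <= 0.05.
Each record carries both the raw and the adjusted p-value and the sign
of the group-median difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .group_stats import ComparisonRecord, bh_fdr, delta_magnitude, cliffs_delta, mann_whitney
from .session import PhaseLabel, TimeSeries, ValidationError

__all__ = [
    "BandDefinition",
    "BANDS",
    "BandPowerMap",
    "welch_psd",
    "band_power",
    "band_power_map",
    "topographic_comparison",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float


BANDS = {
    "delta": BandDefinition("delta", 0.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
}


@dataclass
class BandPowerMap:
    """Absolute band powers of one subject and phase.

    ``powers`` is a DataFrame indexed by electrode with one column per
    band, in uV^2.
    """

    subject: str
    phase: PhaseLabel
    powers: pd.DataFrame

    def value(self, electrode: str, band: str) -> float:
        return float(self.powers.loc[electrode, band])


def welch_psd(eeg_segment: TimeSeries, window_s: float = 2.0):
    """Welch PSD per channel: ``window_s`` Hann windows, 50 % overlap.

    Returns ``(frequencies, psd)`` with ``psd`` of shape
    (n_channels, n_freqs) in units^2/Hz.
    """
    if eeg_segment.duration_s < 2 * window_s:
        raise ValidationError(
            f"PSD needs a segment of at least {2 * window_s:.0f} s, got "
            f"{eeg_segment.duration_s:.2f} s"
        )
    nperseg = int(window_s * eeg_segment.rate)
    f, p = signal.welch(np.asarray(eeg_segment.values, dtype=float),
                        fs=eeg_segment.rate, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2, detrend=False, axis=0)
    return f, p.T


def band_power(frequencies: np.ndarray, psd: np.ndarray,
               band: BandDefinition) -> np.ndarray:
    """Trapezoidal PSD integral over [band.lo, band.hi] per channel.

    Adjacent bands share their edge bin, so integrals over the
    contiguous canonical bands partition the integral over their union.
    """
    f = np.asarray(frequencies)
    if band.lo < f[0] - 1e-9 or band.hi > f[-1] + 1e-9:
        raise ValidationError(
            f"band {band.name} [{band.lo}, {band.hi}] Hz outside the "
            f"spectrum [{f[0]}, {f[-1]}] Hz"
        )
    mask = (f >= band.lo - 1e-9) & (f <= band.hi + 1e-9)
    p = np.atleast_2d(psd)[:, mask]
    return np.trapezoid(p, f[mask], axis=1)


def band_power_map(eeg_segment: TimeSeries, subject: str,
                   phase: PhaseLabel, relative: bool = False) -> BandPowerMap:
    """All four band powers for every electrode of one phase segment.

    With ``relative=True`` each band is divided by the channel's total
    power over (0, 30] Hz (off by default; absolute power is the
    primary quantity).  Channels flagged bad during preprocessing
    (``meta["bad_channels"]``) get NaN powers so they drop out of group
    statistics.
    """
    f, psd = welch_psd(eeg_segment)
    data = {name: band_power(f, psd, b) for name, b in BANDS.items()}
    df = pd.DataFrame(data, index=list(eeg_segment.channel_labels))
    if relative:
        total = band_power(f, psd, BandDefinition("total", 0.0, 30.0))
        df = df.div(np.where(total > 0, total, np.nan), axis=0)
    bad = eeg_segment.meta.get("bad_channels", [])
    if bad:
        df.loc[bad] = np.nan
    return BandPowerMap(subject, PhaseLabel(phase), df)


def topographic_comparison(group_a: list[BandPowerMap],
                           group_b: list[BandPowerMap], band: str,
                           phase: PhaseLabel | str,
                           alpha: float = 0.05) -> list[ComparisonRecord]:
    """Per-electrode Mann-Whitney comparison of one band with BH-FDR.

    ``group_a`` / ``group_b`` are per-subject band power maps (healthy
    first by convention, so a positive delta means higher power in the
    healthy group).  The FDR family is the full electrode set of this
    (band, phase).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("need at least 2 subjects per group")
    if band not in BANDS:
        raise ValidationError(f"unknown band {band!r}")
    electrodes = list(group_a[0].powers.index)
    a = np.array([m.powers[band].loc[electrodes].to_numpy() for m in group_a])
    b = np.array([m.powers[band].loc[electrodes].to_numpy() for m in group_b])
    records = []
    for ei, el in enumerate(electrodes):
        xa, xb = a[:, ei], b[:, ei]
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        flags: tuple[str, ...] = ()
        if len(xa) < 2 or len(xb) < 2:  # channel excluded in most subjects
            records.append(
                ComparisonRecord(f"{band}/{el}", str(PhaseLabel(phase)),
                                 "mann_whitney", 1.0, 0.0, "negligible",
                                 False, flags=("insufficient_data",)))
            continue
        if np.ptp(np.concatenate([xa, xb])) == 0:
            p = 1.0
            flags = ("degenerate",)
        else:
            p = mann_whitney(xa, xb)
        delta, mag = cliffs_delta(xa, xb)
        records.append(
            ComparisonRecord(f"{band}/{el}", str(PhaseLabel(phase)),
                             "mann_whitney", p, delta, mag, False,
                             flags=flags)
        )
    adj = bh_fdr([r.p_value for r in records])
    for r, q in zip(records, adj):
        r.p_adjusted = float(q)
        r.significant = bool(q <= alpha)
    return records
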