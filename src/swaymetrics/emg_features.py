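"""Per-muscle, per-phase surface-EMG feature battery.

Forty-three features are computed on each filtered single-channel
segment: seven from the Welch spectrum and thirty-six from the time
domain.  The battery follows the standard surface-EMG feature-extraction
literature; each definition is given in its docstring or inline below,
because the mnemonics alone (MAV, WL, SSI, ...) admit variants.  Where a
mnemonic is genuinely ambiguous in the literature (ASM, ASS, MSR, VARE,
VO) the definition used here is stated explicitly and should be read as
this package's choice, not as a community standard.

Conventions: ``x`` is the filtered segment of length ``N``;
``dx[i] = x[i+1] - x[i]``; "sample" statistics use ``ddof=1``.  The
zero-mean convention of the EMG literature is kept for SSI/VAR (second
moments about zero), while VARE is the ordinary sample variance about
the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .session import PhaseLabel, TimeSeries, ValidationError

__all__ = [
    "EMGFeatureSet",
    "FREQUENCY_FEATURES",
    "TIME_FEATURES",
    "ALL_FEATURES",
    "emg_frequency_features",
    "emg_time_features",
    "extract_emg_features",
    "extract_emg_all",
]

FREQUENCY_FEATURES = ("PT", "Pmax", "Fmax", "FMD", "FMN", "Fkurt", "Fskew")

TIME_FEATURES = (
    "AAC", "AE", "ASM", "ASS", "CV", "DAMV", "DASDV", "DVARV", "EMAV",
    "EWL", "FZC", "KURT", "IEMG", "IQR", "LCV", "LD", "LDAMV", "LDASDV",
    "LTKEO", "MAD", "MAV", "MFL", "MN", "MD", "MMAV", "MMAV2", "MSR",
    "RMS", "SD", "SKEW", "SSI", "TM", "VAR", "VARE", "VO", "WL",
)

ALL_FEATURES = FREQUENCY_FEATURES + TIME_FEATURES
assert len(ALL_FEATURES) == 43

#: relative threshold of the "new zero crossing" count (fraction of RMS)
FZC_THRESHOLD_RMS = 0.01

_EPS = 1e-300  # guards log/division on exact zeros only


@dataclass
class EMGFeatureSet:
    """The 43 named feature values of one (muscle, phase) segment."""

    muscle: str
    phase: PhaseLabel
    values: dict

    def __post_init__(self) -> None:
        missing = set(ALL_FEATURES) - set(self.values)
        extra = set(self.values) - set(ALL_FEATURES)
        if missing or extra:
            raise ValidationError(
                f"feature set must have exactly the 43 names; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )


def emg_frequency_features(x: np.ndarray, rate: float) -> dict:
    """Seven spectral features from a Welch periodogram.

    Welch parameters: 2 s Hann windows, 50 % overlap (or one window if
    the segment is shorter).  PT is the integrated power, Pmax/Fmax the
    spectral peak, FMD the median frequency (half the power below),
    FMN the spectral centroid, and Fkurt/Fskew the kurtosis and skewness
    of the PSD treated as a distribution over frequency.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2 * rate:
        raise ValidationError("frequency features need a segment of >= 2 s")
    if np.all(x == 0):
        raise ValidationError("degenerate spectrum: all-zero segment")
    nperseg = min(int(2 * rate), x.size)
    f, p = signal.welch(x, fs=rate, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2, detrend=False)
    df = f[1] - f[0]
    pt = float(np.sum(p) * df)
    k = int(np.argmax(p))
    w = p / np.sum(p)
    fmn = float(np.sum(f * w))
    cum = np.cumsum(p)
    fmd = float(f[int(np.searchsorted(cum, cum[-1] / 2.0))])
    var = float(np.sum((f - fmn) ** 2 * w))
    sd = np.sqrt(var)
    if sd > 0:
        fskew = float(np.sum((f - fmn) ** 3 * w) / sd ** 3)
        fkurt = float(np.sum((f - fmn) ** 4 * w) / sd ** 4)
    else:
        fskew, fkurt = 0.0, 0.0
    return {
        "PT": pt,
        "Pmax": float(np.max(p)),
        "Fmax": float(f[k]),
        "FMD": fmd,
        "FMN": fmn,
        "Fkurt": fkurt,
        "Fskew": fskew,
    }


def emg_time_features(x: np.ndarray) -> dict:
    """The 36 time-domain features; definitions inline."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValidationError("time-domain features need at least 3 samples")
    ax = np.abs(x)
    dx = np.diff(x)
    adx = np.abs(dx)

    ssi = float(np.sum(x ** 2))                     # second moment about 0
    rms = float(np.sqrt(ssi / n))
    wl = float(np.sum(adx))                         # waveform length
    mav = float(np.mean(ax))
    mn = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    cv = sd / max(abs(mn), _EPS)

    # position-weighted variants: full weight on the central half of the
    # segment (0.25 N .. 0.75 N), reduced weight in the tails
    idx = np.arange(n)
    central = (idx >= 0.25 * n) & (idx <= 0.75 * n)
    p_exp = np.where(central, 0.75, 0.5)            # EMAV / EWL exponents
    w_mmav = np.where(central, 1.0, 0.5)
    w_mmav2 = np.where(central, 1.0,
                       np.where(idx < 0.25 * n, 4 * idx / n, 4 * (n - idx) / n))
    idx_d = np.arange(n - 1)
    central_d = (idx_d >= 0.25 * n) & (idx_d <= 0.75 * n)
    p_exp_d = np.where(central_d, 0.75, 0.5)

    # zero crossings that jump by more than a fraction of the RMS
    thresh = FZC_THRESHOLD_RMS * rms
    crossing = (np.sign(x[:-1]) * np.sign(x[1:]) < 0) & (adx >= thresh)

    # Teager-Kaiser energy: psi_i = x_i^2 - x_{i-1} x_{i+1}
    tkeo = x[1:-1] ** 2 - x[:-2] * x[2:]

    damv = float(np.mean(adx))
    dasdv = float(np.sqrt(np.mean(dx ** 2)))

    feats = {
        "AAC": wl / (n - 1),                        # average amplitude change
        "AE": ssi / n,                              # average energy
        "ASM": float(np.sum(ax ** (1.0 / 3.0))),    # sum of cube roots
        "ASS": float(np.sum(np.sqrt(ax))),          # sum of square roots
        "CV": cv,                                   # SD / |mean|
        "DAMV": damv,                               # MAV of first difference
        "DASDV": dasdv,                             # RMS of first difference
        "DVARV": float(np.sum(dx ** 2) / max(n - 2, 1)),
        "EMAV": float(np.mean(ax ** p_exp)),        # enhanced MAV
        "EWL": float(np.sum(adx ** p_exp_d)),       # enhanced waveform length
        "FZC": float(np.count_nonzero(crossing)),
        "KURT": float(stats.kurtosis(x, fisher=False, bias=True)) if sd > 0 else 0.0,
        "IEMG": float(np.sum(ax)),
        "IQR": float(np.subtract(*np.percentile(x, [75, 25]))),
        "LCV": float(np.log10(max(cv, _EPS))),
        "LD": float(np.exp(np.mean(np.log(np.maximum(ax, _EPS))))),
        "LDAMV": float(np.log10(max(damv, _EPS))),
        "LDASDV": float(np.log10(max(dasdv, _EPS))),
        "LTKEO": float(np.log(max(abs(float(np.sum(tkeo))), _EPS))),
        "MAD": float(np.mean(np.abs(x - mn))),
        "MAV": mav,
        "MFL": float(np.log10(max(np.sqrt(np.sum(dx ** 2)), _EPS))),
        "MN": mn,
        "MD": float(np.median(x)),
        "MMAV": float(np.mean(w_mmav * ax)),
        "MMAV2": float(np.mean(w_mmav2 * ax)),
        "MSR": float(np.mean(np.sqrt(ax))),
        "RMS": rms,
        "SD": sd,
        "SKEW": float(stats.skew(x, bias=True)) if sd > 0 else 0.0,
        "SSI": ssi,
        "TM": float(abs(np.mean(x ** 3))),          # |3rd temporal moment|
        "VAR": ssi / (n - 1),                       # zero-mean convention
        "VARE": float(np.var(x, ddof=1)),           # variance about the mean
        "VO": float(np.mean(ax ** 3) ** (1.0 / 3.0)),  # v-order, v = 3
        "WL": wl,
    }
    return feats


def extract_emg_features(segment: np.ndarray, rate: float, muscle: str,
                         phase: PhaseLabel) -> EMGFeatureSet:
    """All 43 features of one single-channel filtered segment."""
    values = emg_frequency_features(segment, rate)
    values.update(emg_time_features(segment))
    return EMGFeatureSet(muscle, PhaseLabel(phase), values)


def extract_emg_all(phase_segments: dict, muscles=None) -> list[EMGFeatureSet]:
    """One feature set per (muscle, phase).

    ``phase_segments`` maps ``PhaseLabel -> TimeSeries`` (six filtered
    EMG channels).  Ordering is deterministic: phases in map order,
    muscles in channel order.
    """
    out: list[EMGFeatureSet] = []
    for phase, ts in phase_segments.items():
        names = muscles if muscles is not None else ts.channel_labels
        for muscle in names:
            x = ts.channel(muscle)
            out.append(extract_emg_features(x, ts.rate, muscle, phase))
    return out
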