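"""Seeded two-cohort session generator with known effect directions.

The study's raw recordings are not deposited, so every downstream stage
is exercised on synthetic cohorts whose group differences are *known by
construction*.  The generator emulates the reported effect directions,
not the physiology:

* CoP sway: a mean-reverting (Ornstein-Uhlenbeck) process per axis whose
  stationary SD is the per-group ``cop_sway_scale``; healthy sway is
  larger than PD by default.  The ML channel is a convex mixture of a
  smooth OU component and white jitter with weight ``cop_ml_complexity``
  (rescaled to the target SD), so medio-lateral irregularity — and hence
  sample entropy and the complexity index — is higher in the PD group.
* EMG: Gaussian noise band-limited to 20-450 Hz, amplitude-modulated by
  a smooth random burst envelope, with a per-muscle per-group gain
  (right tibialis anterior larger in healthy controls by default).
* EEG: a 1/f background plus one narrowband oscillation per band
  (delta/theta/alpha/beta) with random phase per channel; the
  ``eeg_band_offset`` map multiplies a band oscillation's power at named
  electrodes per group (default: PD alpha suppression at FC5, T7, T8,
  FT8, P4, PO6).
* Heart rate: a per-subject baseline around the group mean plus slow
  AR(1) wander, with ``hr_trend_post`` bpm added during POST (PD higher).

Between-subject variability (log-normal amplitude jitter, additive
complexity jitter, baseline HR spread) is built in so that group
comparisons face realistic overlap rather than delta-function cohorts.

Determinism: every random stream is derived from
``SeedSequence([seed, group_code, subject_index, stream, phase_index])``,
so a subject's signals never depend on how many other subjects exist,
and each scheduled phase is synthesised as an independent stationary
block.  Phase boundaries coincide with segmentation boundaries, so
analysing a phase slice of a full session and generating that phase in
isolation give bit-identical values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft

from .montage import COP_AXES, EEG_MONTAGE_64, EMG_MUSCLES
from .session import (
    DEFAULT_SCHEDULE,
    GROUPS,
    PhaseLabel,
    PhaseSchedule,
    Session,
    TimeSeries,
    ValidationError,
)

__all__ = [
    "SynthParams",
    "CohortCollection",
    "generate_cop",
    "generate_emg",
    "generate_eeg",
    "generate_hr",
    "generate_cohort_session",
    "generate_phase_segments",
    "assemble_collection",
    "null_params",
]

COP_RATE = 90.0
EMG_RATE = 1600.0
EEG_RATE = 4096.0
HR_RATE = 1.0

_GROUP_CODE = {g: i for i, g in enumerate(GROUPS)}
_STREAM = {"traits": 0, "cop": 1, "emg": 2, "eeg": 3, "hr": 4}

#: Band oscillation centre frequencies (Hz) and base RMS-ish amplitudes (uV).
BAND_CENTER = {"delta": 2.0, "theta": 6.0, "alpha": 10.5, "beta": 21.5}
_BAND_AMP = {"delta": 6.0, "theta": 5.0, "alpha": 10.0, "beta": 3.0}
#: 1/f background level: PSD(f) = _EEG_PINK_LEVEL / f  (uV^2/Hz), 0.5-120 Hz.
_EEG_PINK_LEVEL = 20.0
_EEG_F_MAX = 120.0

_EMG_BASE_RMS_MV = 0.05
_EMG_BAND = (20.0, 450.0)


def _pergroup(healthy, pd):
    return {"healthy": healthy, "pd": pd}


@dataclass
class SynthParams:
    """Cohort-generation parameters; defaults are the study conditions.

    Per-group values are ``{"healthy": x, "pd": y}`` dictionaries.
    """

    n_healthy: int = 29
    n_pd: int = 9
    seed: int = 0
    #: stationary sway SD per axis, mm (healthy sway > PD sway)
    cop_sway_scale: dict = field(default_factory=lambda: _pergroup(3.0, 2.0))
    #: white-jitter mixing weight of the ML channel, in [0, 1]
    cop_ml_complexity: dict = field(default_factory=lambda: _pergroup(0.3, 0.7))
    #: per-muscle amplitude gain (right TA larger in controls)
    emg_burst_gain: dict = field(
        default_factory=lambda: _pergroup(
            {"R_TA": 1.3}, {}
        )
    )
    #: (electrode, band) -> per-group multiplicative power factor
    eeg_band_offset: dict = field(
        default_factory=lambda: {
            (el, "alpha"): _pergroup(1.0, 0.5)
            for el in ("FC5", "T7", "T8", "FT8", "P4", "PO6")
        }
    )
    #: group mean heart rate, bpm, and bpm added during POST
    hr_mean: dict = field(default_factory=lambda: _pergroup(82.5, 88.8))
    hr_trend_post: dict = field(default_factory=lambda: _pergroup(0.0, 5.4))
    #: between-subject baseline HR spread, bpm
    hr_between_sd: dict = field(default_factory=lambda: _pergroup(14.6, 18.1))
    #: between-subject log-normal sigmas / additive jitters
    subject_scale_sigma: float = 0.25
    subject_complexity_sd: float = 0.08
    subject_emg_sigma: float = 0.2
    subject_eeg_amp_sigma: float = 0.15
    subject_band_sigma: float = 0.1

    def validate(self) -> None:
        if self.n_healthy < 2 or self.n_pd < 2:
            raise ValidationError("need at least 2 subjects per group")
        for g in GROUPS:
            if self.cop_sway_scale[g] <= 0:
                raise ValidationError("cop_sway_scale must be positive")
            if not 0.0 <= self.cop_ml_complexity[g] <= 1.0:
                raise ValidationError("cop_ml_complexity must lie in [0, 1]")
            for m, gain in self.emg_burst_gain[g].items():
                if m not in EMG_MUSCLES:
                    raise ValidationError(f"unknown muscle {m!r}")
                if gain <= 0:
                    raise ValidationError("emg_burst_gain must be positive")
        for (el, band), factors in self.eeg_band_offset.items():
            if el not in EEG_MONTAGE_64:
                raise ValidationError(f"unknown electrode {el!r} in eeg_band_offset")
            if band not in BAND_CENTER:
                raise ValidationError(f"unknown band {band!r} in eeg_band_offset")
            for g in GROUPS:
                if factors[g] <= 0:
                    raise ValidationError("band power factors must be positive")

    def muscle_gain(self, group: str, muscle: str) -> float:
        return float(self.emg_burst_gain[group].get(muscle, 1.0))

    def band_factor(self, group: str, electrode: str, band: str) -> float:
        return float(self.eeg_band_offset.get((electrode, band), {}).get(group, 1.0))


def null_params(**overrides) -> SynthParams:
    """Parameters with all group differences removed (null configuration)."""
    p = SynthParams(
        cop_sway_scale=_pergroup(2.5, 2.5),
        cop_ml_complexity=_pergroup(0.5, 0.5),
        emg_burst_gain=_pergroup({}, {}),
        eeg_band_offset={},
        hr_mean=_pergroup(82.5, 82.5),
        hr_trend_post=_pergroup(0.0, 0.0),
        hr_between_sd=_pergroup(15.0, 15.0),
    )
    return replace(p, **overrides)


@dataclass
class CohortCollection:
    sessions: list[Session]
    params: SynthParams


# ---------------------------------------------------------------------------
# seeded stream derivation

def _rng(seed: int, group: str, subject_index: int, stream: str,
         phase_index: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(
        [int(seed), _GROUP_CODE[group], int(subject_index),
         _STREAM[stream], int(phase_index)]
    )
    return np.random.default_rng(ss)


@dataclass
class _SubjectTraits:
    sway_scale: float
    complexity: float
    emg_gains: np.ndarray  # per muscle
    eeg_amp: float
    band_jitter: dict
    hr_base: float


def _subject_traits(params: SynthParams, group: str, index: int) -> _SubjectTraits:
    r = _rng(params.seed, group, index, "traits")
    sway = params.cop_sway_scale[group] * float(
        np.exp(params.subject_scale_sigma * r.standard_normal()))
    comp = float(np.clip(
        params.cop_ml_complexity[group]
        + params.subject_complexity_sd * r.standard_normal(), 0.0, 1.0))
    gains = np.array([
        params.muscle_gain(group, m)
        * np.exp(params.subject_emg_sigma * r.standard_normal())
        for m in EMG_MUSCLES
    ])
    eeg_amp = float(np.exp(params.subject_eeg_amp_sigma * r.standard_normal()))
    band_jit = {b: float(np.exp(params.subject_band_sigma * r.standard_normal()))
                for b in BAND_CENTER}
    hr_base = params.hr_mean[group] + params.hr_between_sd[group] * float(
        r.standard_normal())
    return _SubjectTraits(sway, comp, gains, eeg_amp, band_jit, hr_base)


# ---------------------------------------------------------------------------
# signal primitives

def _ou(n: int, rate: float, tau_s: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary Ornstein-Uhlenbeck path (exact AR(1))."""
    a = np.exp(-1.0 / (rate * tau_s))
    innov = rng.standard_normal(n) * np.sqrt(1.0 - a * a)
    innov[0] = rng.standard_normal()  # stationary start
    x = np.empty(n)
    acc = innov[0]
    x[0] = acc
    # scipy.signal.lfilter would do, but the loop is clearer and this is
    # not a hot path at CoP/HR rates.
    for i in range(1, n):
        acc = a * acc + innov[i]
        x[i] = acc
    return x


def _ou_fast(n: int, rate: float, tau_s: float, rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import lfilter
    a = np.exp(-1.0 / (rate * tau_s))
    innov = rng.standard_normal(n) * np.sqrt(1.0 - a * a)
    innov[0] = rng.standard_normal()
    return lfilter([1.0], [1.0, -a], innov)


def _cop_block(n: int, scale_mm: float, complexity: float,
               rng: np.random.Generator) -> np.ndarray:
    """2-channel (ML, AP) sway block with stationary SD ``scale_mm``."""
    smooth = _ou_fast(n, COP_RATE, 1.0, rng)
    white = rng.standard_normal(n)
    c = complexity
    norm = np.sqrt((1.0 - c) ** 2 + c ** 2)
    ml = scale_mm * ((1.0 - c) * smooth + c * white) / norm
    ap = scale_mm * _ou_fast(n, COP_RATE, 1.0, rng)
    return np.column_stack([ml, ap])


def _noise_spectrum(n: int, rate: float, psd_at_bin, rng: np.random.Generator,
                    dtype=np.complex128) -> np.ndarray:
    """One-sided spectrum whose irfft has one-sided PSD ``psd_at_bin(f)``."""
    duration = n / rate
    nf = n // 2 + 1
    f = np.arange(nf) / duration
    sigma = n * np.sqrt(np.maximum(psd_at_bin(f), 0.0) / (4.0 * duration))
    z = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
    spec = (sigma * z).astype(dtype)
    spec[0] = 0.0
    return spec


def _emg_block(n: int, gains: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """6-channel burst-modulated band-limited (20-450 Hz) noise, mV."""
    lo, hi = _EMG_BAND
    bw = hi - lo
    out = np.empty((n, len(gains)))
    env_rate = 50.0
    n_env = max(int(np.ceil(n * env_rate / EMG_RATE)) + 1, 4)
    t_env = np.arange(n_env) / env_rate
    t = np.arange(n) / EMG_RATE
    for ch, gain in enumerate(gains):
        level = _EMG_BASE_RMS_MV ** 2 / bw  # flat PSD inside the band
        spec = _noise_spectrum(
            n, EMG_RATE,
            lambda f: np.where((f >= lo) & (f <= hi), level, 0.0), rng)
        x = sfft.irfft(spec, n=n)
        env = 1.0 + 0.5 * _ou_fast(n_env, env_rate, 0.25, rng)
        env = np.clip(env, 0.05, None)
        out[:, ch] = gain * x * np.interp(t, t_env, env)
    return out


def _eeg_block(n: int, band_amps: np.ndarray, global_amp: float,
               rng: np.random.Generator) -> np.ndarray:
    """64-channel 1/f-plus-oscillations block, microvolts, float32.

    ``band_amps``: (64, n_bands) oscillation amplitudes in montage order.
    The 1/f background is synthesised in the frequency domain between
    0.5 Hz and 120 Hz; content above 120 Hz is physiologically
    negligible and is removed by the 1-45 Hz analysis band anyway.
    """
    duration = n / EEG_RATE
    nf = n // 2 + 1
    kmax = min(int(_EEG_F_MAX * duration), nf - 1)
    f = np.arange(1, kmax + 1) / duration
    pink = np.where(f >= 0.5, _EEG_PINK_LEVEL / np.maximum(f, 0.5), 0.0)
    sigma = (n * np.sqrt(pink / (4.0 * duration))).astype(np.float32)
    bands = list(BAND_CENTER)
    out_spec = np.zeros((64, nf), dtype=np.complex64)
    z = (rng.standard_normal((64, kmax), dtype=np.float32)
         + 1j * rng.standard_normal((64, kmax), dtype=np.float32))
    out_spec[:, 1:kmax + 1] = global_amp * sigma * z
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(64, len(bands)))
    for bi, band in enumerate(bands):
        k = int(round(BAND_CENTER[band] * duration))
        if 0 < k < nf:
            out_spec[:, k] += (
                (n / 2.0) * band_amps[:, bi] * np.exp(1j * phases[:, bi])
            ).astype(np.complex64)
    return sfft.irfft(out_spec, n=n, axis=1).T


def _hr_block(n: int, mean_bpm: float, rng: np.random.Generator) -> np.ndarray:
    return (mean_bpm + 1.5 * _ou(n, HR_RATE, 30.0, rng))[:, None]


# ---------------------------------------------------------------------------
# public single-modality generators (group-level parameters, explicit seed)

def generate_cop(params: SynthParams, group: str, duration_s: float,
                 seed: int) -> TimeSeries:
    """Continuous 2-channel sway trajectory at 90 Hz for one group."""
    _check_duration(duration_s)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * COP_RATE))
    vals = _cop_block(n, params.cop_sway_scale[group],
                      params.cop_ml_complexity[group], rng)
    return TimeSeries(vals, COP_RATE, list(COP_AXES), "mm")


def generate_emg(params: SynthParams, group: str, duration_s: float,
                 seed: int) -> TimeSeries:
    """Continuous 6-channel burst-modulated EMG at 1600 Hz."""
    _check_duration(duration_s)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * EMG_RATE))
    gains = np.array([params.muscle_gain(group, m) for m in EMG_MUSCLES])
    return TimeSeries(_emg_block(n, gains, rng), EMG_RATE,
                      list(EMG_MUSCLES), "mV")


def generate_eeg(params: SynthParams, group: str, duration_s: float,
                 seed: int) -> TimeSeries:
    """Continuous 64-channel EEG at 4096 Hz with per-band group offsets."""
    _check_duration(duration_s)
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * EEG_RATE))
    amps = _band_amplitudes(params, group, eeg_amp=1.0,
                            band_jitter={b: 1.0 for b in BAND_CENTER})
    return TimeSeries(_eeg_block(n, amps, 1.0, rng), EEG_RATE,
                      list(EEG_MONTAGE_64), "uV")


def generate_hr(params: SynthParams, group: str, duration_s: float,
                seed: int) -> TimeSeries:
    """Slowly wandering heart rate at 1 Hz around the group mean."""
    _check_duration(duration_s)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * HR_RATE))
    return TimeSeries(_hr_block(n, params.hr_mean[group], rng), HR_RATE,
                      ["HR"], "bpm")


def _check_duration(duration_s: float) -> None:
    if duration_s < 10.0:
        raise ValidationError("duration must be at least 10 s")


def _band_amplitudes(params: SynthParams, group: str, eeg_amp: float,
                     band_jitter: dict) -> np.ndarray:
    bands = list(BAND_CENTER)
    amps = np.empty((64, len(bands)))
    for bi, band in enumerate(bands):
        base = _BAND_AMP[band] * eeg_amp * band_jitter[band]
        for ei, el in enumerate(EEG_MONTAGE_64):
            amps[ei, bi] = base * np.sqrt(params.band_factor(group, el, band))
    return amps


# ---------------------------------------------------------------------------
# session assembly (per-phase blocks, subject-level traits)

def _phase_samples(rate: float, start_s: float, end_s: float) -> int:
    """Sample count of a phase block, matching the segmentation
    convention ``[floor(rate*start), floor(rate*end))`` so concatenated
    blocks line up exactly with phase slices."""
    return int(np.floor(rate * end_s)) - int(np.floor(rate * start_s))


def _phase_block(params: SynthParams, group: str, index: int,
                 traits: _SubjectTraits, modality: str, phase_index: int,
                 label: PhaseLabel, start_s: float, end_s: float) -> np.ndarray:
    rng = _rng(params.seed, group, index, modality, phase_index)
    if modality == "cop":
        n = _phase_samples(COP_RATE, start_s, end_s)
        return _cop_block(n, traits.sway_scale, traits.complexity, rng)
    if modality == "emg":
        n = _phase_samples(EMG_RATE, start_s, end_s)
        return _emg_block(n, traits.emg_gains, rng)
    if modality == "eeg":
        n = _phase_samples(EEG_RATE, start_s, end_s)
        amps = _band_amplitudes(params, group, traits.eeg_amp, traits.band_jitter)
        return _eeg_block(n, amps, traits.eeg_amp, rng)
    if modality == "hr":
        n = max(_phase_samples(HR_RATE, start_s, end_s), 1)
        mean = traits.hr_base
        if label == PhaseLabel.POST:
            mean = mean + params.hr_trend_post[group]
        return _hr_block(n, mean, rng)
    raise KeyError(modality)


_MODALITY_SPEC = {
    "cop": (COP_RATE, COP_AXES, "mm"),
    "emg": (EMG_RATE, EMG_MUSCLES, "mV"),
    "eeg": (EEG_RATE, EEG_MONTAGE_64, "uV"),
    "hr": (HR_RATE, ("HR",), "bpm"),
}


def generate_phase_segments(
    params: SynthParams, group: str, subject_index: int,
    phases, modalities=Session.MODALITIES,
    schedule: PhaseSchedule = DEFAULT_SCHEDULE,
) -> dict:
    """Generate only the requested phase segments of one subject.

    Returns ``{modality: {PhaseLabel: TimeSeries}}``, bit-identical to
    slicing :func:`generate_cohort_session` output at the schedule
    boundaries (phases are independent seeded blocks).
    """
    params.validate()
    traits = _subject_traits(params, group, subject_index)
    phase_set = {PhaseLabel(p) for p in phases}
    out: dict = {m: {} for m in modalities}
    for pi, (label, start, end) in enumerate(schedule.entries):
        if label not in phase_set:
            continue
        for m in modalities:
            rate, labels, units = _MODALITY_SPEC[m]
            vals = _phase_block(params, group, subject_index, traits, m, pi,
                                label, start, end)
            out[m][label] = TimeSeries(vals, rate, list(labels), units)
    return out


def generate_cohort_session(
    params: SynthParams, group: str, subject_index: int,
    schedule: PhaseSchedule = DEFAULT_SCHEDULE,
) -> Session:
    """Full session covering the whole schedule for one subject."""
    params.validate()
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}")
    traits = _subject_traits(params, group, subject_index)
    parts = {}
    for m in Session.MODALITIES:
        rate, labels, units = _MODALITY_SPEC[m]
        blocks = [
            _phase_block(params, group, subject_index, traits, m, pi, label,
                         start, end)
            for pi, (label, start, end) in enumerate(schedule.entries)
        ]
        parts[m] = TimeSeries(np.concatenate(blocks, axis=0), rate,
                              list(labels), units)
    session = Session(
        subject_id=f"{group}_{subject_index:02d}",
        group=group,
        cop=parts["cop"], emg=parts["emg"], eeg=parts["eeg"], hr=parts["hr"],
        metadata={"synthetic": True, "seed": params.seed,
                  "subject_index": subject_index},
    )
    session.validate()
    return session


def assemble_collection(
    params: SynthParams, schedule: PhaseSchedule = DEFAULT_SCHEDULE,
) -> CohortCollection:
    """All ``n_healthy + n_pd`` sessions, deterministically seeded."""
    params.validate()
    sessions = [
        generate_cohort_session(params, group, i, schedule)
        for group, count in (("healthy", params.n_healthy), ("pd", params.n_pd))
        for i in range(count)
    ]
    return CohortCollection(sessions, params)


def iter_subjects(params: SynthParams):
    """Yield ``(group, subject_index, subject_id)`` in collection order."""
    for group, count in (("healthy", params.n_healthy), ("pd", params.n_pd)):
        for i in range(count):
            yield group, i, f"{group}_{i:02d}"
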