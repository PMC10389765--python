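"""Core in-memory containers: uniformly sampled signals, recording
sessions, and the experimental phase schedule.

A *session* is one subject's synchronised multi-modal recording during the
platform protocol: centre-of-pressure sway (90 Hz), six-channel lower-limb
EMG (1600 Hz), 64-channel EEG (4096 Hz) and beat-averaged heart rate
(1 Hz), plus a group label (healthy control or early-stage Parkinson's
disease).

The protocol is a fixed 320 s sequence of six phases: a 120 s stationary
baseline, a 40 s quiet-standing PRE phase with the visual sea scene, three
40 s platform-motion phases of increasing amplitude (25/50/75 %), and a
final 40 s quiet-standing POST phase.  Time is measured in seconds from
recording start and phase windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .montage import COP_AXES, EEG_MONTAGE_64, EMG_MUSCLES

__all__ = [
    "TimeSeries",
    "Session",
    "PhaseLabel",
    "PhaseSchedule",
    "DEFAULT_SCHEDULE",
    "GROUPS",
    "ValidationError",
]

GROUPS = ("healthy", "pd")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class TimeSeries:
    """A uniformly sampled multi-channel signal.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_channels)
        Signal samples; must be finite.
    rate : float
        Sampling rate in Hz, strictly positive.
    channel_labels : list of str
        One label per column of ``values``.
    units : str
        Physical units of the samples (e.g. ``"mm"``, ``"uV"``).
    meta : dict
        Free-form annotations (e.g. bad-channel flags added during
        preprocessing).
    """

    values: np.ndarray
    rate: float
    channel_labels: list[str]
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.channel_labels = list(self.channel_labels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def validate(self) -> None:
        if self.rate <= 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.rate}")
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (samples x channels)")
        if self.n_channels != len(self.channel_labels):
            raise ValidationError(
                f"{self.n_channels} channels but "
                f"{len(self.channel_labels)} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite samples")

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D sample vector of the named channel."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None
        return self.values[:, idx]

    def slice_seconds(self, start_s: float, end_s: float) -> "TimeSeries":
        """Half-open time slice ``[start_s, end_s)`` by sample index
        ``[floor(rate*start), floor(rate*end))``."""
        i0 = int(np.floor(self.rate * start_s))
        i1 = int(np.floor(self.rate * end_s))
        return replace(self, values=self.values[i0:i1], meta=dict(self.meta))


class PhaseLabel(str, enum.Enum):
    """The six named windows of the experimental paradigm."""

    BASELINE = "Baseline"
    PRE = "PRE"
    P25 = "25%"
    P50 = "50%"
    P75 = "75%"
    POST = "POST"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered, contiguous, non-overlapping phase windows in seconds."""

    entries: tuple[tuple[PhaseLabel, float, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("schedule has no entries")
        prev_end = None
        for label, start, end in self.entries:
            if end <= start:
                raise ValidationError(
                    f"phase {label} has non-positive span [{start}, {end})"
                )
            if prev_end is not None and not np.isclose(start, prev_end):
                raise ValidationError(
                    f"schedule not contiguous at phase {label}: "
                    f"starts at {start}, previous ended at {prev_end}"
                )
            prev_end = end

    @property
    def labels(self) -> tuple[PhaseLabel, ...]:
        return tuple(e[0] for e in self.entries)

    @property
    def span_s(self) -> float:
        return self.entries[-1][2]

    def window(self, label: PhaseLabel | str) -> tuple[float, float]:
        label = PhaseLabel(label)
        for lab, start, end in self.entries:
            if lab == label:
                return start, end
        raise KeyError(f"phase {label!r} not in schedule")

    def scaled(self, factor: float) -> "PhaseSchedule":
        """A schedule with every window shrunk/stretched by ``factor``.

        Used for miniature test sessions; the default full-length schedule
        is the experimental condition.
        """
        return PhaseSchedule(
            tuple((lab, s * factor, e * factor) for lab, s, e in self.entries)
        )


#: The experimental paradigm: 120 s baseline, 40 s PRE, three 40 s
#: platform-motion phases, 40 s POST.
DEFAULT_SCHEDULE = PhaseSchedule(
    (
        (PhaseLabel.BASELINE, 0.0, 120.0),
        (PhaseLabel.PRE, 120.0, 160.0),
        (PhaseLabel.P25, 160.0, 200.0),
        (PhaseLabel.P50, 200.0, 240.0),
        (PhaseLabel.P75, 240.0, 280.0),
        (PhaseLabel.POST, 280.0, 320.0),
    )
)


@dataclass
class Session:
    """One subject's synchronised multi-modal recording plus group label."""

    subject_id: str
    group: str
    cop: TimeSeries
    emg: TimeSeries
    eeg: TimeSeries
    hr: TimeSeries
    metadata: dict = field(default_factory=dict)

    MODALITIES = ("cop", "emg", "eeg", "hr")

    def modality(self, name: str) -> TimeSeries:
        if name not in self.MODALITIES:
            raise KeyError(f"unknown modality {name!r}")
        return getattr(self, name)

    def validate(self, schedule: PhaseSchedule | None = None) -> None:
        """Check structural invariants; with ``schedule``, additionally
        require every modality to cover the full scheduled span."""
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        for name in self.MODALITIES:
            ts = self.modality(name)
            try:
                ts.validate()
            except ValidationError as exc:
                raise ValidationError(f"{name}: {exc}") from exc
        if list(self.cop.channel_labels) != list(COP_AXES):
            raise ValidationError(
                f"cop channels must be {COP_AXES}, got {self.cop.channel_labels}"
            )
        if list(self.emg.channel_labels) != list(EMG_MUSCLES):
            raise ValidationError(
                f"emg channels must be {EMG_MUSCLES}, got {self.emg.channel_labels}"
            )
        if list(self.eeg.channel_labels) != list(EEG_MONTAGE_64):
            raise ValidationError("eeg channels must match the 64-name montage")
        if schedule is not None:
            for name in self.MODALITIES:
                ts = self.modality(name)
                if ts.duration_s < schedule.span_s - 0.5 / ts.rate:
                    raise ValidationError(
                        f"{name} covers {ts.duration_s:.2f} s < scheduled "
                        f"{schedule.span_s:.2f} s"
                    )
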