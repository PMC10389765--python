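"""Stabilogram (centre-of-pressure) feature battery.

The sway trajectory is a 2-channel series (ML, AP) in millimetres; all
features are computed on the trajectory centred by subtracting its own
per-phase mean, which defines the origin for distances and half-planes.

The battery covers: path-length and distance statistics (TOTEX, RD,
MDIST, RDIST, MVELO, SD), the 95 % confidence ellipse of the sway cloud,
sample entropy and multiscale complexity indices per axis plus a
bivariate (multivariate-embedding) complexity index, displacement
magnitude/direction histogram entropies, and the extreme excursion in
each of the four half-planes.

Sample entropy: SampEn(m, r) = -ln(A/B) where B counts template pairs of
length m within Chebyshev distance r (self-matches excluded) and A the
same for length m+1.  Defaults m = 2, r = 0.15 * SD of the scale-1
series, tolerance held fixed across scales (the classic multiscale
convention); the complexity index is the sum of SampEn over scales
1..tau_max (default 10).  Undefined entropies (no matches) are returned
as NaN and excluded from group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .session import PhaseLabel, TimeSeries, ValidationError

__all__ = [
    "EllipseParams",
    "MSEProfile",
    "CoPFeatureSet",
    "COP_FEATURE_NAMES",
    "cop_path_features",
    "confidence_ellipse",
    "sample_entropy",
    "coarse_grain",
    "multiscale_ci",
    "multivariate_sample_entropy",
    "multivariate_ci",
    "sway_direction_entropies",
    "directional_extremes",
    "extract_cop_features",
]

COP_FEATURE_NAMES = (
    "TOTEX", "TOTEX-ML", "TOTEX-AP", "RD", "MDIST-ML", "MDIST-AP",
    "MVELO", "MVELO-ML", "MVELO-AP", "RDIST", "RDIST-ML", "RDIST-AP",
    "ML-SampEn", "AP-SampEn", "ML-CI", "AP-CI",
    "Ellipse-area", "Ellipse-angle", "Ellipse-main-axis", "Ellipse-minor-axis",
    "SD-AP", "SD-ML", "SD-magnitude", "SD-direction",
    "Magnitude-entropy", "Direction-entropy", "Multivariate-CI",
    "Antero-magnitude", "Antero-angle", "Postero-magnitude", "Postero-angle",
    "Left-magnitude", "Left-angle", "Right-magnitude", "Right-angle",
)

DEFAULT_M = 2
DEFAULT_R_FACTOR = 0.15
DEFAULT_TAU_MAX = 10
DEFAULT_ANGLE_BINS = 36

_R_FLOOR = 1e-12  # tolerance floor so constant series compare as equal


# ---------------------------------------------------------------------------
# sample entropy kernels (numba-accelerated with a numpy fallback)

def _py_sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    n = x.shape[0]
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
            if d <= r:
                b += 1
                t = abs(x[i + m] - x[j + m])
                if t > d:
                    d = t
                if d <= r:
                    a += 1
    return a, b


def _py_mv_counts(x: np.ndarray, y: np.ndarray, m: int, r: float) -> tuple[int, int]:
    n = x.shape[0]
    a2 = 0  # extension matches, both channels pooled
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
                t = abs(y[i + k] - y[j + k])
                if t > d:
                    d = t
            if d <= r:
                b += 1
                tx = abs(x[i + m] - x[j + m])
                if max(d, tx) <= r:
                    a2 += 1
                ty = abs(y[i + m] - y[j + m])
                if max(d, ty) <= r:
                    a2 += 1
    return a2, b


try:  # pragma: no cover - exercised whenever numba is present
    from numba import njit

    _sampen_counts = njit(cache=False)(_py_sampen_counts)
    _mv_counts = njit(cache=False)(_py_mv_counts)
except ImportError:  # pragma: no cover
    _sampen_counts = _py_sampen_counts
    _mv_counts = _py_mv_counts


def sample_entropy(series, m: int = DEFAULT_M,
                   r_factor: float = DEFAULT_R_FACTOR,
                   r: float | None = None) -> float:
    """SampEn(m, r) of a 1-D series; NaN when no template pairs match.

    ``r`` defaults to ``r_factor * SD(series)`` (population SD).  A
    constant series gets a tiny positive tolerance so that all templates
    match and the entropy is exactly 0.
    """
    x = np.ascontiguousarray(np.asarray(series, dtype=float).ravel())
    if x.size < 10 * m:
        raise ValidationError(
            f"sample entropy needs at least {10 * m} samples, got {x.size}"
        )
    if r is None:
        r = r_factor * float(np.std(x))
    r = max(float(r), _R_FLOOR)
    a, b = _sampen_counts(x, m, r)
    if a == 0 or b == 0:
        return float("nan")
    return float(-math.log(a / b))


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping window means of length ``tau``."""
    x = np.asarray(series, dtype=float).ravel()
    n = (x.size // tau) * tau
    return x[:n].reshape(-1, tau).mean(axis=1)


@dataclass
class MSEProfile:
    """Per-scale sample entropy curve and its complexity index (sum)."""

    scales: tuple[int, ...]
    sampen_per_scale: tuple[float, ...]
    complexity_index: float
    undefined_scales: tuple[int, ...] = ()


def multiscale_ci(series, tau_max: int = DEFAULT_TAU_MAX, m: int = DEFAULT_M,
                  r_factor: float = DEFAULT_R_FACTOR) -> MSEProfile:
    """Multiscale entropy with the tolerance anchored at scale 1.

    The complexity index is the sum of defined per-scale entropies;
    undefined scales (NaN) are flagged and excluded from the sum.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 10 * m * tau_max:
        raise ValidationError(
            f"multiscale entropy to scale {tau_max} needs at least "
            f"{10 * m * tau_max} samples, got {x.size}"
        )
    r = max(r_factor * float(np.std(x)), _R_FLOOR)
    values = []
    undefined = []
    for tau in range(1, tau_max + 1):
        se = sample_entropy(coarse_grain(x, tau), m=m, r=r)
        values.append(se)
        if math.isnan(se):
            undefined.append(tau)
    ci = float(np.nansum(values)) if len(undefined) < tau_max else float("nan")
    return MSEProfile(tuple(range(1, tau_max + 1)), tuple(values), ci,
                      tuple(undefined))


def multivariate_sample_entropy(ml, ap, m: int = DEFAULT_M,
                                r: float | None = None,
                                r_factor: float = DEFAULT_R_FACTOR) -> float:
    """Bivariate sample entropy via composite delay vectors.

    Both channels are embedded with ``m`` lags into one composite vector;
    the conditional (m+1) stage averages matches over the two possible
    single-channel extensions.  The tolerance defaults to
    ``r_factor * pooled SD`` (root mean of the channel variances).  By
    construction the statistic is symmetric under channel swap.
    """
    x = np.ascontiguousarray(np.asarray(ml, dtype=float).ravel())
    y = np.ascontiguousarray(np.asarray(ap, dtype=float).ravel())
    if x.size != y.size:
        raise ValidationError("channels must have equal length")
    if x.size < 10 * m:
        raise ValidationError(
            f"multivariate sample entropy needs at least {10 * m} samples"
        )
    if r is None:
        r = r_factor * float(np.sqrt((np.var(x) + np.var(y)) / 2.0))
    r = max(float(r), _R_FLOOR)
    a2, b = _mv_counts(x, y, m, r)
    if a2 == 0 or b == 0:
        return float("nan")
    return float(-math.log((a2 / 2.0) / b))


def multivariate_ci(traj, tau_max: int = DEFAULT_TAU_MAX, m: int = DEFAULT_M,
                    r_factor: float = DEFAULT_R_FACTOR) -> float:
    """Sum over scales of the bivariate sample entropy of (ML, AP)."""
    arr = _as_traj(traj)
    ml, ap = arr[:, 0], arr[:, 1]
    if ml.size < 10 * m * tau_max:
        raise ValidationError(
            f"multivariate CI to scale {tau_max} needs at least "
            f"{10 * m * tau_max} samples, got {ml.size}"
        )
    r = max(r_factor * float(np.sqrt((np.var(ml) + np.var(ap)) / 2.0)), _R_FLOOR)
    total = 0.0
    any_defined = False
    for tau in range(1, tau_max + 1):
        se = multivariate_sample_entropy(coarse_grain(ml, tau),
                                         coarse_grain(ap, tau), m=m, r=r)
        if not math.isnan(se):
            total += se
            any_defined = True
    return total if any_defined else float("nan")


# ---------------------------------------------------------------------------
# geometry

@dataclass
class EllipseParams:
    """95 % confidence ellipse of the sway cloud.

    ``angle_deg`` is measured counter-clockwise from the +ML axis to the
    major axis, mapped to (-90, 90].
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle_deg: float
    area: float
    level: float
    degenerate: bool = False

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        p = np.asarray(points, dtype=float) - np.asarray(self.center)
        th = math.radians(self.angle_deg)
        rot = np.array([[math.cos(th), math.sin(th)],
                        [-math.sin(th), math.cos(th)]])
        q = p @ rot.T
        if self.semi_minor == 0:
            return np.zeros(len(p), dtype=bool)
        return ((q[:, 0] / self.semi_major) ** 2
                + (q[:, 1] / self.semi_minor) ** 2) <= 1.0


def confidence_ellipse(traj, level: float = 0.95) -> EllipseParams:
    """Covariance-based confidence ellipse via eigen-decomposition.

    Semi-axes are ``sqrt(eigenvalue * q)`` with ``q`` the chi-square
    quantile with 2 degrees of freedom at ``level`` — the exact coverage
    region for bivariate normal sway.  Collinear data give a degenerate
    ellipse with zero minor axis and area.
    """
    arr = _as_traj(traj)
    if arr.shape[0] < 3:
        raise ValidationError("confidence ellipse needs at least 3 samples")
    center = arr.mean(axis=0)
    cov = np.cov(arr, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.maximum(evals, 0.0)
    q = float(sstats.chi2.ppf(level, df=2))
    semi_minor = float(np.sqrt(evals[0] * q))
    semi_major = float(np.sqrt(evals[1] * q))
    lead = evecs[:, 1]
    angle = math.degrees(math.atan2(lead[1], lead[0]))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    degenerate = evals[0] <= 1e-12 * max(evals[1], 1.0)
    if degenerate:
        semi_minor = 0.0
    return EllipseParams(
        center=(float(center[0]), float(center[1])),
        semi_major=semi_major, semi_minor=semi_minor, angle_deg=angle,
        area=float(math.pi * semi_major * semi_minor), level=level,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# path statistics

def _as_traj(traj) -> np.ndarray:
    if isinstance(traj, TimeSeries):
        arr = np.asarray(traj.values, dtype=float)
    else:
        arr = np.asarray(traj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("trajectory must be 2-channel (ML, AP)")
    return arr


def cop_path_features(traj, rate: float) -> dict:
    """Path-length, distance and dispersion statistics of the centred
    trajectory.  Velocities divide the excursion by the traversal time
    ``(n - 1) / rate``; direction statistics are computed on consecutive
    displacement increments, not positions."""
    arr = _as_traj(traj)
    n = arr.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples")
    arr = arr - arr.mean(axis=0)
    ml, ap = arr[:, 0], arr[:, 1]
    d = np.diff(arr, axis=0)
    step = np.hypot(d[:, 0], d[:, 1])
    duration = (n - 1) / rate
    radial = np.hypot(ml, ap)
    totex = float(np.sum(step))
    totex_ml = float(np.sum(np.abs(d[:, 0])))
    totex_ap = float(np.sum(np.abs(d[:, 1])))
    angles = np.arctan2(d[:, 1], d[:, 0])
    return {
        "TOTEX": totex,
        "TOTEX-ML": totex_ml,
        "TOTEX-AP": totex_ap,
        "RD": float(np.mean(radial)),
        "MDIST-ML": float(np.mean(np.abs(ml))),
        "MDIST-AP": float(np.mean(np.abs(ap))),
        "MVELO": totex / duration,
        "MVELO-ML": totex_ml / duration,
        "MVELO-AP": totex_ap / duration,
        "RDIST": float(np.sqrt(np.mean(ml ** 2 + ap ** 2))),
        "RDIST-ML": float(np.sqrt(np.mean(ml ** 2))),
        "RDIST-AP": float(np.sqrt(np.mean(ap ** 2))),
        "SD-ML": float(np.std(ml, ddof=1)),
        "SD-AP": float(np.std(ap, ddof=1)),
        "SD-magnitude": float(np.std(step, ddof=1)) if len(step) > 1 else 0.0,
        "SD-direction": float(np.std(angles, ddof=1)) if len(angles) > 1 else 0.0,
    }


def sway_direction_entropies(traj, n_bins: int = DEFAULT_ANGLE_BINS) -> tuple[float, float]:
    """Shannon entropies (nats) of displacement magnitude and direction.

    Magnitudes are histogrammed into ``n_bins`` equal-width bins on
    [0, max]; directions into ``n_bins`` equal bins on (-pi, pi].
    """
    arr = _as_traj(traj)
    if arr.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    d = np.diff(arr, axis=0)
    mags = np.hypot(d[:, 0], d[:, 1])
    if np.max(mags) == 0:
        return 0.0, 0.0
    mag_counts, _ = np.histogram(mags, bins=n_bins, range=(0.0, float(np.max(mags))))
    moving = mags > 0
    angles = np.arctan2(d[moving, 1], d[moving, 0])
    ang_counts, _ = np.histogram(angles, bins=n_bins, range=(-np.pi, np.pi))
    return _shannon(mag_counts), _shannon(ang_counts)


def _shannon(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-np.sum(p * np.log(p)))


def directional_extremes(traj) -> dict:
    """Extreme radial excursion per half-plane of the centred trajectory.

    Half-planes: antero AP > 0, postero AP < 0, left ML < 0, right
    ML > 0.  The trajectory is taken as already centred (the origin is
    the caller's reference point).  Returns
    ``{name: (magnitude_mm, angle_deg)}``; an empty half-plane yields
    magnitude 0 and NaN angle.
    """
    arr = _as_traj(traj)
    ml, ap = arr[:, 0], arr[:, 1]
    radial = np.hypot(ml, ap)
    out = {}
    for name, mask in (
        ("antero", ap > 0), ("postero", ap < 0),
        ("left", ml < 0), ("right", ml > 0),
    ):
        if not np.any(mask):
            out[name] = (0.0, float("nan"))
            continue
        idx = np.flatnonzero(mask)[np.argmax(radial[mask])]
        out[name] = (
            float(radial[idx]),
            float(math.degrees(math.atan2(ap[idx], ml[idx]))),
        )
    return out


# ---------------------------------------------------------------------------
# full battery

@dataclass
class CoPFeatureSet:
    """All named stabilogram features of one phase."""

    phase: PhaseLabel
    values: dict

    def __post_init__(self) -> None:
        missing = set(COP_FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(COP_FEATURE_NAMES)
        if missing or extra:
            raise ValidationError(
                f"CoP feature set incomplete; missing={sorted(missing)} "
                f"extra={sorted(extra)}"
            )


def extract_cop_features(traj, rate: float, phase: PhaseLabel,
                         tau_max: int = DEFAULT_TAU_MAX,
                         m: int = DEFAULT_M,
                         r_factor: float = DEFAULT_R_FACTOR,
                         n_bins: int = DEFAULT_ANGLE_BINS) -> CoPFeatureSet:
    """Compute the complete stabilogram battery on one phase segment."""
    arr = _as_traj(traj)
    arr = arr - arr.mean(axis=0)
    ml, ap = arr[:, 0], arr[:, 1]
    values = cop_path_features(arr, rate)
    ellipse = confidence_ellipse(arr)
    values["Ellipse-area"] = ellipse.area
    values["Ellipse-angle"] = ellipse.angle_deg
    values["Ellipse-main-axis"] = 2.0 * ellipse.semi_major
    values["Ellipse-minor-axis"] = 2.0 * ellipse.semi_minor
    mse_ml = multiscale_ci(ml, tau_max=tau_max, m=m, r_factor=r_factor)
    mse_ap = multiscale_ci(ap, tau_max=tau_max, m=m, r_factor=r_factor)
    values["ML-SampEn"] = mse_ml.sampen_per_scale[0]
    values["AP-SampEn"] = mse_ap.sampen_per_scale[0]
    values["ML-CI"] = mse_ml.complexity_index
    values["AP-CI"] = mse_ap.complexity_index
    values["Multivariate-CI"] = multivariate_ci(arr, tau_max=tau_max, m=m,
                                                r_factor=r_factor)
    mag_e, dir_e = sway_direction_entropies(arr, n_bins=n_bins)
    values["Magnitude-entropy"] = mag_e
    values["Direction-entropy"] = dir_e
    for name, (mag, ang) in directional_extremes(arr).items():
        values[f"{name.capitalize()}-magnitude"] = mag
        values[f"{name.capitalize()}-angle"] = ang
    return CoPFeatureSet(PhaseLabel(phase), values)
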