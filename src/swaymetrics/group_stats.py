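"""Two-group univariate comparison machinery shared by the EMG, CoP, HR
and EEG branches.

For every feature the procedure is: test each group for normality with
Shapiro-Wilk; if both groups look Gaussian (p > 0.05) compare them with
Welch's unequal-variance t-test, otherwise with the two-sided
Mann-Whitney U-test.  Cliff's delta is always computed as the effect
size, by full pairwise enumeration:

    delta = (#{a > b} - #{a < b}) / (n_A * n_B)

so that delta = +1 when every observation of the first group exceeds every
observation of the second, and -1 in the reverse case.  |delta| > 0.42 is
labelled a *large* effect (Vargha-Delaney rule); below that the standard
0.147 / 0.33 cut-offs give negligible / small / medium.

EMG, CoP and HR families are compared at a raw significance level of
0.05 with no multiplicity correction by default; the EEG topographic
branch applies Benjamini-Hochberg FDR across the 64 electrodes of one
(band, phase) family (see :mod:`swaymetrics.eeg_features`).  An optional
FDR switch exists for the other families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonRecord",
    "normality_gate",
    "welch_t",
    "mann_whitney",
    "cliffs_delta",
    "delta_magnitude",
    "bh_fdr",
    "compare_feature_tables",
    "hr_summary",
]

#: |delta| above which an effect is labelled "large".
LARGE_DELTA = 0.42


@dataclass
class ComparisonRecord:
    """Outcome of one two-group feature comparison."""

    feature: str
    phase: str
    test: str  # "welch_t" | "mann_whitney"
    p_value: float
    cliff_delta: float
    magnitude: str
    significant: bool
    p_adjusted: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)


def _clean(sample) -> np.ndarray:
    a = np.asarray(sample, dtype=float).ravel()
    return a[np.isfinite(a)]


def normality_gate(sample_a, sample_b, alpha: float = 0.05,
                   rule: str = "both") -> tuple[str, tuple[str, ...]]:
    """Choose the comparison test for two samples.

    Returns ``(test_name, flags)``.  With the default ``rule="both"``
    (the strictest reading) Welch's t is chosen iff the Shapiro-Wilk
    p-value exceeds ``alpha`` in *both* groups; ``rule="either"``
    requires only one group to look Gaussian.  Groups smaller than 3
    cannot be tested for normality; the nonparametric branch is forced
    and flagged.
    """
    if rule not in ("both", "either"):
        raise ValueError(f"unknown gate rule {rule!r}")
    a, b = _clean(sample_a), _clean(sample_b)
    if len(a) < 3 or len(b) < 3:
        return "mann_whitney", ("small_sample",)
    ps = []
    for s in (a, b):
        if np.ptp(s) == 0:  # constant sample: trivially non-Gaussian
            ps.append(0.0)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps.append(stats.shapiro(s).pvalue)
    passed = [p > alpha for p in ps]
    if all(passed) if rule == "both" else any(passed):
        return "welch_t", ()
    return "mann_whitney", ()


def welch_t(sample_a, sample_b) -> float:
    """Two-sided p-value of Welch's unequal-variance t-test."""
    a, b = _clean(sample_a), _clean(sample_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t needs at least 2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def mann_whitney(sample_a, sample_b) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration of the U distribution when both groups have at
    most 8 observations and there are no ties; otherwise the normal
    approximation with mid-ranks and tie-corrected variance.
    """
    a, b = _clean(sample_a), _clean(sample_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("mann_whitney needs at least 2 observations per group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= 8 and len(b) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def cliffs_delta(sample_a, sample_b) -> tuple[float, str]:
    """Cliff's delta by full pairwise enumeration, with magnitude label.

    delta = (#{a > b} - #{a < b}) / (n_A * n_B); ties contribute zero.
    """
    a, b = _clean(sample_a), _clean(sample_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cliffs_delta requires non-empty samples")
    diff = a[:, None] - b[None, :]
    delta = float((np.sum(diff > 0) - np.sum(diff < 0)) / (len(a) * len(b)))
    return delta, delta_magnitude(delta)


def delta_magnitude(delta: float) -> str:
    """Magnitude label: "large" iff |delta| > 0.42; otherwise the
    conventional negligible/small/medium cut-offs."""
    d = abs(delta)
    if d > LARGE_DELTA:
        return "large"
    if d < 0.147:
        return "negligible"
    if d < 0.33:
        return "small"
    return "medium"


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_feature_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    phase: str,
    alpha: float = 0.05,
    apply_fdr: bool = False,
    gate_rule: str = "both",
) -> list[ComparisonRecord]:
    """Gate-then-test every shared feature column of two cohort tables.

    ``table_a`` and ``table_b`` hold one row per subject and one column
    per feature, already restricted to a single phase.  Non-finite
    entries (features flagged undefined for a subject) are dropped per
    group before testing.  Significance is ``p < alpha`` on the raw
    p-value unless ``apply_fdr`` is set, in which case BH-adjusted
    p-values are used across the table's feature family.
    """
    cols_a, cols_b = set(table_a.columns), set(table_b.columns)
    if cols_a != cols_b:
        raise ValueError(
            "feature columns differ between groups: "
            f"{sorted(cols_a.symmetric_difference(cols_b))}"
        )
    records: list[ComparisonRecord] = []
    for feature in table_a.columns:
        a, b = _clean(table_a[feature]), _clean(table_b[feature])
        flags: tuple[str, ...] = ()
        if len(a) < 2 or len(b) < 2:
            records.append(
                ComparisonRecord(feature, str(phase), "mann_whitney", 1.0,
                                 0.0, "negligible", False,
                                 flags=("insufficient_data",))
            )
            continue
        test, gate_flags = normality_gate(a, b, alpha=alpha, rule=gate_rule)
        flags += gate_flags
        if test == "welch_t":
            p = welch_t(a, b)
        else:
            p = mann_whitney(a, b)
        delta, mag = cliffs_delta(a, b)
        records.append(
            ComparisonRecord(feature, str(phase), test, p, delta, mag,
                             p < alpha, flags=flags)
        )
    if apply_fdr:
        adj = bh_fdr([r.p_value for r in records])
        for r, q in zip(records, adj):
            r.p_adjusted = float(q)
            r.significant = q <= alpha
    return records


def hr_summary(hr_values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (ddof=1) of a heart
    rate segment in bpm.  A single sample has SD 0."""
    v = _clean(hr_values)
    if v.size == 0:
        raise ValueError("empty heart-rate segment")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)), sd
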