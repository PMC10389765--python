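"""End-to-end orchestration: simulate/load -> segment -> condition ->
extract -> compare -> report.

The default analysis mirrors the experimental focus: features are
extracted and compared for the two quiet-standing phases (PRE and POST)
only; the baseline and platform-motion phases are segmented and
extractable but excluded from default comparisons.  Comparisons always
put the healthy cohort first, so positive Cliff's delta means
"healthy larger".

Outputs (when an output directory is given):

* ``cop_features.csv``   one row per (subject, phase), stabilogram battery
* ``emg_features.csv``   one row per (subject, muscle, phase), 43 features
* ``eeg_band_power.csv`` long table (subject, phase, electrode, band, power)
* ``hr_summary.csv``     per-subject phase means; ``hr_cohort_summary.csv``
  the cohort mean +/- SD table
* ``*_comparison.csv``   per-family comparison tables (EEG with BH-FDR)
* ``run_manifest.json``  config hash, seed, package/library versions

Given the same configuration and seed the pipeline is fully
deterministic and its CSV outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .cop_features import COP_FEATURE_NAMES, extract_cop_features
from .eeg_features import BANDS, BandPowerMap, band_power_map, topographic_comparison
from .emg_features import ALL_FEATURES as EMG_FEATURES, extract_emg_features
from .group_stats import ComparisonRecord, compare_feature_tables, hr_summary
from .montage import EMG_MUSCLES
from .preprocessing import filter_emg, preprocess_eeg, segment_phases, smooth_cop
from .session import (
    DEFAULT_SCHEDULE,
    PhaseLabel,
    PhaseSchedule,
    Session,
    ValidationError,
)
from .session_io import read_session, write_comparison_table
from .synthetic import SynthParams, generate_phase_segments, iter_subjects

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """What to analyse and how.

    Exactly one of ``synth`` (generate cohorts in memory) or
    ``input_dir`` (a directory of session subdirectories) must be set.
    """

    synth: SynthParams | None = None
    input_dir: str | None = None
    phases: tuple = (PhaseLabel.PRE, PhaseLabel.POST)
    modalities: tuple = Session.MODALITIES
    bands: tuple = tuple(BANDS)
    schedule: PhaseSchedule = DEFAULT_SCHEDULE
    out_dir: str | None = None
    seed: int | None = None
    alpha: float = 0.05
    apply_fdr_univariate: bool = False  # EMG/CoP/HR families stay raw-p by default
    gate_rule: str = "both"             # normality gate: "both" | "either"
    eeg_relative_power: bool = False    # absolute band power by default
    eeg_fdr_scope: str = "band"         # FDR family: "band" | "global"
    cop_smooth: bool = True             # Savitzky-Golay off = raw trajectories
    # stabilogram entropy configuration
    cop_tau_max: int = 10
    cop_m: int = 2
    cop_r_factor: float = 0.15

    def resolved_synth(self) -> SynthParams | None:
        if self.synth is None:
            return None
        if self.seed is not None:
            return dataclasses.replace(self.synth, seed=int(self.seed))
        return self.synth

    def validate(self) -> None:
        if (self.synth is None) == (self.input_dir is None):
            raise ValidationError(
                "exactly one of synth parameters or input_dir must be given"
            )
        labels = set(self.schedule.labels)
        for p in self.phases:
            try:
                lab = PhaseLabel(p)
            except ValueError:
                raise ValidationError(f"unknown phase {p!r}") from None
            if lab not in labels:
                raise ValidationError(f"phase {lab} not in schedule")
        for m in self.modalities:
            if m not in Session.MODALITIES:
                raise ValidationError(f"unknown modality {m!r}")
        for b in self.bands:
            if b not in BANDS:
                raise ValidationError(f"unknown band {b!r}")
        if self.gate_rule not in ("both", "either"):
            raise ValidationError(f"unknown gate rule {self.gate_rule!r}")
        if self.eeg_fdr_scope not in ("band", "global"):
            raise ValidationError(f"unknown FDR scope {self.eeg_fdr_scope!r}")


@dataclass
class PipelineResult:
    features: dict          # name -> DataFrame
    comparisons: dict       # name -> list[ComparisonRecord]
    manifest: dict
    paths: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; see the module docstring for outputs."""
    config.validate()
    phases = tuple(PhaseLabel(p) for p in config.phases)
    try:
        subject_frames = _extract_stage(config, phases)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'extract' failed: {exc}") from exc

    try:
        comparisons = _compare_stage(config, subject_frames, phases)
    except Exception as exc:
        raise PipelineError(f"stage 'compare' failed: {exc}") from exc

    manifest = _manifest(config)
    result = PipelineResult(subject_frames, comparisons, manifest)
    if config.out_dir is not None:
        try:
            result.paths = _report_stage(config, result)
        except Exception as exc:
            raise PipelineError(f"stage 'report' failed: {exc}") from exc
    return result


# ---------------------------------------------------------------------------
# extraction

def _iter_phase_segments(config: PipelineConfig, phases):
    """Yield ``(subject_id, group, {modality: {phase: TimeSeries}})``.

    Synthetic subjects are generated phase-by-phase on the fly, so only
    the analysed phases are ever materialised.
    """
    synth = config.resolved_synth()
    if synth is not None:
        for group, idx, subject_id in iter_subjects(synth):
            segs = generate_phase_segments(synth, group, idx, phases,
                                           config.modalities, config.schedule)
            yield subject_id, group, segs
    else:
        root = Path(config.input_dir)
        session_dirs = sorted(p for p in root.iterdir() if p.is_dir())
        if not session_dirs:
            raise PipelineError(f"no session directories under {root}")
        for sdir in session_dirs:
            session = read_session(sdir)
            session.validate(config.schedule)
            segset = segment_phases(session, config.schedule)
            segs = {m: {ph: segset.get(m, ph) for ph in phases}
                    for m in config.modalities}
            yield session.subject_id, session.group, segs


def _extract_stage(config: PipelineConfig, phases) -> dict:
    cop_rows, emg_rows, eeg_rows, hr_rows = [], [], [], []
    for subject_id, group, segs in _iter_phase_segments(config, phases):
        base = {"subject": subject_id, "group": group}
        for phase in phases:
            if "cop" in segs:
                ts = segs["cop"][phase]
                if config.cop_smooth:
                    ts = smooth_cop(ts)
                fs = extract_cop_features(ts, ts.rate, phase,
                                          tau_max=config.cop_tau_max,
                                          m=config.cop_m,
                                          r_factor=config.cop_r_factor)
                cop_rows.append({**base, "phase": str(phase), **fs.values})
            if "emg" in segs:
                ts = filter_emg(segs["emg"][phase])
                for muscle in EMG_MUSCLES:
                    feats = extract_emg_features(ts.channel(muscle), ts.rate,
                                                 muscle, phase)
                    emg_rows.append({**base, "muscle": muscle,
                                     "phase": str(phase), **feats.values})
            if "eeg" in segs:
                ts = preprocess_eeg(segs["eeg"][phase])
                bpm = band_power_map(ts, subject_id, phase,
                                     relative=config.eeg_relative_power)
                for el in bpm.powers.index:
                    for band in config.bands:
                        eeg_rows.append({**base, "phase": str(phase),
                                         "electrode": el, "band": band,
                                         "power": bpm.powers.loc[el, band]})
            if "hr" in segs:
                mean, sd = hr_summary(segs["hr"][phase].values)
                hr_rows.append({**base, "phase": str(phase),
                                "mean_bpm": mean, "sd_bpm": sd})
    frames = {}
    if cop_rows:
        frames["cop"] = pd.DataFrame(cop_rows)
    if emg_rows:
        frames["emg"] = pd.DataFrame(emg_rows)
    if eeg_rows:
        frames["eeg"] = pd.DataFrame(eeg_rows)
    if hr_rows:
        frames["hr"] = pd.DataFrame(hr_rows)
    return frames


# ---------------------------------------------------------------------------
# comparison

def _split_groups(df: pd.DataFrame):
    return df[df["group"] == "healthy"], df[df["group"] == "pd"]


def _compare_stage(config: PipelineConfig, frames: dict, phases) -> dict:
    comparisons: dict[str, list[ComparisonRecord]] = {}
    if "cop" in frames:
        recs = []
        for phase in phases:
            sub = frames["cop"][frames["cop"]["phase"] == str(phase)]
            a, b = _split_groups(sub)
            recs += compare_feature_tables(
                a[list(COP_FEATURE_NAMES)], b[list(COP_FEATURE_NAMES)],
                str(phase), alpha=config.alpha,
                apply_fdr=config.apply_fdr_univariate,
                gate_rule=config.gate_rule)
        comparisons["cop"] = recs
    if "emg" in frames:
        recs = []
        for phase in phases:
            for muscle in EMG_MUSCLES:
                sub = frames["emg"][
                    (frames["emg"]["phase"] == str(phase))
                    & (frames["emg"]["muscle"] == muscle)]
                if sub.empty:
                    continue
                a, b = _split_groups(sub)
                muscle_recs = compare_feature_tables(
                    a[list(EMG_FEATURES)], b[list(EMG_FEATURES)], str(phase),
                    alpha=config.alpha, apply_fdr=config.apply_fdr_univariate,
                    gate_rule=config.gate_rule)
                for r in muscle_recs:
                    r.feature = f"{muscle}/{r.feature}"
                recs += muscle_recs
        comparisons["emg"] = recs
    if "eeg" in frames:
        recs = []
        for phase in phases:
            for band in config.bands:
                maps_a, maps_b = [], []
                sub = frames["eeg"][frames["eeg"]["phase"] == str(phase)]
                for subject, sdf in sub.groupby("subject", sort=True):
                    pivot = sdf.pivot(index="electrode", columns="band",
                                      values="power")
                    m = BandPowerMap(subject, PhaseLabel(phase), pivot)
                    (maps_a if sdf["group"].iloc[0] == "healthy"
                     else maps_b).append(m)
                recs += topographic_comparison(maps_a, maps_b, band,
                                               phase, alpha=config.alpha)
        if config.eeg_fdr_scope == "global":
            # one FDR family across all (band, phase) electrode tests
            from .group_stats import bh_fdr

            adj = bh_fdr([r.p_value for r in recs])
            for r, q in zip(recs, adj):
                r.p_adjusted = float(q)
                r.significant = bool(q <= config.alpha)
        comparisons["eeg"] = recs
    if "hr" in frames:
        recs = []
        for phase in phases:
            sub = frames["hr"][frames["hr"]["phase"] == str(phase)]
            a, b = _split_groups(sub)
            recs += compare_feature_tables(
                a[["mean_bpm"]], b[["mean_bpm"]], str(phase),
                alpha=config.alpha, apply_fdr=config.apply_fdr_univariate,
                gate_rule=config.gate_rule)
        comparisons["hr"] = recs
    return comparisons


# ---------------------------------------------------------------------------
# reporting

def _manifest(config: PipelineConfig) -> dict:
    cfg = _config_dict(config)
    blob = json.dumps(cfg, sort_keys=True).encode()
    synth = config.resolved_synth()
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": None if synth is None else synth.seed,
        "versions": {
            "swaymetrics": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }


def _config_dict(config: PipelineConfig) -> dict:
    synth = config.resolved_synth()
    synth_dict = None
    if synth is not None:
        synth_dict = dataclasses.asdict(synth)
        synth_dict["eeg_band_offset"] = {
            f"{el}:{band}": factors
            for (el, band), factors in synth.eeg_band_offset.items()
        }
    return {
        "synth": synth_dict,
        "input_dir": config.input_dir,
        "phases": [str(p) for p in config.phases],
        "modalities": list(config.modalities),
        "bands": list(config.bands),
        "schedule": [[str(l), s, e] for l, s, e in config.schedule.entries],
        "alpha": config.alpha,
        "apply_fdr_univariate": config.apply_fdr_univariate,
        "gate_rule": config.gate_rule,
        "eeg_relative_power": config.eeg_relative_power,
        "eeg_fdr_scope": config.eeg_fdr_scope,
        "cop_smooth": config.cop_smooth,
        "cop_entropy": {"tau_max": config.cop_tau_max, "m": config.cop_m,
                        "r_factor": config.cop_r_factor},
    }


def _report_stage(config: PipelineConfig, result: PipelineResult) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        name_map = {"cop": "cop_features.csv", "emg": "emg_features.csv",
                    "eeg": "eeg_band_power.csv", "hr": "hr_summary.csv"}
        for key, df in result.features.items():
            path = out / name_map[key]
            df.to_csv(path, index=False, float_format=_FLOAT_FMT)
            written[name_map[key]] = path
        if "hr" in result.features:
            cohort = (result.features["hr"]
                      .groupby(["group", "phase"], sort=True)["mean_bpm"]
                      .agg(mean_bpm="mean", sd_bpm=lambda s: s.std(ddof=1))
                      .reset_index())
            path = out / "hr_cohort_summary.csv"
            cohort.to_csv(path, index=False, float_format=_FLOAT_FMT)
            written["hr_cohort_summary.csv"] = path
        for key, recs in result.comparisons.items():
            if not recs:
                continue
            path = out / f"{key}_comparison.csv"
            write_comparison_table(recs, path)
            written[f"{key}_comparison.csv"] = path
        path = out / "run_manifest.json"
        path.write_text(json.dumps(result.manifest, indent=1, sort_keys=True))
        written["run_manifest.json"] = path
    except Exception:
        for p in written.values():  # do not leave partial output behind
            p.unlink(missing_ok=True)
        raise
    return written
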