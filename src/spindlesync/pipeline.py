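"""End-to-end experiment orchestration.

For each simulated subject: build the head/sensor/source geometry,
synthesize matrix + core spindle activity and 1/f background, render EEG
and MEG recordings from the same ground-truth sources, low-pass at 40 Hz,
estimate diagonal noise covariances from band-passed (10-15 Hz) quiet
epochs (or an empty-room recording for MEG), compute EEG-only, MEG-only
and combined inverse operators, apply dSPM to every annotated spindle,
and compute the synchrony statistics.  Statistics are aggregated in two
levels — spindles within subject, then across subjects — so grand values
are means of subject means.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from . import __version__
from .geometry import (
    Modality,
    SourceSpace,
    SphericalHeadModel,
    build_sensor_array,
    build_source_space,
)
from .forward import GainMatrix, assemble_gain
from .inverse import (
    InverseOperator,
    apply_dspm,
    combined_inverse,
    compute_inverse_operator,
    estimate_noise_covariance,
    signed_normal_timecourses,
)
from .simulate import (
    Annotation,
    GeneratorConfig,
    Recording,
    SpindleEvent,
    _quiet_epoch_annotations,
    _sensor_noise,
    extract_epochs,
    filter_recording,
    one_over_f_noise,
    sample_spindle_events,
    synthesize_core_activity,
    synthesize_matrix_activity,
)
from .synchrony import (
    ActivationMap,
    average_max_maps,
    between_modality_correlation,
    map_correlation,
    mean_pairwise_correlation,
    mvdr_coherence,
    spindle_max_map,
    welch_coherence,
)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage failure with subject/spindle context attached."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Study design: defaults mirror the recorded protocol at desk scale.

    7 subjects x 12 spindles (~85 events) with 100 quiet 600-ms epochs per
    subject; source space 642 dipoles per hemisphere (a decimated stand-in
    for the ~3200/hemisphere of a full cortical reconstruction).
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_per_hemisphere: int = 642
    fold_amplitude: float = 0.1
    fold_wavenumber: int = 12
    source_radius: float = 0.070
    shell_radii: tuple[float, float, float] = (0.080, 0.085, 0.092)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    legendre_order: int = 120
    snr: float = 1.0
    covariance_mode: str = "baseline_epochs"  # | "empty_room" (MEG only)
    welch_segment_length: int = 128
    welch_overlap: float = 0.5
    coherence_source_subsample: int | None = None
    master_seed: int = 0
    output_dir: str | None = None

    def head(self) -> SphericalHeadModel:
        return SphericalHeadModel(
            shell_radii=self.shell_radii,
            conductivities=self.conductivities,
            legendre_order=self.legendre_order,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator", {})
        if "n_core_patches_per_spindle" in gen:
            gen["n_core_patches_per_spindle"] = tuple(gen["n_core_patches_per_spindle"])
        for key in ("shell_radii", "conductivities"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=GeneratorConfig(**gen), **raw)

    def hash(self) -> str:
        """Design hash: identifies the study conditions, not the seed."""
        payload = asdict(self)
        payload.pop("master_seed")
        payload.pop("output_dir")
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Report schema
# ---------------------------------------------------------------------------

class StatSummary(BaseModel):
    mean: float
    sd: float


class GrandStats(BaseModel):
    within_eeg_r: StatSummary
    within_meg_r: StatSummary
    within_combined_r: StatSummary
    between_modality_r: StatSummary
    between_modality_coherence_welch: StatSummary
    between_modality_coherence_mvdr: StatSummary
    map_correlation_eeg_meg: StatSummary


class ExperimentReport(BaseModel):
    """Two-level aggregate of the synchrony statistics.

    ``grand`` values are means (+/- SD) of subject means, each subject
    mean being a mean over its spindles.
    """

    config_hash: str
    master_seed: int
    version: str
    n_subjects: int
    n_sources: int
    n_pairs_per_spindle: int
    per_spindle: list[dict]
    per_subject: list[dict]
    grand: GrandStats

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def per_spindle_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_spindle)

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentReport":
        return cls.model_validate_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Subject-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Everything simulated and estimated for one subject."""

    source_space: SourceSpace
    rec_eeg: Recording
    rec_meg: Recording
    gain_eeg: GainMatrix
    gain_meg: GainMatrix
    events: tuple[SpindleEvent, ...]
    operators: dict[str, InverseOperator] = field(default_factory=dict)


def simulate_subject(
    config: ExperimentConfig, subject_seed: np.random.SeedSequence
) -> SubjectData:
    """Geometry, ground truth, and both modality recordings for a subject."""
    seeds = subject_seed.spawn(6)
    geo_seed = int(seeds[0].generate_state(1)[0] % 2**31)
    head = config.head()
    ss = build_source_space(
        config.n_per_hemisphere,
        config.fold_amplitude,
        config.fold_wavenumber,
        seed=geo_seed,
        radius=config.source_radius,
    )
    arr_eeg = build_sensor_array(Modality.EEG, head, seed=geo_seed)
    arr_meg = build_sensor_array(Modality.MEG, head, seed=geo_seed)
    gain_eeg = assemble_gain(ss, arr_eeg, head)
    gain_meg = assemble_gain(ss, arr_meg, head)
    Gn = {"EEG": gain_eeg.along_normals(ss), "MEG": gain_meg.along_normals(ss)}

    gen = config.generator
    ev_seed = int(seeds[1].generate_state(1)[0] % 2**31)
    events = tuple(sample_spindle_events(gen, ss, seed=ev_seed))
    n_samples = int(round(gen.record_duration * gen.sampling_rate))
    x = {"EEG": np.zeros((60, n_samples)), "MEG": np.zeros((306, n_samples))}

    for ev in events:
        parts = []
        if gen.matrix_amplitude > 0:
            parts.append(synthesize_matrix_activity(ev, ss, gen))
        if gen.core_amplitude > 0 and ev.core_patches:
            parts.append(synthesize_core_activity(ev, ss, gen))
        for act in parts:
            i0, i1 = act.first_sample, act.first_sample + act.values.shape[1]
            for mod in ("EEG", "MEG"):
                x[mod][:, i0:i1] += Gn[mod] @ act.values

    # 1/f background, chunked over sources so the full source x time matrix
    # is never materialized; the same draw feeds both modalities
    if gen.background_amplitude > 0:
        bg_rng = np.random.default_rng(seeds[2])
        chunk = 128
        for j0 in range(0, ss.n_sources, chunk):
            j1 = min(j0 + chunk, ss.n_sources)
            bg = gen.background_amplitude * one_over_f_noise(
                j1 - j0, n_samples, bg_rng, gen.sampling_rate
            )
            for mod in ("EEG", "MEG"):
                x[mod] += Gn[mod][:, j0:j1] @ bg

    noise_rng = np.random.default_rng(seeds[3])
    annotations = [Annotation("spindle", ev.onset, ev.duration) for ev in events]
    annotations += _quiet_epoch_annotations(events, gen)
    recs = {}
    for mod, arr in (("EEG", arr_eeg), ("MEG", arr_meg)):
        recs[mod] = Recording(
            values=x[mod] + _sensor_noise(arr, n_samples, gen, noise_rng),
            sampling_rate=gen.sampling_rate,
            array=arr,
            annotations=list(annotations),
            provenance="simulated",
            events=events,
        )
    return SubjectData(
        source_space=ss,
        rec_eeg=recs["EEG"],
        rec_meg=recs["MEG"],
        gain_eeg=gain_eeg,
        gain_meg=gain_meg,
        events=events,
    )


def build_operators(
    config: ExperimentConfig,
    data: SubjectData,
    empty_room_seed: int = 12345,
) -> dict[str, InverseOperator]:
    """EEG, MEG and combined dSPM operators from band-passed quiet epochs."""
    bp_eeg = filter_recording(data.rec_eeg, "band10_15")
    bp_meg = filter_recording(data.rec_meg, "band10_15")
    cov_eeg = estimate_noise_covariance(
        extract_epochs(bp_eeg, "quiet_epoch"), "baseline_epochs",
        channel_order=data.rec_eeg.array.names,
    )
    if config.covariance_mode == "empty_room":
        from .simulate import empty_room_recording

        n = int(round(60.0 * config.generator.sampling_rate))
        er = empty_room_recording(data.rec_meg.array, config.generator, n, seed=empty_room_seed)
        er = filter_recording(er, "band10_15")
        cov_meg = estimate_noise_covariance(
            er.values, "empty_room", channel_order=data.rec_meg.array.names
        )
    else:
        cov_meg = estimate_noise_covariance(
            extract_epochs(bp_meg, "quiet_epoch"), "baseline_epochs",
            channel_order=data.rec_meg.array.names,
        )
    ops = {
        "EEG": compute_inverse_operator(data.gain_eeg, cov_eeg, config.snr),
        "MEG": compute_inverse_operator(data.gain_meg, cov_meg, config.snr),
        "combined": combined_inverse(
            data.gain_eeg, data.gain_meg, cov_eeg, cov_meg, config.snr
        ),
    }
    return ops


def _mvdr_length(n_samples: int) -> int:
    """Largest admissible MVDR filter length for a short interval."""
    return int(np.clip(n_samples // 20, 8, 64))


def analyze_subject(
    config: ExperimentConfig, data: SubjectData, subject_index: int
) -> tuple[list[dict], dict]:
    """Per-spindle statistics and the subject-level aggregate."""
    lp_eeg = filter_recording(data.rec_eeg, "lowpass40")
    lp_meg = filter_recording(data.rec_meg, "lowpass40")
    ops = data.operators
    fs = config.generator.sampling_rate
    n = data.source_space.n_sources
    rows: list[dict] = []
    maps: dict[str, list[ActivationMap]] = {"EEG": [], "MEG": [], "combined": []}
    spindles = [a for a in lp_eeg.annotations if a.label == "spindle"]
    rng = np.random.default_rng(config.master_seed + subject_index)
    for k, ann in enumerate(spindles):
        try:
            ests = {
                "EEG": apply_dspm(ops["EEG"], lp_eeg, ann, spindle_id=k),
                "MEG": apply_dspm(ops["MEG"], lp_meg, ann, spindle_id=k),
            }
            sl = lp_eeg.sample_slice(ann)
            stacked = np.vstack([lp_eeg.values[:, sl], lp_meg.values[:, sl]])
            ests["combined"] = apply_dspm(ops["combined"], stacked, spindle_id=k)
            row = {"subject": subject_index, "spindle": k, "duration": ann.duration}
            for mod, est in ests.items():
                row[f"within_{mod.lower()}_r"] = mean_pairwise_correlation(est)
            # between-modality comparisons use signed normal-component time
            # courses: the rectified magnitude folds the spindle rhythm onto
            # twice its frequency, outside the 10-15 Hz coherence band
            ori = data.source_space.orientations
            sig_e = signed_normal_timecourses(ops["EEG"], lp_eeg, ori, ann)
            sig_m = signed_normal_timecourses(ops["MEG"], lp_meg, ori, ann)
            row["between_modality_r"] = between_modality_correlation(sig_e, sig_m)
            n_samp = ests["EEG"].values.shape[1]
            if config.coherence_source_subsample and config.coherence_source_subsample < n:
                src_idx = np.sort(
                    rng.choice(n, size=config.coherence_source_subsample, replace=False)
                )
            else:
                src_idx = np.arange(n)
            seg = min(config.welch_segment_length, max(16, n_samp // 2))
            L = _mvdr_length(n_samp)
            welch_vals, mvdr_vals = [], []
            for j in src_idx:
                a = sig_e[j]
                b = sig_m[j]
                welch_vals.append(
                    welch_coherence(a, b, fs, segment_length=seg, overlap=config.welch_overlap)
                )
                mvdr_vals.append(mvdr_coherence(a, b, fs, filter_length=L))
            row["between_modality_coherence_welch"] = float(np.mean(welch_vals))
            row["between_modality_coherence_mvdr"] = float(np.mean(mvdr_vals))
            rows.append(row)
            for mod, est in ests.items():
                maps[mod].append(spindle_max_map(est))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(
                f"stats stage failed for subject {subject_index}, spindle {k}: {exc}"
            ) from exc

    frame = pd.DataFrame(rows)
    avg_maps = {mod: average_max_maps(m) for mod, m in maps.items()}
    subject_row = {
        "subject": subject_index,
        "n_spindles": len(rows),
        "map_correlation_eeg_meg": map_correlation(avg_maps["EEG"], avg_maps["MEG"]),
    }
    for col in frame.columns:
        if col in ("subject", "spindle"):
            continue
        subject_row[col] = float(frame[col].mean())
    subject_row["_avg_maps"] = avg_maps
    return rows, subject_row


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Simulate, invert and analyze every subject; aggregate two-level."""
    root = np.random.SeedSequence(config.master_seed)
    subject_seeds = root.spawn(config.generator.n_subjects)
    all_rows: list[dict] = []
    subject_rows: list[dict] = []
    n_sources = None
    for s, sseed in enumerate(subject_seeds):
        try:
            data = simulate_subject(config, sseed)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"simulate stage failed for subject {s}: {exc}") from exc
        try:
            data.operators = build_operators(config, data)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"inverse stage failed for subject {s}: {exc}") from exc
        rows, subject_row = analyze_subject(config, data, s)
        subject_row.pop("_avg_maps")
        all_rows.extend(rows)
        subject_rows.append(subject_row)
        n_sources = data.source_space.n_sources

    frame = pd.DataFrame(subject_rows)

    def summary(col: str) -> StatSummary:
        vals = frame[col].to_numpy(dtype=float)
        return StatSummary(mean=float(vals.mean()), sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0)

    grand = GrandStats(
        within_eeg_r=summary("within_eeg_r"),
        within_meg_r=summary("within_meg_r"),
        within_combined_r=summary("within_combined_r"),
        between_modality_r=summary("between_modality_r"),
        between_modality_coherence_welch=summary("between_modality_coherence_welch"),
        between_modality_coherence_mvdr=summary("between_modality_coherence_mvdr"),
        map_correlation_eeg_meg=summary("map_correlation_eeg_meg"),
    )
    report = ExperimentReport(
        config_hash=config.hash(),
        master_seed=config.master_seed,
        version=__version__,
        n_subjects=config.generator.n_subjects,
        n_sources=int(n_sources),
        n_pairs_per_spindle=int(n_sources * (n_sources - 1) // 2),
        per_spindle=all_rows,
        per_subject=subject_rows,
        grand=grand,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        config.to_yaml(out / "config.yaml")
        pd.DataFrame(all_rows).to_csv(out / "per_spindle.csv", index=False)
    return report
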