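"""End-to-end experiment, one subject at desk scale (~30 s).

Simulates one subject with 6 spindles on the 642-dipole/hemisphere
source space, runs the EEG/MEG/combined dSPM inversions, and prints the
synchrony statistics.  The qualitative pattern — EEG-derived sources far
more synchronous than MEG-derived ones, near-zero between-modality
correlation but substantial band coherence — is the analysis's headline
structure.  (The full run uses 7 subjects x 12 spindles:
`spindlesync run-all --out results`.)
"""

from spindlesync import ExperimentConfig, GeneratorConfig, run_experiment

config = ExperimentConfig(
    generator=GeneratorConfig(n_subjects=1, spindles_per_subject=6, seed=0),
    coherence_source_subsample=50,
    master_seed=1,
)
report = run_experiment(config)
g = report.grand
print(f"{report.n_subjects} subject(s), {report.n_sources} sources, "
      f"{report.n_pairs_per_spindle} source pairs per spindle")
print(f"within-modality mean r:   EEG {g.within_eeg_r.mean:.2f}   "
      f"MEG {g.within_meg_r.mean:.2f}   combined {g.within_combined_r.mean:.2f}")
print(f"between-modality:         r {g.between_modality_r.mean:+.2f}   "
      f"coherence Welch {g.between_modality_coherence_welch.mean:.2f} / "
      f"MVDR {g.between_modality_coherence_mvdr.mean:.2f}")
print(f"EEG-vs-MEG map correlation: {g.map_correlation_eeg_meg.mean:.2f}")
print("\n-> sources estimated from EEG oscillate together; the same spindles seen")
print("   through MEG decompose into shifting, mutually asynchronous foci.")
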