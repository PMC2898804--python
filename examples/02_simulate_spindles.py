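"""Simulate one subject's spindles and look at the two source systems.

Draws spindle events (durations 721 +/- 235 ms in [483, 1123] ms, 10-15
Hz), synthesizes the diffuse synchronous matrix system and the focal
asynchronous core patches, and reports how visible each system is to EEG
versus MEG at the sensors.
"""

import numpy as np

from spindlesync import (
    GeneratorConfig,
    SphericalHeadModel,
    assemble_gain,
    build_sensor_array,
    build_source_space,
    sample_spindle_events,
    synthesize_core_activity,
    synthesize_matrix_activity,
)

head = SphericalHeadModel()
ss = build_source_space(200, fold_amplitude=0.1, fold_wavenumber=12, seed=0)
cfg = GeneratorConfig(spindles_per_subject=12, seed=0)

events = sample_spindle_events(cfg, ss, seed=1)
durations = np.array([ev.duration for ev in events]) * 1e3
print(f"{len(events)} spindles, durations {durations.mean():.0f} +/- {durations.std():.0f} ms "
      f"(range {durations.min():.0f}-{durations.max():.0f} ms)")
print(f"matrix frequencies: {[round(ev.matrix_frequency, 1) for ev in events[:5]]} ... Hz")
print(f"core patches per spindle: {[len(ev.core_patches) for ev in events]}")

eeg_gain = assemble_gain(ss, build_sensor_array("EEG", head, seed=0), head).along_normals(ss)
meg_gain = assemble_gain(ss, build_sensor_array("MEG", head, seed=0), head).along_normals(ss)

ev = events[0]
matrix = synthesize_matrix_activity(ev, ss, cfg).values
core = synthesize_core_activity(ev, ss, cfg).values


def rms(x):
    return float(np.sqrt((x**2).mean()))


r_eeg = rms(eeg_gain @ matrix) / rms(eeg_gain @ core)
r_meg = rms(meg_gain @ matrix) / rms(meg_gain @ core)
print(f"\nsensor RMS ratio matrix/core:  EEG {r_eeg:.1f}   MEG {r_meg:.1f}")
print("-> the diffuse matrix system dominates EEG far more strongly than MEG,")
print("   the differential visibility that drives the whole analysis.")
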