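{
 "$defs": {
  "GrandStats": {
   "properties": {
    "between_modality_coherence_mvdr": {
     "$ref": "#/$defs/StatSummary"
    },
    "between_modality_coherence_welch": {
     "$ref": "#/$defs/StatSummary"
    },
    "between_modality_r": {
     "$ref": "#/$defs/StatSummary"
    },
    "map_correlation_eeg_meg": {
     "$ref": "#/$defs/StatSummary"
    },
    "within_combined_r": {
     "$ref": "#/$defs/StatSummary"
    },
    "within_eeg_r": {
     "$ref": "#/$defs/StatSummary"
    },
    "within_meg_r": {
     "$ref": "#/$defs/StatSummary"
    }
   },
   "required": [
    "within_eeg_r",
    "within_meg_r",
    "within_combined_r",
    "between_modality_r",
    "between_modality_coherence_welch",
    "between_modality_coherence_mvdr",
    "map_correlation_eeg_meg"
   ],
   "title": "GrandStats",
   "type": "object"
  },
  "StatSummary": {
   "properties": {
    "mean": {
     "title": "Mean",
     "type": "number"
    },
    "sd": {
     "title": "Sd",
     "type": "number"
    }
   },
   "required": [
    "mean",
    "sd"
   ],
   "title": "StatSummary",
   "type": "object"
  }
 },
 "description": "Two-level aggregate of the synchrony statistics.\n\n``grand`` values are means (+/- SD) of subject means, each subject\nmean being a mean over its spindles.",
 "properties": {
  "config_hash": {
   "title": "Config Hash",
   "type": "string"
  },
  "grand": {
   "$ref": "#/$defs/GrandStats"
  },
  "master_seed": {
   "title": "Master Seed",
   "type": "integer"
  },
  "n_pairs_per_spindle": {
   "title": "N Pairs Per Spindle",
   "type": "integer"
  },
  "n_sources": {
   "title": "N Sources",
   "type": "integer"
  },
  "n_subjects": {
   "title": "N Subjects",
   "type": "integer"
  },
  "per_spindle": {
   "items": {
    "additionalProperties": true,
    "type": "object"
   },
   "title": "Per Spindle",
   "type": "array"
  },
  "per_subject": {
   "items": {
    "additionalProperties": true,
    "type": "object"
   },
   "title": "Per Subject",
   "type": "array"
  },
  "version": {
   "title": "Version",
   "type": "string"
  }
 },
 "required": [
  "config_hash",
  "master_seed",
  "version",
  "n_subjects",
  "n_sources",
  "n_pairs_per_spindle",
  "per_spindle",
  "per_subject",
  "grand"
 ],
 "title": "ExperimentReport",
 "type": "object"
}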