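# Channel-name equivalence groups for PSG montages.
# Names within a group refer to the same derivation; matching is
# case-insensitive.  Edit or extend freely for local montages.
- ["EEG Fpz-Cz", "Fpz-Cz"]
- ["EEG Pz-Oz", "Pz-Oz"]
- ["EOG horizontal", "ROC-LOC", "EOG ROC-LOC", "EOG(L)", "LOC-ROC", "EOG LOC-ROC"]
- ["EEG C4-A1", "C4-A1", "C4-M1"]
- ["EEG C3-A2", "C3-A2", "C3-M2"]
- ["EEG F4-A1", "F4-A1", "F4-M1"]
- ["EEG F3-A2", "F3-A2", "F3-M2"]
- ["EOG left", "EOGL", "EOG(L) E1-M2", "E1-M2"]
- ["EOG right", "EOGR", "E2-M1"]
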