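# two groups that differ in inter-channel coupling; 30-s recordings
groups:
  - label: hi
    n_subjects: 10
    duration: 30
    coupling: 0.9
  - label: lo
    n_subjects: 10
    duration: 30
    coupling: 0.1
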