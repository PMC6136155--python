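# Calcium sensor -> kernel speed class (fast = 0.7 s, medium = 1.25 s, slow = 2 s).
# GCaMP6 variants are assigned by version: 6f fast, 6m medium, 6s slow,
# matching the published ordering of their decay times.
OGB        medium
GCaMP5k    fast
jRCaMP1a   slow
jRGECO1a   fast
GCaMP6f    fast
GCaMP6m    medium
GCaMP6s    slow
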