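# Single-cell carrier design: TMTpro 16-plex, channel 126 carries a bulk
# proteome at 14-434x the single-cell amount, channel 127C is left empty, and
# the remaining 14 channels hold equal single-cell samples.  Isotopic
# impurity leakage (same-type +1 at 4%, -1 at 1%, plus carrier cross-type
# leakage into 127N) inflates the carrier's neighbors unless corrected.
name = "ds1_carrier"
label_set = "TMTpro16"
n_plexes = 1
channel_roles = [
    "carrier", "sample", "empty", "sample", "sample", "sample", "sample",
    "sample", "sample", "sample", "sample", "sample", "sample", "sample",
    "sample", "sample",
]
channel_conditions = [
    "", "sc", "", "sc", "sc", "sc", "sc", "sc", "sc", "sc", "sc", "sc",
    "sc", "sc", "sc", "sc",
]
psms_per_protein = 3.0
noise_sigma = 0.1
abundance_sigma = 2.0

[[species]]
name = "human"
n_proteins = 300
reference_amount = 0.0
carrier_amount = 434.0

[species.condition_amounts]
sc = 1.0

[correction]
entries = [
    ["126", "127C", 4.0],
    ["127N", "128N", 4.0],
    ["127C", "128C", 4.0],
    ["128N", "129N", 4.0],
    ["128C", "129C", 4.0],
    ["129N", "130N", 4.0],
    ["129C", "130C", 4.0],
    ["130N", "131N", 4.0],
    ["130C", "131C", 4.0],
    ["131N", "132N", 4.0],
    ["131C", "132C", 4.0],
    ["132N", "133N", 4.0],
    ["132C", "133C", 4.0],
    ["133N", "134N", 4.0],
    ["127C", "126", 1.0],
    ["128N", "127N", 1.0],
    ["128C", "127C", 1.0],
    ["129N", "128N", 1.0],
    ["129C", "128C", 1.0],
    ["130N", "129N", 1.0],
    ["130C", "129C", 1.0],
    ["131N", "130N", 1.0],
    ["131C", "130C", 1.0],
    ["132N", "131N", 1.0],
    ["132C", "131C", 1.0],
    ["133N", "132N", 1.0],
    ["133C", "132C", 1.0],
    ["134N", "133N", 1.0],
    ["126", "127N", 1.0],
]
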