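# Two-proteome ratio series: TMT 11-plex with a constant human background of
# 50 units in every sample channel and yeast spiked at 1 / 1.75 / 3 / 5.2 / 9
# units (two replicates per plex), against a reference channel holding
# 50 units human + 3.9 units yeast.  Per-plex batch scale factors are drawn
# uniformly from [0.25, 4] to emulate plex-to-plex intensity batch effects.
name = "ds3_two_proteome"
label_set = "TMT11"
n_plexes = 2
channel_roles = [
    "sample", "sample", "sample", "sample", "sample",
    "sample", "sample", "sample", "sample", "sample",
    "reference",
]
channel_conditions = [
    "y1.0", "y1.0", "y1.75", "y1.75", "y3.0",
    "y3.0", "y5.2", "y5.2", "y9.0", "y9.0",
    "",
]
psms_per_protein = 5.0
noise_sigma = 0.1
batch_factor_range = [0.25, 4.0]
abundance_sigma = 2.0

[[species]]
name = "human"
n_proteins = 200
reference_amount = 50.0

[species.condition_amounts]
"y1.0" = 50.0
"y1.75" = 50.0
"y3.0" = 50.0
"y5.2" = 50.0
"y9.0" = 50.0

[[species]]
name = "yeast"
n_proteins = 200
reference_amount = 3.9

[species.condition_amounts]
"y1.0" = 1.0
"y1.75" = 1.75
"y3.0" = 3.0
"y5.2" = 5.2
"y9.0" = 9.0
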