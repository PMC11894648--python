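# Ratio-compression design: TMTpro 16-plex with a constant human background
# of 100 units and yeast at 0 / 6 / 9 / 12 units in triplicate; the first
# channel is left empty (as are the three unused high channels).  Per-PSM
# co-isolation contamination draws its reporter pattern from the constant
# human background and sets the PSM's true PIF to 1 - f, so raising the PIF
# threshold removes the most ratio-compressed spectra.
name = "ds5_phospho_ratios"
label_set = "TMTpro16"
n_plexes = 1
channel_roles = [
    "empty",
    "sample", "sample", "sample", "sample", "sample", "sample",
    "sample", "sample", "sample", "sample", "sample", "sample",
    "empty", "empty", "empty",
]
channel_conditions = [
    "",
    "100:0", "100:0", "100:0",
    "100:6", "100:6", "100:6",
    "100:9", "100:9", "100:9",
    "100:12", "100:12", "100:12",
    "", "", "",
]
psms_per_protein = 8.0
noise_sigma = 0.1
contamination_clean_fraction = 0.3
contamination_max = 0.6
background_species = "human"
abundance_sigma = 2.0

[[species]]
name = "human"
n_proteins = 400

[species.condition_amounts]
"100:0" = 100.0
"100:6" = 100.0
"100:9" = 100.0
"100:12" = 100.0

[[species]]
name = "yeast"
n_proteins = 400

[species.condition_amounts]
"100:0" = 0.0
"100:6" = 6.0
"100:9" = 9.0
"100:12" = 12.0
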