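# Synthetic paddy-soil depth-profile fixture (ground truth for the chip
# simulator; not measured data). Emulates a flooded paddy microcosm
# sliced at 2-mm intervals after 30 days of incubation, plus the bulk
# soil before flooding. True abundances per methanotroph type follow the
# reported orders of magnitude (type Ia and Ib 1e5-1e6, type IIa ~1e7
# copies per g dry soil), peak in the 0-2 mm oxic surface layer, and put
# the 0-2 mm layer at 3.4x (Ia) and 4.8x (Ib) the pre-flooding value,
# i.e. increases of 240% and 380%. The type IIa minimum sits at 6-8 mm,
# the only layer distinguishable from the surface for that type.

[design]
samples = ["before", "0-2", "2-4", "4-6", "6-8", "8-10"]
mob_types = ["Ia", "Ib", "IIa"]
replicates = 3
rep_sd_log10 = 0.05
seed = 7

[extraction]
elution_volume_ul = 100.0
soil_dry_mass_g = 0.5
template_volume_ul = 1.5
reaction_volume_ul = 15.0

# Abundant type IIa extracts are pre-diluted tenfold so chips stay in
# the precise occupancy range (lambda below ~1).
[extraction.template_dilution]
Ia = 1.0
Ib = 1.0
IIa = 10.0

[truth.before]
Ia = 2.5e5
Ib = 2.0e5
IIa = 1.6e7

[truth."0-2"]
Ia = 8.5e5
Ib = 9.6e5
IIa = 2.1e7

[truth."2-4"]
Ia = 4.0e5
Ib = 5.0e5
IIa = 1.7e7

[truth."4-6"]
Ia = 2.8e5
Ib = 3.0e5
IIa = 1.4e7

[truth."6-8"]
Ia = 2.0e5
Ib = 2.2e5
IIa = 1.1e7

[truth."8-10"]
Ia = 1.8e5
Ib = 2.0e5
IIa = 1.3e7
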