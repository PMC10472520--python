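# pmoA typing assay for chip digital PCR.
# Universal pmoA/amoA primer pair plus three hydrolysis probes specific
# to type Ia, Ib and IIa methanotrophs. Probes are written 5'->3' as
# synthesized and hybridize to the sense strand of the amplicon.

[assay]
chip_wells = 20000
loaded_volume_ul = 14.5
reaction_volume_ul = 15.0
template_volume_ul = 1.5

[primers.forward]
name = "A189f"
sequence = "GGNGACTGGGACTTCTGG"

[primers.reverse]
name = "A682r"
sequence = "GAASGCNGAGAAGAASGC"

[[probes]]
name = "mb661_Ia"
sequence = "ATACWGGAGCAACGTCYTTACCRA"
target_groups = ["Ia"]
fluorophore = "FAM"
quenchers = ["ZEN", "IBFQ"]
annealing_c = 57.0

[[probes]]
name = "Ib547"
sequence = "ACATCAGCATSCCGTTGTAYTCMAC"
target_groups = ["Ib", "RPC1"]
fluorophore = "FAM"
quenchers = ["ZEN", "IBFQ"]
annealing_c = 55.0

[[probes]]
name = "II646_mod"
sequence = "CGTGCCGCGCTCSACCATGY"
target_groups = ["IIa"]
fluorophore = "FAM"
quenchers = ["ZEN", "IBFQ"]
annealing_c = 57.0
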