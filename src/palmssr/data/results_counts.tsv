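key	value
redundant_est_ssrs	85014
primer_and_exon_filtered	7492
nonredundant_est_ssrs	418
validation_panel	232
amplified	145
polymorphic	100
pic_high	39
pic_medium	61
pic_low	31
pic_null	14
total_marker_bands	476
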