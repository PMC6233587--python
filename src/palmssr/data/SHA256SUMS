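d6e970e5f19ba436f90f34c1f2be4543c9af6baf7d49e04cd3e64d37e667275f  table1_tissue.tsv
59bd74bdc3b37dd63ec1aa3fb3ecf3838cdb0401693fd2573aa0b0cc0f2e14fe  table1_repeats.tsv
bd60b386537506586f7b95466b1cbd6e67c9dd093a90a569242dfd50351fc658  table1_motifs.tsv
bf855549622912265e0f1a9d4552256e6a4bfe68e6390c9979e850fa8997f224  results_counts.tsv
3294b1b5f74f359f656d718f3473fd8586ce47ac81da276ff51ddc4b52a58592  transfer_counts.tsv
a88d27971d742cd21c3d98ac94e3bd52584cfd144964fa6690a563800e86983c  table2_private_alleles.tsv
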