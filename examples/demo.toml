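# Fully synthetic end-to-end demo: simulates a diverged genome pair with
# one planted insertion and one planted inversion, then runs alignment,
# region/inversion calling, repeat landscape and copy-number estimation.
#
#   genomepair all --config examples/demo.toml

[output]
dir = "demo_out"

[simulate]
seed = 21
n_chromosomes = 2
chrom_length = 150000
snp_divergence = 0.02
n_genes = 8
gene_length = 1000
# family, consensus length (bp), copies in genome A, copies in genome B
te_library = [["LTR_gypsy", 3000, 3, 4], ["LINE", 2000, 2, 2]]
rdna_unit_length = 3000
rdna_array_copies_a = 2
rdna_array_copies_b = 3
# chromosome index, position, length, rDNA / TE / random composition weights
insertions = [[0, 100000, 25000, 0.3, 0.2, 0.5]]
# chromosome index, start, length
inversions = [[1, 40000, 20000]]
coverage = 8.0

[regions]
min_block = 2000
min_len = 2000
min_region = 10000
merge_gap = 5000

[inversions]
chain_gap = 30000
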