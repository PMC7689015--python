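import numpy as np
import pytest

from genomepair.simulate import (PlantedInsertion, PlantedInversion,
                                 SimulationConfig, TEFamily,
                                 simulate_genome_pair, simulate_reads)


@pytest.fixture(scope="session")
def small_pair():
    """A small diverged genome pair with one insertion and one inversion."""
    cfg = SimulationConfig(
        seed=11, n_chromosomes=2, chrom_length=200_000, snp_divergence=0.02,
        n_genes=10, gene_length=1_000,
        te_library=(TEFamily("LTR_gypsy", 4_000, 4, 5),
                    TEFamily("LINE", 2_500, 3, 3)),
        rdna_unit_length=3_000, rdna_array_copies_a=3, rdna_array_copies_b=5,
        insertions=(PlantedInsertion(0, 120_000, 40_000,
                                     w_rdna=0.3, w_te=0.2, w_random=0.5),),
        inversions=(PlantedInversion(1, 60_000, 30_000),),
        coverage=10.0, read_length=100, read_error_rate=0.01,
    )
    genome_a, genome_b, ann_a, ann_b, truth = simulate_genome_pair(cfg)
    return cfg, genome_a, genome_b, ann_a, ann_b, truth


@pytest.fixture(scope="session")
def cnv_sim():
    """Single-chromosome genome with repeat families of known copy number
    and its read set (used by the copy-number tests)."""
    cfg = SimulationConfig(
        seed=3, n_chromosomes=1, chrom_length=120_000, snp_divergence=0.0,
        n_genes=15, gene_length=1_000,
        te_library=(TEFamily("LTR_gypsy", 2_000, 5, 5),
                    TEFamily("LINE", 1_500, 20, 20),
                    TEFamily("LTR_copia", 1_000, 1, 1)),
        rdna_unit_length=3_000, rdna_array_copies_a=10,
        rdna_array_copies_b=10,
        coverage=20.0, read_length=100, read_error_rate=0.01,
    )
    genome_a, _, ann_a, _, truth = simulate_genome_pair(cfg)
    reads = simulate_reads(genome_a, cfg)
    return cfg, genome_a, ann_a, truth, reads
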