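"""Synthetic-evaluation protocols: planted-truth recovery benchmarks.

Each function builds the study conditions for one benchmark (fixed synthetic
design, seeded), runs the relevant pipeline stages, and returns the measured
recovery metrics.  The suite and the reproduction script both call these, so
reported numbers always come from a fresh run of the package.
"""

from __future__ import annotations

import random as pyrandom
import warnings

import dendropy
import numpy as np

from .cnv import calibrate_single_copy, map_reads_depth
from .formats import SequenceRecord
from .landscape import chi_square_homogeneity
from .phylo import (DistanceMatrix, neighbor_joining, tree_bipartitions,
                    tree_path_distances)
from .pipeline import cnv_from_annotations
from .simulate import (PlantedInsertion, PlantedInversion, SimulationConfig,
                       TEFamily, simulate_genome_pair, simulate_reads)
from .structural import (anchor_align, detect_inversions,
                         detect_specific_regions, filter_blocks)


# ---------------------------------------------------------------------------
# Structural recovery: planted insertions and inversions on a 2 x 1 Mb pair
# ---------------------------------------------------------------------------

STRUCTURAL_MIN_REGION = 20_000
STRUCTURAL_MERGE_GAP = 10_000
STRUCTURAL_CHAIN_GAP = 50_000


def structural_recovery_config(seed: int) -> SimulationConfig:
    """Two 1-Mb chromosomes at 2% SNP divergence with three planted
    insertions (0.05-0.2 Mb, rDNA/TE/random composition) and two planted
    inversions (60 and 150 kb)."""
    return SimulationConfig(
        seed=seed, n_chromosomes=2, chrom_length=1_000_000,
        snp_divergence=0.02, n_genes=20, gene_length=1_000,
        te_library=(TEFamily("LTR_gypsy", 5_000, 6, 10),
                    TEFamily("LTR_copia", 4_000, 5, 5),
                    TEFamily("LINE", 3_000, 4, 8)),
        rdna_unit_length=9_000, rdna_array_copies_a=2, rdna_array_copies_b=2,
        insertions=(
            PlantedInsertion(0, 300_000, 200_000,
                             w_rdna=0.3, w_te=0.3, w_random=0.4),
            PlantedInsertion(0, 700_000, 50_000,
                             w_rdna=0.4, w_te=0.0, w_random=0.6),
            PlantedInsertion(1, 200_000, 120_000,
                             w_rdna=0.5, w_te=0.0, w_random=0.5),
        ),
        inversions=(PlantedInversion(1, 500_000, 150_000),
                    PlantedInversion(1, 800_000, 60_000)),
    )


def structural_recovery(seed: int = 1) -> dict:
    """Detect the planted events and measure boundary/span errors (bp)."""
    cfg = structural_recovery_config(seed)
    genome_a, genome_b, _, _, truth = simulate_genome_pair(cfg)
    blocks = filter_blocks(anchor_align(genome_b, genome_a))
    regions = detect_specific_regions(
        genome_b, [blocks], min_region=STRUCTURAL_MIN_REGION,
        merge_gap=STRUCTURAL_MERGE_GAP)
    calls = detect_inversions(blocks, chain_gap=STRUCTURAL_CHAIN_GAP)

    ins_errors = []
    for ins in truth.insertions:
        errs = [max(abs(r.start - ins.start), abs(r.end - ins.end))
                for r in regions if r.seqid == ins.seqid]
        ins_errors.append(min(errs) if errs else float("inf"))
    inv_errors = []
    for inv in truth.inversions:
        errs = [max(abs(c.ref_start - inv.b_start),
                    abs(c.ref_end - inv.b_end))
                for c in calls if c.ref_seqid == inv.seqid]
        inv_errors.append(min(errs) if errs else float("inf"))
    return {
        "n_insertions": len(truth.insertions),
        "n_inversions": len(truth.inversions),
        "insertion_boundary_errors": ins_errors,
        "inversion_boundary_errors": inv_errors,
        "insertions_recovered": sum(e <= STRUCTURAL_MERGE_GAP
                                    for e in ins_errors),
        "inversions_recovered": sum(e <= STRUCTURAL_CHAIN_GAP
                                    for e in inv_errors),
        "n_regions_called": len(regions),
        "n_inversion_calls": len(calls),
    }


# ---------------------------------------------------------------------------
# Copy-number recovery: planted family copy counts {1, 5, 20, 50} at 20x
# ---------------------------------------------------------------------------

def cnv_recovery_config(seed: int) -> SimulationConfig:
    """Single 300-kb chromosome carrying repeat families of 1, 5, 20 and 50
    copies plus 15 single-copy genes; 20x single-end reads at 1% error."""
    return SimulationConfig(
        seed=seed, n_chromosomes=1, chrom_length=300_000,
        snp_divergence=0.0, n_genes=15, gene_length=1_000,
        te_library=(TEFamily("LTR_copia", 1_500, 1, 1),
                    TEFamily("LTR_gypsy", 2_000, 5, 5),
                    TEFamily("LINE", 1_500, 20, 20)),
        rdna_unit_length=3_000, rdna_array_copies_a=50,
        rdna_array_copies_b=50,
        coverage=20.0, read_length=100, read_error_rate=0.01,
    )


def cnv_recovery(seed: int = 1) -> dict:
    cfg = cnv_recovery_config(seed)
    genome_a, _, ann_a, _, truth = simulate_genome_pair(cfg)
    reads = simulate_reads(genome_a, cfg)
    df = cnv_from_annotations(genome_a, ann_a, reads)
    totals = df.groupby("family")["family_total"].first().to_dict()
    estimates = {fam: (counts["A"], totals.get(fam, 0.0))
                 for fam, counts in truth.family_copies.items()}
    rel_errors = {fam: abs(est - true) / true
                  for fam, (true, est) in estimates.items() if true > 1}
    abs_err_single = {fam: abs(est - true)
                      for fam, (true, est) in estimates.items()
                      if true == 1}

    # calibration self-test: the estimator applied to its own genes
    rec_by_id = {g.id: g for g in genome_a}
    genes = [SequenceRecord(f"g_{seqid}_{s}",
                            rec_by_id[seqid].residues[s:e])
             for seqid, s, e in truth.gene_intervals]
    depths = map_reads_depth(reads, genes)
    cal = calibrate_single_copy(list(depths.values()))
    self_median = float(np.median([d / cal for d in depths.values()]))
    return {
        "estimates": estimates,
        "max_rel_error": max(rel_errors.values()),
        "single_copy_abs_errors": abs_err_single,
        "calibration_self_median": self_median,
    }


# ---------------------------------------------------------------------------
# Neighbor-joining consistency on random additive matrices
# ---------------------------------------------------------------------------

def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random tree with branch lengths in [0.1, 1] and its additive
    distance matrix (the oracle is the generating tree itself)."""
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        rng=pyrandom.Random(int(rng.integers(2 ** 31))))
    try:
        tree.collapse_basal_bifurcation()
    except (AttributeError, ValueError):
        pass
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = float(rng.uniform(0.1, 1.0))
    tree.is_rooted = False
    taxa = sorted(t.label for t in tree.taxon_namespace)
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    mat = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(taxa):
        for j in range(i + 1, n_taxa):
            mat[i, j] = mat[j, i] = pdm.distance(tx[a], tx[taxa[j]])
    return tree, taxa, mat


def nj_consistency(seed: int = 1, n_matrices: int = 100,
                   max_taxa: int = 12) -> dict:
    """Topology recovery and path-length reproduction over random additive
    matrices."""
    rng = np.random.default_rng(seed)
    recovered = 0
    worst_path_error = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(4, max_taxa + 1))
        true_tree, taxa, mat = random_additive_tree(rng, n)
        est = neighbor_joining(DistanceMatrix(taxa, mat))
        if tree_bipartitions(est) == tree_bipartitions(true_tree):
            recovered += 1
        paths = tree_path_distances(est)
        for i in range(n):
            for j in range(i + 1, n):
                err = abs(paths[frozenset((taxa[i], taxa[j]))] - mat[i, j])
                worst_path_error = max(worst_path_error, err)
    return {
        "n_matrices": n_matrices,
        "topology_recovery_pct": 100.0 * recovered / n_matrices,
        "max_path_length_error": worst_path_error,
    }


# ---------------------------------------------------------------------------
# Region logic vs brute-force per-base counting
# ---------------------------------------------------------------------------

def region_oracle_fuzz(seed: int = 1, n_instances: int = 50) -> dict:
    """detect_specific_regions vs a per-base coverage array on random
    instances (chromosomes <= 100 kb)."""
    from .formats import AlignmentBlock
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_instances):
        L = int(rng.integers(5_000, 100_000))
        genome = [SequenceRecord("c", "A" * L)]
        block_sets, arrays = [], []
        for _c in range(int(rng.integers(1, 4))):
            ivs = []
            for _b in range(int(rng.integers(0, 10))):
                s = int(rng.integers(0, L - 1))
                e = int(min(L, s + rng.integers(1, L // 2)))
                if e > s:
                    ivs.append((s, e))
            block_sets.append([
                AlignmentBlock("c", s, e, "q", s, e, "forward", 99.0)
                for s, e in ivs])
            arr = np.zeros(L, dtype=bool)
            for s, e in ivs:
                arr[s:e] = True
            arrays.append(arr)
        min_region = int(rng.integers(1, 5_000))
        regions = detect_specific_regions(genome, block_sets,
                                          min_region=min_region, merge_gap=0)
        uncovered = np.all(~np.array(arrays), axis=0)
        expected, start = [], None
        for i in range(L + 1):
            if i < L and uncovered[i]:
                if start is None:
                    start = i
            elif start is not None:
                if i - start >= min_region:
                    expected.append((start, i))
                start = None
        if [(r.start, r.end) for r in regions] != expected:
            mismatches += 1
    return {"n_instances": n_instances, "mismatches": mismatches}


# ---------------------------------------------------------------------------
# Chi-square type-I calibration
# ---------------------------------------------------------------------------

def chi2_type1_calibration(seed: int = 1, n_tables: int = 5_000,
                           alpha: float = 0.05) -> dict:
    """Rejection rate at ``alpha`` over homogeneous 5 x 4 multinomial
    tables (row totals 200, shared cell probabilities)."""
    rng = np.random.default_rng(seed)
    p = np.array([0.4, 0.3, 0.2, 0.1])
    rejections = 0
    for _ in range(n_tables):
        table = rng.multinomial(200, p, size=5)
        _, _, pval = chi_square_homogeneity(table)
        rejections += pval < alpha
    return {"n_tables": n_tables, "alpha": alpha,
            "rejection_rate": rejections / n_tables}
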