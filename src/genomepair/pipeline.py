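"""End-to-end orchestration of the analysis stages on a TOML config.

Stages (each skippable): simulate -> align/filter -> regions + inversions ->
landscape -> cnv -> phylo -> gsize.  Every stage writes its table(s) into
the output directory and records its parameters (with default-vs-config
provenance) and seeds in ``summary.json``; identical config + seeds give
identical outputs.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import cnv as cnv_mod
from . import formats, landscape as land_mod, phylo as phylo_mod
from . import gsize as gsize_mod
from . import structural as struct_mod
from .simulate import (PlantedInsertion, PlantedInversion, SimulationConfig,
                       TEFamily, simulate_genome_pair, simulate_reads,
                       write_fastq)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


_DEFAULTS: dict[str, dict[str, Any]] = {
    "regions": {"k": 21, "min_block": 4000, "max_gap": 2000,
                "min_identity": 95.0, "min_len": 4000,
                "min_region": 1_000_000, "merge_gap": 50_000},
    "inversions": {"chain_gap": 100_000},
    "landscape": {"window": 100_000},
    "cnv": {"min_identity": 90.0, "k": 21, "max_mismatch_frac": 0.1},
    "phylo": {"bootstrap": 1000, "seed": 42, "prune_factor": 10.0},
    "gsize": {"standard_1c": gsize_mod.DEFAULT_STANDARD_1C_PG,
              "n_perm": 10_000, "seed": 0},
}


def _params(config: Mapping, stage: str) -> tuple[dict, dict]:
    """Merge stage defaults with config overrides; report provenance."""
    merged = dict(_DEFAULTS.get(stage, {}))
    prov = {k: "default" for k in merged}
    for k, v in config.get(stage, {}).items():
        merged[k] = v
        prov[k] = "config"
    return merged, prov


def _sim_config(section: Mapping) -> SimulationConfig:
    kwargs = dict(section)
    if "te_library" in kwargs:
        kwargs["te_library"] = tuple(
            TEFamily(*row) for row in kwargs["te_library"])
    if "insertions" in kwargs:
        kwargs["insertions"] = tuple(
            PlantedInsertion(*row) for row in kwargs["insertions"])
    if "inversions" in kwargs:
        kwargs["inversions"] = tuple(
            PlantedInversion(*row) for row in kwargs["inversions"])
    return SimulationConfig(**kwargs)


def run_pipeline(config: Mapping | str | Path) -> Path:
    """Run the configured stages; returns the report directory."""
    if not isinstance(config, Mapping):
        with open(config, "rb") as fh:
            config = tomllib.load(fh)
    outdir = Path(config.get("output", {}).get("dir", "genomepair_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"stages": {}, "outputs": []}

    def record(stage: str, params: dict, prov: dict, outputs: list[str]):
        summary["stages"][stage] = {
            "parameters": params,
            "provenance": prov,
            "outputs": outputs,
        }
        summary["outputs"].extend(outputs)

    genome_a = genome_b = ann_a = ann_b = reads = truth = None

    # ---------------- simulate ----------------
    if "simulate" in config:
        try:
            sim_cfg = _sim_config(config["simulate"])
            genome_a, genome_b, ann_a, ann_b, truth = \
                simulate_genome_pair(sim_cfg)
            reads = simulate_reads(genome_b, sim_cfg)
            formats.write_fasta(genome_a, outdir / "genome_A.fa")
            formats.write_fasta(genome_b, outdir / "genome_B.fa")
            formats.write_gff3(ann_a, outdir / "genome_A.gff3")
            formats.write_gff3(ann_b, outdir / "genome_B.gff3")
            write_fastq(reads, outdir / "reads_B.fastq")
            truth.write_tsv(outdir / "truth.tsv")
            record("simulate", {"seed": sim_cfg.seed,
                                "n_chromosomes": sim_cfg.n_chromosomes,
                                "chrom_length": sim_cfg.chrom_length,
                                "coverage": sim_cfg.coverage},
                   {"seed": "config"},
                   ["genome_A.fa", "genome_B.fa", "genome_A.gff3",
                    "genome_B.gff3", "reads_B.fastq", "truth.tsv"])
        except Exception as exc:
            raise StageError(f"simulate stage failed: {exc}") from exc

    # ---------------- inputs from files when not simulating ----------------
    if genome_a is None and "inputs" in config:
        ins = config["inputs"]
        if "ref_fasta" in ins:
            genome_b = formats.read_fasta(ins["ref_fasta"])
        if "cmp_fasta" in ins:
            genome_a = formats.read_fasta(ins["cmp_fasta"])
        if "ref_gff" in ins:
            ann_b = formats.read_gff3(ins["ref_gff"])
        if "reads" in ins:
            from .simulate import read_fastq
            reads = read_fastq(ins["reads"])

    blocks = None
    # ---------------- regions + inversions ----------------
    if config.get("regions", {}).get("enabled", True) \
            and genome_b is not None and genome_a is not None:
        try:
            p, prov = _params(config, "regions")
            blocks = struct_mod.anchor_align(
                genome_b, genome_a, k=p["k"], min_block=p["min_block"],
                max_gap=p["max_gap"])
            filtered = struct_mod.filter_blocks(
                blocks, min_identity=p["min_identity"], min_len=p["min_len"])
            formats.write_alignment_blocks(filtered, outdir / "blocks.tsv")
            regions = struct_mod.detect_specific_regions(
                genome_b, [filtered], min_region=p["min_region"],
                merge_gap=p["merge_gap"])
            formats.write_bed([(r.seqid, r.start, r.end) for r in regions],
                              outdir / "regions.bed")
            outputs = ["blocks.tsv", "regions.bed"]
            if ann_b is not None and regions:
                summaries = [struct_mod.summarize_region(r, genome_b, ann_b)
                             for r in regions]
                struct_mod.summaries_to_frame(summaries).to_csv(
                    outdir / "region_table.tsv", sep="\t", index=False)
                outputs.append("region_table.tsv")
            record("regions", p, prov, outputs)

            pi, provi = _params(config, "inversions")
            calls = struct_mod.detect_inversions(
                filtered, chain_gap=pi["chain_gap"])
            pd.DataFrame([vars(c) for c in calls]).to_csv(
                outdir / "inversions.tsv", sep="\t", index=False)
            record("inversions", pi, provi, ["inversions.tsv"])
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"regions stage failed: {exc}") from exc

    # ---------------- landscape ----------------
    if config.get("landscape", {}).get("enabled", True) and ann_b is not None \
            and genome_b is not None:
        try:
            p, prov = _params(config, "landscape")
            lengths = {g.id: len(g) for g in genome_b}
            dens = land_mod.compute_density_tracks(
                ann_b, lengths, window=p["window"])
            dens.to_csv(outdir / "density.tsv", sep="\t", index=False)
            prop = land_mod.te_order_proportions(ann_b, lengths)
            prop.to_csv(outdir / "proportions.tsv", sep="\t")
            record("landscape", p, prov, ["density.tsv", "proportions.tsv"])
        except Exception as exc:
            raise StageError(f"landscape stage failed: {exc}") from exc

    # ---------------- cnv ----------------
    if config.get("cnv", {}).get("enabled", True) and reads is not None \
            and ann_b is not None and genome_b is not None:
        try:
            p, prov = _params(config, "cnv")
            df = cnv_from_annotations(
                genome_b, ann_b, reads, min_identity=p["min_identity"],
                k=p["k"], max_mismatch_frac=p["max_mismatch_frac"])
            df.to_csv(outdir / "cnv.tsv", sep="\t", index=False)
            record("cnv", p, prov, ["cnv.tsv"])
        except Exception as exc:
            raise StageError(f"cnv stage failed: {exc}") from exc

    # ---------------- phylo ----------------
    if "phylo" in config and "msa" in config.get("phylo", {}):
        try:
            p, prov = _params(config, "phylo")
            records = formats.read_fasta(config["phylo"]["msa"])
            msa = phylo_mod.MultipleAlignment.from_records(records)
            trimmed = phylo_mod.trim_alignment(msa)
            tree = phylo_mod.bootstrap_support(
                trimmed, n_reps=p["bootstrap"], seed=p["seed"])
            _, tree, removed = phylo_mod.prune_long_branches(
                tree, trimmed, factor=p["prune_factor"])
            (outdir / "tree.nwk").write_text(formats.write_newick(tree) + "\n")
            p["removed_taxa"] = removed
            record("phylo", p, prov, ["tree.nwk"])
        except Exception as exc:
            raise StageError(f"phylo stage failed: {exc}") from exc

    # ---------------- gsize ----------------
    if "gsize" in config and "peaks" in config.get("gsize", {}):
        try:
            p, prov = _params(config, "gsize")
            peaks = pd.read_csv(config["gsize"]["peaks"])
            samples = [
                gsize_mod.FlowSample(row["accession"], int(row["replicate"]),
                                     float(row["sample_g1_mean"]),
                                     float(row["standard_g1_mean"]))
                for _, row in peaks.iterrows()]
            df = gsize_mod.size_report(samples,
                                       standard_1c_pg=p["standard_1c"])
            df.to_csv(outdir / "sizes.tsv", sep="\t", index=False)
            groups = {a: g["c1_pg"].tolist()
                      for a, g in df.groupby("accession")}
            outputs = ["sizes.tsv"]
            if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
                an = gsize_mod.anova_oneway(groups)
                letters = gsize_mod.tukey_groups(
                    groups, n_perm=p["n_perm"], seed=p["seed"])
                p["anova"] = {"F": an.F, "df_between": an.df_between,
                              "df_within": an.df_within, "p": an.p}
                p["tukey_letters"] = letters
            record("gsize", p, prov, outputs)
        except Exception as exc:
            raise StageError(f"gsize stage failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return outdir


def cnv_from_annotations(genome, annotations, reads,
                         min_identity: float = 90.0, k: int = 21,
                         max_mismatch_frac: float = 0.1) -> pd.DataFrame:
    """Copy-number table for the repeat families annotated on a genome.

    Repeat copies are extracted from the genome by annotation interval,
    clustered per family, collapsed to consensus sequences, and quantified
    against the read set with single-copy-gene calibration.
    """
    by_class: dict[str, list] = {}
    gene_seqs = []
    recs = {g.id: g for g in genome}
    for i, a in enumerate(annotations):
        cls = formats.classify_feature(a.feature_type)
        s, e = a.interval()
        seq = recs[a.seqid].residues[s:e]
        if a.strand == "-":
            seq = formats.reverse_complement(seq)
        rec = formats.SequenceRecord(f"{cls}_{a.seqid}_{s}_{i}", seq)
        if cls == formats.GENE_CLASS:
            gene_seqs.append(rec)
        elif cls in formats.TE_CLASSES or cls in formats.RDNA_CLASSES:
            by_class.setdefault(cls, []).append(rec)
    if not gene_seqs:
        raise ValueError("no single-copy gene annotations found")
    references: list[formats.SequenceRecord] = list(gene_seqs)
    families: dict[str, str] = {}
    for cls, members in sorted(by_class.items()):
        clusters = cnv_mod.cluster_sequences(members,
                                             min_identity=min_identity)
        for ci, cl in enumerate(clusters):
            cons = cnv_mod.build_consensus(cl, f"{cls}_c{ci}")
            references.append(cons)
            families[cons.id] = cls
    depths = cnv_mod.map_reads_depth(reads, references, k=k,
                                     max_mismatch_frac=max_mismatch_frac)
    calibration = cnv_mod.calibrate_single_copy(
        [depths[g.id] for g in gene_seqs])
    repeat_depths = {cid: depths[cid] for cid in families}
    estimates = cnv_mod.estimate_family_copy_numbers(
        repeat_depths, families, calibration)
    return cnv_mod.estimates_to_frame(estimates)
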