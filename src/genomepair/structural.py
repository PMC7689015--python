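"""Genome-pair structural comparison: anchor alignment, block filtering,
genome-specific region and inversion calling, and region summary tables.

The aligner is a desk-scale whole-genome comparison: unique exact k-mer
anchors (both strands) chained into collinear ungapped runs, with percent
identity computed by direct column comparison over the chained span.  Users
with real MUMmer show-coords tables can load them through
:func:`genomepair.formats.read_alignment_blocks` instead.

A region of the reference is "specific" when no comparator genome covers it
with any filtered alignment block: the complement of the block-coverage
union, intersected across all comparators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (Annotation, AlignmentBlock, SequenceRecord,
                      classify_feature, reverse_complement,
                      GENE_CLASS, RDNA_CLASSES, TE_CLASSES)
from .intervals import (complement_intervals, intersect_intervals,
                        merge_intervals, overlap)


@dataclass
class SpecificRegion:
    """An interval of the reference with no orthologous match in any
    comparator genome."""
    seqid: str
    start: int
    end: int
    label: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class InversionCall:
    ref_seqid: str
    ref_start: int
    ref_end: int
    qry_seqid: str
    qry_start: int
    qry_end: int
    n_blocks: int


@dataclass
class RegionSummary:
    """One row of a region report: composition of a genomic interval."""
    seqid: str
    start: int
    end: int
    length_bp: int
    pct_n: float
    pct_gc: float
    n_genes: int
    cum_gene_len_bp: int
    n_tes: int
    cum_te_len_bp: int
    n_rdna: int
    cum_rdna_len_bp: int


# ---------------------------------------------------------------------------
# Anchor alignment
# ---------------------------------------------------------------------------

def _seq_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _unique_kmer_index(seq: str, k: int) -> dict[str, int]:
    """Positions of k-mers occurring exactly once (N-containing skipped)."""
    index: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in dup:
            continue
        if km in index:
            del index[km]
            dup.add(km)
        elif "N" not in km:
            index[km] = i
    return index


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    return 100.0 * float(np.count_nonzero(a == b)) / a.size


def anchor_align(ref_genome: Sequence[SequenceRecord],
                 qry_genome: Sequence[SequenceRecord],
                 k: int = 21,
                 min_block: int = 4_000,
                 max_gap: int = 2_000) -> list[AlignmentBlock]:
    """Anchor-based pairwise genome comparison.

    Unique exact ``k``-mer matches between each reference and query
    chromosome (both strands) are chained along diagonals: consecutive
    anchors on the same (anti-)diagonal within ``max_gap`` on the reference
    form one ungapped run.  Runs spanning at least ``min_block`` on the
    reference become :class:`AlignmentBlock` records with percent identity
    from direct column comparison.
    """
    if k < 15:
        raise ValueError("k must be >= 15")
    blocks: list[AlignmentBlock] = []
    qry_indexes = [(_unique_kmer_index(q.residues, k), q) for q in qry_genome]
    for ref in ref_genome:
        ref_index = _unique_kmer_index(ref.residues, k)
        ref_u8 = _seq_u8(ref.residues)
        for q_index, qry in qry_indexes:
            qry_u8 = _seq_u8(qry.residues)
            fwd: dict[int, list[tuple[int, int]]] = {}
            rev: dict[int, list[tuple[int, int]]] = {}
            for km, i in ref_index.items():
                j = q_index.get(km)
                if j is not None:
                    fwd.setdefault(j - i, []).append((i, j))
                j = q_index.get(reverse_complement(km))
                if j is not None:
                    rev.setdefault(i + j, []).append((i, j))
            for diag, anchors in fwd.items():
                anchors.sort()
                run = [anchors[0]]
                for a in anchors[1:]:
                    if a[0] - run[-1][0] <= max_gap:
                        run.append(a)
                    else:
                        _emit_run(blocks, run, k, min_block, "forward",
                                  ref, qry, ref_u8, qry_u8)
                        run = [a]
                _emit_run(blocks, run, k, min_block, "forward",
                          ref, qry, ref_u8, qry_u8)
            for anti, anchors in rev.items():
                anchors.sort()
                run = [anchors[0]]
                for a in anchors[1:]:
                    if a[0] - run[-1][0] <= max_gap:
                        run.append(a)
                    else:
                        _emit_run(blocks, run, k, min_block, "reverse",
                                  ref, qry, ref_u8, qry_u8)
                        run = [a]
                _emit_run(blocks, run, k, min_block, "reverse",
                          ref, qry, ref_u8, qry_u8)
    blocks.sort(key=lambda b: (b.ref_seqid, b.ref_start, b.qry_seqid,
                               b.qry_start))
    return blocks


def _emit_run(blocks: list[AlignmentBlock], run: list[tuple[int, int]],
              k: int, min_block: int, orientation: str,
              ref: SequenceRecord, qry: SequenceRecord,
              ref_u8: np.ndarray, qry_u8: np.ndarray) -> None:
    rs, re_ = run[0][0], run[-1][0] + k
    if re_ - rs < min_block:
        return
    if orientation == "forward":
        qs, qe = run[0][1], run[-1][1] + k
        ident = _identity(ref_u8[rs:re_], qry_u8[qs:qe])
    else:
        # anti-diagonal: qry start decreases as ref start increases
        qs, qe = run[-1][1], run[0][1] + k
        qspan = reverse_complement(qry.residues[qs:qe])
        ident = _identity(ref_u8[rs:re_], _seq_u8(qspan))
    blocks.append(AlignmentBlock(
        ref_seqid=ref.id, ref_start=rs, ref_end=re_,
        qry_seqid=qry.id, qry_start=qs, qry_end=qe,
        orientation=orientation, percent_identity=round(ident, 2)))


# ---------------------------------------------------------------------------
# Filtering and detection
# ---------------------------------------------------------------------------

def filter_blocks(blocks: Iterable[AlignmentBlock],
                  min_identity: float = 95.0,
                  min_len: int = 4_000) -> list[AlignmentBlock]:
    """Keep blocks with identity >= ``min_identity`` and reference span
    >= ``min_len`` (the classic -id 95 / -l 4000 regime); order preserved."""
    return [b for b in blocks
            if b.percent_identity >= min_identity and b.ref_span >= min_len]


def detect_specific_regions(ref_genome: Sequence[SequenceRecord],
                            block_sets: Sequence[Sequence[AlignmentBlock]],
                            min_region: int = 1_000_000,
                            merge_gap: int = 50_000) -> list[SpecificRegion]:
    """Reference intervals uncovered by every comparator's blocks.

    Per chromosome: union of covered reference intervals per comparator,
    complement within the chromosome, intersection of the complements over
    all comparators, then merging of intervals separated by covered
    stretches shorter than ``merge_gap``; merged intervals of at least
    ``min_region`` bp are reported.
    """
    lengths = {g.id: len(g) for g in ref_genome}
    for bset in block_sets:
        for b in bset:
            if b.ref_seqid not in lengths:
                raise ValueError(
                    f"block {b.ref_seqid}:{b.ref_start}-{b.ref_end} refers "
                    "to an unknown reference sequence")
    regions: list[SpecificRegion] = []
    for g in ref_genome:
        L = lengths[g.id]
        uncovered = None
        for bset in block_sets:
            cov = [(b.ref_start, b.ref_end) for b in bset
                   if b.ref_seqid == g.id]
            unc = complement_intervals(cov, L)
            uncovered = unc if uncovered is None \
                else intersect_intervals(uncovered, unc)
        if uncovered is None:
            uncovered = [(0, L)]
        for s, e in merge_intervals(uncovered, gap=merge_gap):
            if e - s >= min_region:
                regions.append(SpecificRegion(g.id, s, e))
    return regions


def detect_inversions(blocks: Iterable[AlignmentBlock],
                      chain_gap: int = 100_000) -> list[InversionCall]:
    """Chain reverse-orientation blocks into inversion calls.

    Blocks on the same (ref, qry) pair are sorted by reference start and
    chained while consecutive blocks lie within ``chain_gap`` on both
    genomes and query coordinates decrease as reference coordinates
    increase.  Isolated reverse blocks are reported as single-block calls.
    """
    groups: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        if b.orientation == "reverse":
            groups.setdefault((b.ref_seqid, b.qry_seqid), []).append(b)
    calls: list[InversionCall] = []
    for (_rid, _qid), bs in sorted(groups.items()):
        bs.sort(key=lambda b: b.ref_start)
        chain = [bs[0]]
        for b in bs[1:]:
            prev = chain[-1]
            if (b.ref_start - prev.ref_end <= chain_gap
                    and b.qry_end <= prev.qry_start + 1
                    and prev.qry_start - b.qry_end <= chain_gap):
                chain.append(b)
            else:
                calls.append(_chain_to_call(chain))
                chain = [b]
        calls.append(_chain_to_call(chain))
    calls.sort(key=lambda c: (c.ref_seqid, c.ref_start))
    return calls


def _chain_to_call(chain: list[AlignmentBlock]) -> InversionCall:
    return InversionCall(
        ref_seqid=chain[0].ref_seqid,
        ref_start=min(b.ref_start for b in chain),
        ref_end=max(b.ref_end for b in chain),
        qry_seqid=chain[0].qry_seqid,
        qry_start=min(b.qry_start for b in chain),
        qry_end=max(b.qry_end for b in chain),
        n_blocks=len(chain))


# ---------------------------------------------------------------------------
# Region summaries
# ---------------------------------------------------------------------------

def summarize_region(region: tuple[str, int, int] | SpecificRegion,
                     genome: Sequence[SequenceRecord] | SequenceRecord,
                     annotations: Iterable[Annotation]) -> RegionSummary:
    """Composition summary of one interval: N%, GC% (all-bases denominator,
    N included), and per-class feature counts and region-clipped cumulative
    lengths.  A feature counts if it overlaps the region by >= 1 bp."""
    if isinstance(region, SpecificRegion):
        seqid, start, end = region.seqid, region.start, region.end
    else:
        seqid, start, end = region
    if isinstance(genome, SequenceRecord):
        records = {genome.id: genome}
    else:
        records = {g.id: g for g in genome}
    if seqid not in records:
        raise ValueError(f"unknown sequence {seqid!r}")
    rec = records[seqid]
    if not (0 <= start < end <= len(rec)):
        raise ValueError(
            f"region {seqid}:{start}-{end} out of bounds (length {len(rec)})")
    span = rec.residues[start:end]
    length = end - start
    n_count = span.count("N")
    gc_count = span.count("G") + span.count("C")
    counts = {"gene": 0, "te": 0, "rdna": 0}
    cums = {"gene": 0, "te": 0, "rdna": 0}
    for a in annotations:
        if a.seqid != seqid:
            continue
        ov = overlap(a.interval(), (start, end))
        if ov < 1:
            continue
        cls = classify_feature(a.feature_type)
        if cls == GENE_CLASS:
            key = "gene"
        elif cls in TE_CLASSES:
            key = "te"
        elif cls in RDNA_CLASSES:
            key = "rdna"
        else:
            continue
        counts[key] += 1
        cums[key] += ov
    return RegionSummary(
        seqid=seqid, start=start, end=end, length_bp=length,
        pct_n=100.0 * n_count / length,
        pct_gc=100.0 * gc_count / length,
        n_genes=counts["gene"], cum_gene_len_bp=cums["gene"],
        n_tes=counts["te"], cum_te_len_bp=cums["te"],
        n_rdna=counts["rdna"], cum_rdna_len_bp=cums["rdna"])


#: reporting precision classes for summary columns
BP_COLUMNS = ("length_bp", "cum_gene_len_bp", "cum_te_len_bp",
              "cum_rdna_len_bp")
COUNT_COLUMNS = ("n_genes", "n_tes", "n_rdna")
PERCENT_COLUMNS = ("pct_n", "pct_gc")


def summarize_table(rows: Sequence[RegionSummary] | pd.DataFrame
                    ) -> dict[str, dict[str, float]]:
    """Column statistics (sum, mean, median) over a region-summary table.

    Reporting conventions: bp-valued means/medians are truncated toward
    zero to integer bp; count columns are reported to 2 decimals; percent
    columns are rounded to 2 decimals.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame([vars(r) for r in rows])
    if len(df) == 0:
        raise ValueError("summarize_table requires at least one row")
    out: dict[str, dict[str, float]] = {}
    for col in df.columns:
        if col in BP_COLUMNS:
            out[col] = {
                "sum": int(df[col].sum()),
                "mean": math.trunc(float(df[col].mean())),
                "median": math.trunc(float(df[col].median())),
            }
        elif col in COUNT_COLUMNS:
            out[col] = {
                "sum": int(df[col].sum()),
                "mean": round(float(df[col].mean()), 2),
                "median": round(float(df[col].median()), 2),
            }
        elif col in PERCENT_COLUMNS:
            out[col] = {
                "sum": round(float(df[col].sum()), 2),
                "mean": round(float(df[col].mean()), 2),
                "median": round(float(df[col].median()), 2),
            }
    return out


def summaries_to_frame(rows: Sequence[RegionSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])
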