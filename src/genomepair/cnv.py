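"""Read-depth copy-number estimation of repeat families, calibrated on
single-copy genes.

Candidate repeat copies are clustered by global-alignment identity
(single linkage, > 90% by default), a majority-rule consensus is built per
cluster, shotgun reads are assigned to the consensus and calibration
references with a seed-and-extend mini-mapper, and copy number is the ratio
of a consensus' mean read depth to the median mean depth over single-copy
genes (the depth corresponding to copy number 1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .formats import SequenceRecord, reverse_complement

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


# ---------------------------------------------------------------------------
# Identity and clustering
# ---------------------------------------------------------------------------

def pairwise_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Percent identity (matches / alignment length) from a global alignment
    with unit match/mismatch/gap costs."""
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(sa, sb, mode="NW", task="path")
    matches = alen = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        alen += n
        if op == "=":
            matches += n
    return 100.0 * matches / alen


@dataclass
class SequenceCluster:
    """A single-linkage identity cluster of repeat copies."""
    members: list[SequenceRecord]
    consensus: SequenceRecord | None = None

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


def cluster_sequences(seqs: Sequence[SequenceRecord],
                      min_identity: float = 90.0) -> list[SequenceCluster]:
    """Single-linkage components of the graph with an edge wherever the
    pairwise identity exceeds ``min_identity`` (strictly)."""
    if not seqs:
        raise ValueError("need at least one sequence")
    n = len(seqs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(seqs[i], seqs[j]) > min_identity:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    comps: dict[int, list[SequenceRecord]] = {}
    for i, s in enumerate(seqs):
        comps.setdefault(find(i), []).append(s)
    return [SequenceCluster(members=m)
            for _, m in sorted(comps.items())]


def build_consensus(cluster: SequenceCluster,
                    consensus_id: str | None = None) -> SequenceRecord:
    """Majority-rule consensus via center-star alignment.

    The center is the member with the highest mean identity to the others;
    every other member is globally aligned to it, columns are taken over
    center positions (insertions relative to the center are discarded),
    columns with more than 50% gaps are dropped, and residue ties break
    alphabetically.
    """
    members = cluster.members
    if not members:
        raise ValueError("empty cluster")
    cid = consensus_id or f"consensus_{members[0].id}"
    if len(members) == 1:
        cons = SequenceRecord(cid, members[0].residues)
        cluster.consensus = cons
        return cons
    n = len(members)
    mean_ident = np.zeros(n)
    for i in range(n):
        idents = [pairwise_identity(members[i], members[j])
                  for j in range(n) if j != i]
        mean_ident[i] = float(np.mean(idents))
    center_i = int(np.argmax(mean_ident))
    center = members[center_i]
    clen = len(center.residues)
    # columns[pos] -> residues observed at that center position ('-' for gap)
    columns = [[] for _ in range(clen)]
    for pos, ch in enumerate(center.residues):
        columns[pos].append(ch)
    for j, m in enumerate(members):
        if j == center_i:
            continue
        res = edlib.align(m.residues, center.residues, mode="NW", task="path")
        qi = ti = 0  # query = member, target = center
        for cnt, op in _CIGAR_RE.findall(res["cigar"]):
            cnt = int(cnt)
            if op in "=XM":
                for t in range(cnt):
                    columns[ti + t].append(m.residues[qi + t])
                qi += cnt
                ti += cnt
            elif op == "I":
                # consumes the query only: insertion relative to the center
                qi += cnt
            elif op == "D":
                # deletion in the member: gaps over center positions
                for t in range(cnt):
                    columns[ti + t].append("-")
                ti += cnt
    out = []
    for col in columns:
        gaps = col.count("-")
        if gaps * 2 > len(col):
            continue
        residues = [c for c in col if c != "-"]
        counts = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts.values())
        out.append(min(c for c, k in counts.items() if k == best))
    cons = SequenceRecord(cid, "".join(out))
    cluster.consensus = cons
    return cons


# ---------------------------------------------------------------------------
# Mini-mapper
# ---------------------------------------------------------------------------

def map_reads_depth(reads: Sequence[SequenceRecord],
                    references: Sequence[SequenceRecord],
                    k: int = 21,
                    max_mismatch_frac: float = 0.1) -> dict[str, float]:
    """Per-reference mean read depth from exact k-mer seeding plus ungapped
    extension (both strands).

    Each read is assigned to the reference(s) with the fewest mismatches
    over the aligned (reference-clipped) span, subject to the mismatch
    fraction cap; ties are split fractionally (1/n of the aligned bp to each
    of the n best references).  Mean depth = total aligned bp / reference
    length.
    """
    if not references:
        raise ValueError("empty reference set")
    if reads and k > min(len(r) for r in reads):
        raise ValueError("seed length k exceeds read length")
    ref_u8 = [np.frombuffer(r.residues.encode("ascii"), dtype=np.uint8)
              for r in references]
    index: dict[str, list[tuple[int, int]]] = {}
    for ri, ref in enumerate(references):
        seq = ref.residues
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            if "N" not in km:
                index.setdefault(km, []).append((ri, i))
    depth_bp = np.zeros(len(references))
    for read in reads:
        best = _assign_read(read.residues, ref_u8, index, k,
                            max_mismatch_frac)
        if not best:
            continue
        share = 1.0 / len(best)
        for ri, aligned in best.items():
            depth_bp[ri] += share * aligned
    return {references[ri].id: depth_bp[ri] / len(references[ri].residues)
            for ri in range(len(references))}


def _assign_read(seq: str, ref_u8: list[np.ndarray],
                 index: Mapping[str, list[tuple[int, int]]],
                 k: int, max_mismatch_frac: float) -> dict[int, int]:
    """Best references for one read: ``{ref_index: aligned_bp}`` over the
    minimal-mismatch candidates, or empty when nothing qualifies."""
    rl = len(seq)
    best_mm = None
    best: dict[int, int] = {}
    # dense seeding: a stride of k/3 keeps the chance that a read with a
    # few percent divergence misses every seed negligibly small
    stride = max(1, k // 3)
    for strand_seq in (seq, reverse_complement(seq)):
        read_u8 = np.frombuffer(strand_seq.encode("ascii"), dtype=np.uint8)
        seen: set[tuple[int, int]] = set()
        for p in range(0, rl - k + 1, stride):
            hits = index.get(strand_seq[p:p + k])
            if not hits:
                continue
            for ri, rpos in hits:
                offset = rpos - p
                key = (ri, offset)
                if key in seen:
                    continue
                seen.add(key)
                ref = ref_u8[ri]
                rs = max(0, offset)
                re_ = min(len(ref), offset + rl)
                aligned = re_ - rs
                if aligned < k:
                    continue
                mm = int(np.count_nonzero(
                    ref[rs:re_] != read_u8[rs - offset:re_ - offset]))
                if mm > max_mismatch_frac * aligned:
                    continue
                if best_mm is None or mm < best_mm:
                    best_mm = mm
                    best = {ri: aligned}
                elif mm == best_mm:
                    # keep the larger aligned span for a ref seen twice
                    best[ri] = max(best.get(ri, 0), aligned)
    return best


# ---------------------------------------------------------------------------
# Calibration and estimation
# ---------------------------------------------------------------------------

def calibrate_single_copy(gene_depths: Sequence[float]) -> float:
    """Median of per-gene mean depths: the depth of copy number 1."""
    if len(gene_depths) == 0:
        raise ValueError("need at least one single-copy gene depth")
    return float(np.median(np.asarray(gene_depths, dtype=float)))


def estimate_copy_number(mean_depth: float, calibration_depth: float) -> float:
    """Copy number = mean depth / single-copy calibration depth."""
    if calibration_depth <= 0:
        raise ValueError("calibration depth must be positive")
    return mean_depth / calibration_depth


@dataclass
class CopyNumberEstimate:
    consensus_id: str
    family: str
    mean_depth: float
    calibration_depth: float
    copy_number: float
    family_total: float


def estimate_family_copy_numbers(depths: Mapping[str, float],
                                 families: Mapping[str, str],
                                 calibration_depth: float
                                 ) -> list[CopyNumberEstimate]:
    """Per-consensus copy numbers plus per-family totals.

    ``depths`` maps consensus id to mean depth; ``families`` maps consensus
    id to its family label.
    """
    per = {cid: estimate_copy_number(d, calibration_depth)
           for cid, d in depths.items()}
    totals: dict[str, float] = {}
    for cid, cn in per.items():
        fam = families.get(cid, cid)
        totals[fam] = totals.get(fam, 0.0) + cn
    return [
        CopyNumberEstimate(
            consensus_id=cid, family=families.get(cid, cid),
            mean_depth=depths[cid], calibration_depth=calibration_depth,
            copy_number=round(per[cid], 1),
            family_total=round(totals[families.get(cid, cid)], 1))
        for cid in depths
    ]


def estimates_to_frame(estimates: Sequence[CopyNumberEstimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])
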