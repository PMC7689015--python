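"""Synthetic genome-pair generator with planted ground truth.

Emulates the study design of an intraspecific genome comparison: an
ancestral haploid genome (A) carrying single-copy genes, transposable-element
copies and a tandem 45S rDNA array, and a derived genome (B) that differs by
a uniform SNP overlay, planted large insertions (tandem rDNA units, TE copies
and random filler), and planted inversions.  Uniform-coverage single-end
shotgun reads with substitution errors can be drawn from either genome.

Every planted event is recorded in a :class:`TruthManifest`, the oracle used
by the acceptance suite.  Identical config + seed gives byte-identical
output.

The SNP overlay is applied before the structural events, so inserted and
inverted segments carry the same background divergence as the rest of the
genome (keeping alignment identity uniform across the genome).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .formats import Annotation, SequenceRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TEFamily:
    """A transposable-element family: one consensus, ``copies_a`` instances
    in genome A (inherited by B) and ``copies_b`` >= ``copies_a`` in B, the
    surplus planted inside the configured insertions."""
    family: str            # e.g. "LTR_gypsy", "LTR_copia", "LINE"
    consensus_length: int
    copies_a: int
    copies_b: int
    divergence: float = 0.02   # per-copy divergence from the consensus


@dataclass(frozen=True)
class PlantedInsertion:
    chrom: int            # chromosome index
    position: int         # insertion point on the ancestral coordinate
    length: int
    # composition weights over {rdna, te, random}; normalised internally
    w_rdna: float = 0.0
    w_te: float = 0.0
    w_random: float = 1.0


@dataclass(frozen=True)
class PlantedInversion:
    chrom: int
    start: int            # ancestral coordinates, 0-based half-open
    length: int


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    gc_content: float = 0.36
    snp_divergence: float = 0.02
    n_genes: int = 30
    gene_length: int = 1_000
    te_library: tuple[TEFamily, ...] = (
        TEFamily("LTR_gypsy", 5_000, 10, 10),
        TEFamily("LTR_copia", 4_000, 8, 8),
        TEFamily("LINE", 3_000, 6, 6),
    )
    rdna_unit_length: int = 9_000   # one 45S unit (18S-5.8S-26S + spacers)
    rdna_unit_divergence: float = 0.005
    rdna_array_copies_a: int = 5
    rdna_array_copies_b: int = 5
    insertions: tuple[PlantedInsertion, ...] = ()
    inversions: tuple[PlantedInversion, ...] = ()
    read_length: int = 100
    read_error_rate: float = 0.01
    coverage: float = 20.0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ConfigError("need at least one non-empty chromosome")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ConfigError("gc_content must lie in [0, 1]")
        for frac in (self.snp_divergence, self.read_error_rate):
            if not (0.0 <= frac <= 1.0):
                raise ConfigError("rates must lie in [0, 1]")
        for fam in self.te_library:
            if fam.copies_b < fam.copies_a:
                raise ConfigError(
                    f"family {fam.family}: copies_b < copies_a "
                    "(deletions are not modelled)")
        if self.rdna_array_copies_b < self.rdna_array_copies_a:
            raise ConfigError("rdna_array_copies_b < rdna_array_copies_a")
        events: dict[int, list[tuple[int, int, str]]] = {}
        for ins in self.insertions:
            if not (0 <= ins.chrom < self.n_chromosomes):
                raise ConfigError(f"insertion chromosome {ins.chrom} out of range")
            if not (0 <= ins.position <= self.chrom_length):
                raise ConfigError("insertion position outside chromosome")
            events.setdefault(ins.chrom, []).append(
                (ins.position, ins.position, "insertion"))
        for inv in self.inversions:
            if not (0 <= inv.chrom < self.n_chromosomes):
                raise ConfigError(f"inversion chromosome {inv.chrom} out of range")
            if inv.length < 2 or inv.start < 0 \
                    or inv.start + inv.length > self.chrom_length:
                raise ConfigError("inversion outside chromosome bounds")
            events.setdefault(inv.chrom, []).append(
                (inv.start, inv.start + inv.length, "inversion"))
        for chrom, evs in events.items():
            evs.sort()
            for (s1, e1, k1), (s2, e2, k2) in zip(evs, evs[1:]):
                if s2 < e1 or (s2 == e1 == s1):
                    raise ConfigError(
                        f"planted events overlap on chromosome {chrom}: "
                        f"{k1} [{s1},{e1}) and {k2} [{s2},{e2})")


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass
class TruthInsertion:
    genome: str           # always "B"
    seqid: str
    start: int            # final B coordinates, 0-based half-open
    end: int
    ancestral_position: int


@dataclass
class TruthInversion:
    seqid: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int


@dataclass
class TruthManifest:
    """Planted ground truth emitted alongside the genome pair."""
    insertions: list[TruthInsertion] = field(default_factory=list)
    inversions: list[TruthInversion] = field(default_factory=list)
    #: realised copy count per repeat family, per genome
    family_copies: dict[str, dict[str, int]] = field(default_factory=dict)
    #: (seqid, start, end) of single-copy genes in genome A coordinates
    gene_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tgenome\tseqid\tstart\tend\textra\n")
            for ins in self.insertions:
                fh.write(f"insertion\t{ins.genome}\t{ins.seqid}\t{ins.start}"
                         f"\t{ins.end}\tancestral_pos={ins.ancestral_position}\n")
            for inv in self.inversions:
                fh.write(f"inversion\tA\t{inv.seqid}\t{inv.a_start}"
                         f"\t{inv.a_end}\t.\n")
                fh.write(f"inversion\tB\t{inv.seqid}\t{inv.b_start}"
                         f"\t{inv.b_end}\t.\n")
            for fam, counts in self.family_copies.items():
                for genome, n in counts.items():
                    fh.write(f"copy_count\t{genome}\t.\t0\t0\t{fam}={n}\n")
            for seqid, s, e in self.gene_intervals:
                fh.write(f"gene\tA\t{seqid}\t{s}\t{e}\t.\n")


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Random uint8 base array with the requested GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    out = arr.copy()
    if rate <= 0.0 or out.size == 0:
        return out
    hit = np.nonzero(rng.random(out.size) < rate)[0]
    if hit.size:
        # shift by 1..3 positions in base space -> always a different base
        idx = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(idx + rng.integers(1, 4, size=hit.size)) % 4]
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return np.frombuffer(
        reverse_complement(_to_str(arr)).encode("ascii"), dtype=np.uint8
    ).copy()


def _sample_free_intervals(rng: np.random.Generator, length: int,
                           sizes: Sequence[int],
                           occupied: list[tuple[int, int]],
                           max_tries: int = 2000) -> list[tuple[int, int]]:
    """Sample non-overlapping placement intervals of the given sizes."""
    placed: list[tuple[int, int]] = []
    taken = sorted(occupied)
    for size in sizes:
        ok = False
        for _ in range(max_tries):
            s = int(rng.integers(0, max(1, length - size)))
            iv = (s, s + size)
            if all(iv[1] <= t[0] or iv[0] >= t[1] for t in taken):
                taken.append(iv)
                taken.sort()
                placed.append(iv)
                ok = True
                break
        if not ok:
            raise ConfigError(
                "could not place all features without overlap; "
                "reduce feature load or enlarge chromosomes")
    return placed


# ---------------------------------------------------------------------------
# Genome-pair simulation
# ---------------------------------------------------------------------------

def _chrom_name(i: int) -> str:
    return f"A{i + 1:02d}"


def simulate_genome_pair(config: SimulationConfig) -> tuple[
        list[SequenceRecord], list[SequenceRecord],
        list[Annotation], list[Annotation], TruthManifest]:
    """Generate the diverged genome pair, annotations and truth manifest.

    Returns ``(genome_A, genome_B, annotations_A, annotations_B, truth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = TruthManifest()

    # --- family consensus sequences and the base rDNA unit -----------------
    consensi = {
        fam.family: _random_seq(rng, fam.consensus_length, config.gc_content)
        for fam in config.te_library
    }
    rdna_unit = _random_seq(rng, config.rdna_unit_length, config.gc_content)

    # --- ancestral genome A -------------------------------------------------
    genome_a: list[SequenceRecord] = []
    ann_a: list[Annotation] = []
    chrom_arrays: list[np.ndarray] = []
    # per-chromosome list of (start, end) occupied by features or planted
    # structural events (events kept feature-free so they stay clean)
    for ci in range(config.n_chromosomes):
        chrom_arrays.append(_random_seq(rng, config.chrom_length,
                                        config.gc_content))

    # distribute genes and TE copies across chromosomes; the rDNA array and
    # planted events reserve space first
    reserved: dict[int, list[tuple[int, int]]] = {
        ci: [] for ci in range(config.n_chromosomes)}
    for ins in config.insertions:
        reserved[ins.chrom].append((max(0, ins.position - 1),
                                    min(config.chrom_length, ins.position + 1)))
    for inv in config.inversions:
        reserved[inv.chrom].append((inv.start, inv.start + inv.length))

    array_len = config.rdna_array_copies_a * config.rdna_unit_length
    rdna_chrom = 0
    rdna_array_iv: tuple[int, int] | None = None
    if config.rdna_array_copies_a > 0:
        rdna_array_iv = _sample_free_intervals(
            rng, config.chrom_length, [array_len], reserved[rdna_chrom])[0]
        reserved[rdna_chrom].append(rdna_array_iv)

    # genes: spread round-robin over chromosomes
    gene_chroms = [i % config.n_chromosomes for i in range(config.n_genes)]
    gene_ivs: list[tuple[int, int, int]] = []   # (chrom, start, end)
    for ci in range(config.n_chromosomes):
        sizes = [config.gene_length] * gene_chroms.count(ci)
        for iv in _sample_free_intervals(rng, config.chrom_length, sizes,
                                         reserved[ci]):
            reserved[ci].append(iv)
            gene_ivs.append((ci, iv[0], iv[1]))

    # TE copies of each family
    te_copies_a: list[tuple[int, int, int, str]] = []  # (chrom, s, e, family)
    for fam in config.te_library:
        for _ in range(fam.copies_a):
            ci = int(rng.integers(0, config.n_chromosomes))
            iv = _sample_free_intervals(
                rng, config.chrom_length, [fam.consensus_length],
                reserved[ci])[0]
            reserved[ci].append(iv)
            copy_seq = _mutate(consensi[fam.family], fam.divergence, rng)
            chrom_arrays[ci][iv[0]:iv[1]] = copy_seq
            te_copies_a.append((ci, iv[0], iv[1], fam.family))

    # write the rDNA array content
    if rdna_array_iv is not None:
        s0 = rdna_array_iv[0]
        for u in range(config.rdna_array_copies_a):
            unit = _mutate(rdna_unit, config.rdna_unit_divergence, rng)
            us = s0 + u * config.rdna_unit_length
            chrom_arrays[rdna_chrom][us:us + config.rdna_unit_length] = unit
            ann_a.append(Annotation(
                _chrom_name(rdna_chrom), "sim", "rDNA_45S",
                us + 1, us + config.rdna_unit_length, strand="+",
                attributes={"ID": f"rdna_A_{u}"}))

    for ci, s, e in gene_ivs:
        ann_a.append(Annotation(_chrom_name(ci), "sim", "gene", s + 1, e,
                                strand="+",
                                attributes={"ID": f"gene_{ci}_{s}"}))
        truth.gene_intervals.append((_chrom_name(ci), s, e))
    for ci, s, e, fam in te_copies_a:
        ann_a.append(Annotation(_chrom_name(ci), "sim", fam, s + 1, e,
                                strand="+",
                                attributes={"ID": f"te_{fam}_{ci}_{s}"}))

    genome_a = [SequenceRecord(_chrom_name(ci), _to_str(chrom_arrays[ci]))
                for ci in range(config.n_chromosomes)]

    # --- genome B: SNP overlay, then inversions, then insertions ------------
    b_arrays = [_mutate(a, config.snp_divergence, rng) for a in chrom_arrays]
    ann_b: list[Annotation] = [replace(a) for a in ann_a]

    for inv in config.inversions:
        s, e = inv.start, inv.start + inv.length
        b_arrays[inv.chrom][s:e] = _revcomp_arr(b_arrays[inv.chrom][s:e])
        name = _chrom_name(inv.chrom)
        remapped: list[Annotation] = []
        for a in ann_b:
            if a.seqid != name:
                remapped.append(a)
                continue
            fs, fe = a.interval()
            if fe <= s or fs >= e:
                remapped.append(a)
            elif fs >= s and fe <= e:
                ns, ne = s + (e - fe), s + (e - fs)
                strand = {"+": "-", "-": "+", ".": "."}[a.strand]
                remapped.append(replace(a, start=ns + 1, end=ne,
                                        strand=strand))
            # else: feature straddles the breakpoint -> dropped from B
        ann_b = remapped
        truth.inversions.append(TruthInversion(name, s, e, s, e))

    # planned insertion events: user-configured plus the automatic rDNA
    # array extension when copies_b exceeds copies_a
    extra_te: list[str] = []
    for fam in config.te_library:
        extra_te.extend([fam.family] * (fam.copies_b - fam.copies_a))
    rng.shuffle(extra_te)  # type: ignore[arg-type]
    extra_te = list(extra_te)

    @dataclass
    class _Event:
        chrom: int
        position: int          # ancestral coordinate
        seq: np.ndarray
        anns: list[tuple[str, int, int]]   # (ftype, rel_start, rel_end)
        record: bool           # record in truth.insertions

    events: list[_Event] = []
    rdna_b_extra = config.rdna_array_copies_b - config.rdna_array_copies_a
    if rdna_b_extra > 0:
        if rdna_array_iv is None:
            raise ConfigError(
                "rdna_array_copies_b > 0 requires an array in genome A")
        parts, anns = [], []
        for u in range(rdna_b_extra):
            unit = _mutate(rdna_unit, config.rdna_unit_divergence, rng)
            anns.append(("rDNA_45S", u * config.rdna_unit_length,
                         (u + 1) * config.rdna_unit_length))
            parts.append(unit)
        events.append(_Event(rdna_chrom, rdna_array_iv[1],
                             np.concatenate(parts), anns, True))

    for ins in config.insertions:
        w = np.array([max(ins.w_rdna, 0.0), max(ins.w_te, 0.0),
                      max(ins.w_random, 0.0)], dtype=float)
        if w.sum() <= 0:
            raise ConfigError("insertion composition weights sum to zero")
        w = w / w.sum()
        parts: list[np.ndarray] = []
        anns = []
        pos = 0
        n_units = int(w[0] * ins.length // config.rdna_unit_length)
        for _ in range(n_units):
            unit = _mutate(rdna_unit, config.rdna_unit_divergence, rng)
            parts.append(unit)
            anns.append(("rDNA_45S", pos, pos + config.rdna_unit_length))
            pos += config.rdna_unit_length
        te_budget = int(w[1] * ins.length)
        te_bp = 0
        fam_by_name = {f.family: f for f in config.te_library}
        while extra_te:
            fam = fam_by_name[extra_te[0]]
            if te_bp + fam.consensus_length > te_budget \
                    or pos + fam.consensus_length > ins.length:
                break
            extra_te.pop(0)
            copy_seq = _mutate(consensi[fam.family], fam.divergence, rng)
            parts.append(copy_seq)
            anns.append((fam.family, pos, pos + fam.consensus_length))
            pos += fam.consensus_length
            te_bp += fam.consensus_length
        filler = ins.length - pos
        if filler > 0:
            parts.append(_random_seq(rng, filler, config.gc_content))
        seq = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        events.append(_Event(ins.chrom, ins.position, seq, anns, True))

    if extra_te:
        raise ConfigError(
            f"{len(extra_te)} surplus TE copies (copies_b > copies_a) could "
            "not be placed: configure insertions with sufficient TE budget")

    # splice events per chromosome in ascending ancestral order
    for ci in range(config.n_chromosomes):
        evs = sorted((e for e in events if e.chrom == ci),
                     key=lambda e: e.position)
        offset = 0
        name = _chrom_name(ci)
        for ev in evs:
            b_pos = ev.position + offset
            arr = b_arrays[ci]
            b_arrays[ci] = np.concatenate([arr[:b_pos], ev.seq, arr[b_pos:]])
            L = ev.seq.size
            # shift downstream annotations and previously recorded events
            for a in ann_b:
                if a.seqid == name and a.start - 1 >= b_pos:
                    a.start += L
                    a.end += L
            for inv in truth.inversions:
                if inv.seqid == name and inv.b_start >= b_pos:
                    inv.b_start += L
                    inv.b_end += L
            for prev in truth.insertions:
                if prev.seqid == name and prev.start >= b_pos:
                    prev.start += L
                    prev.end += L
            for ftype, rs, re_ in ev.anns:
                ann_b.append(Annotation(
                    name, "sim", ftype, b_pos + rs + 1, b_pos + re_,
                    strand="+",
                    attributes={"ID": f"ins_{ftype}_{ci}_{b_pos + rs}"}))
            if ev.record and L > 0:
                truth.insertions.append(TruthInsertion(
                    "B", name, b_pos, b_pos + L, ev.position))
            offset += L

    genome_b = [SequenceRecord(_chrom_name(ci), _to_str(b_arrays[ci]))
                for ci in range(config.n_chromosomes)]

    # realised family copy counts
    for fam in config.te_library:
        truth.family_copies[fam.family] = {
            "A": sum(1 for a in ann_a if a.feature_type == fam.family),
            "B": sum(1 for a in ann_b if a.feature_type == fam.family),
        }
    truth.family_copies["rDNA_45S"] = {
        "A": sum(1 for a in ann_a if a.feature_type == "rDNA_45S"),
        "B": sum(1 for a in ann_b if a.feature_type == "rDNA_45S"),
    }

    ann_a.sort(key=lambda a: (a.seqid, a.start))
    ann_b.sort(key=lambda a: (a.seqid, a.start))
    return genome_a, genome_b, ann_a, ann_b, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(genome: Sequence[SequenceRecord],
                   config: SimulationConfig,
                   seed: int | None = None) -> list[SequenceRecord]:
    """Uniform-coverage single-end reads with substitution errors.

    The number of reads is ``floor(coverage * total_length / read_length)``;
    start positions are uniform over valid starts, strands equiprobable.
    """
    rl = config.read_length
    shortest = min(len(g) for g in genome)
    if rl > shortest:
        raise ConfigError(
            f"read_length {rl} exceeds shortest chromosome ({shortest} bp)")
    if config.coverage <= 0:
        raise ConfigError("coverage must be positive")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    total = sum(len(g) for g in genome)
    n_reads = int(config.coverage * total / rl)
    arrays = [np.frombuffer(g.residues.encode("ascii"), dtype=np.uint8)
              for g in genome]
    starts_per = np.array([len(g) - rl + 1 for g in genome], dtype=np.int64)
    cum = np.cumsum(starts_per)
    pick = rng.integers(0, cum[-1], size=n_reads)
    chrom_idx = np.searchsorted(cum, pick, side="right")
    start = pick - np.concatenate([[0], cum[:-1]])[chrom_idx]
    strand = rng.random(n_reads) < 0.5
    reads: list[SequenceRecord] = []
    for i in range(n_reads):
        ci, s = int(chrom_idx[i]), int(start[i])
        frag = arrays[ci][s:s + rl]
        frag = _mutate(frag, config.read_error_rate, rng)
        if strand[i]:
            frag = _revcomp_arr(frag)
        reads.append(SequenceRecord(
            f"read_{i}", _to_str(frag),
            f"{genome[ci].id}:{s}:{'-' if strand[i] else '+'}"))
    return reads


def write_fastq(reads: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id} {r.description}\n{r.residues}\n+\n"
                     f"{'I' * len(r.residues)}\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    reads: list[SequenceRecord] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            rid, _, desc = header[1:].strip().partition(" ")
            reads.append(SequenceRecord(rid, seq.upper(), desc))
    return reads
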