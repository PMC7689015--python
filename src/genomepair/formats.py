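"""Readers and writers for the flat-file formats shared by every stage.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open; conversion to and from the
1-based inclusive coordinates of GFF3 and show-coords tables happens only at
the file boundary.  :class:`Annotation` keeps the native GFF3 coordinates as
read; use :meth:`Annotation.interval` to obtain the internal form.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FormatError(ValueError):
    """An input file violates its declared format."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; residues are uppercased, order is preserved."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, str(rec.seq).upper(), rec.description)
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id,
                      description=r.description if r.description != r.id else "")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 annotations
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    """One GFF3 feature.  ``start``/``end`` are 1-based inclusive (as in the
    file); :meth:`interval` converts to the internal 0-based half-open form."""

    seqid: str
    source: str
    feature_type: str
    start: int
    end: int
    score: float | None = None
    strand: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"annotation {self.seqid}:{self.start}-{self.end}: "
                "requires 1 <= start <= end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    def interval(self) -> tuple[int, int]:
        """0-based half-open interval."""
        return self.start - 1, self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_gff3(path: str | Path) -> list[Annotation]:
    """Read GFF3.  Directive/comment lines are tolerated; records with
    start > end are dropped with a warning; non-numeric coordinates raise
    :class:`FormatError`."""
    out: list[Annotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seqid, source, ftype, s, e, score, strand, _phase, attrs = cols
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinate"
                ) from exc
            if start > end:
                warnings.warn(
                    f"{path}:{lineno}: start > end ({start} > {end}); "
                    "record skipped"
                )
                continue
            attributes = {}
            for item in attrs.split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, value = item.partition("=")
                attributes[key] = value
            out.append(Annotation(
                seqid=seqid, source=source, feature_type=ftype,
                start=start, end=end,
                score=None if score == "." else float(score),
                strand=strand, attributes=attributes,
            ))
    return out


def write_gff3(annotations: Iterable[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = ";".join(f"{k}={v}" for k, v in a.attributes.items()) or "."
            score = "." if a.score is None else f"{a.score:g}"
            fh.write(
                f"{a.seqid}\t{a.source}\t{a.feature_type}\t{a.start}\t{a.end}"
                f"\t{score}\t{a.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Controlled repeat vocabulary
# ---------------------------------------------------------------------------

#: canonical feature classes used by the landscape / summary stages
GENE_CLASS = "gene"
TE_CLASSES = ("LTR_gypsy", "LTR_copia", "LINE", "ClassI_other", "ClassII")
RDNA_CLASSES = ("rDNA_45S", "rDNA_5S")
OTHER_CLASS = "other"
ALL_CLASSES = (GENE_CLASS,) + TE_CLASSES + RDNA_CLASSES + (OTHER_CLASS,)


def classify_feature(feature_type: str) -> str:
    """Map a free-text GFF3 feature type onto the controlled vocabulary.

    Annotation pipelines emit heterogeneous type strings (``LTR/Gypsy``,
    ``Gypsy-LTR``, ``DNA/hAT`` ...); this keeps the downstream category
    tables computable.  Unrecognised types fall into ``other``.
    """
    t = feature_type.lower()
    if t == "gene" or t.endswith("_gene") or t == "mrna":
        return GENE_CLASS
    if "45s" in t or "35s" in t or "25s" in t:
        return "rDNA_45S"
    if "5s" in t and ("rdna" in t or "rrna" in t):
        return "rDNA_5S"
    if "rdna" in t or "rrna" in t:
        return "rDNA_45S"
    if "gypsy" in t:
        return "LTR_gypsy"
    if "copia" in t:
        return "LTR_copia"
    if "line" in t:
        return "LINE"
    if "sine" in t or "trim" in t or "lard" in t or "ltr" in t \
            or "classi_" in t or t == "classi" or "retro" in t:
        return "ClassI_other"
    if "classii" in t or t.startswith("dna") or "tir" in t or "helitron" in t \
            or "mite" in t or "mariner" in t or "hat" in t or "mutator" in t \
            or "harbinger" in t or "cacta" in t or "transposon" in t:
        return "ClassII"
    return OTHER_CLASS


def is_te(feature_type: str) -> bool:
    return classify_feature(feature_type) in TE_CLASSES


def is_rdna(feature_type: str) -> bool:
    return classify_feature(feature_type) in RDNA_CLASSES


# ---------------------------------------------------------------------------
# Alignment blocks
# ---------------------------------------------------------------------------

@dataclass
class AlignmentBlock:
    """One local alignment between two genomes (0-based half-open on both)."""

    ref_seqid: str
    ref_start: int
    ref_end: int
    qry_seqid: str
    qry_start: int
    qry_end: int
    orientation: str  # "forward" | "reverse"
    percent_identity: float

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start:
            raise ValueError("ref_end must exceed ref_start")
        if self.qry_end <= self.qry_start:
            raise ValueError("qry_end must exceed qry_start")
        if self.orientation not in {"forward", "reverse"}:
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity out of [0, 100]")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_span(self) -> int:
        return self.qry_end - self.qry_start


_INTERNAL_HEADER = ("ref_seqid", "ref_start", "ref_end", "qry_seqid",
                    "qry_start", "qry_end", "orientation", "pct_identity")


def read_alignment_blocks(path: str | Path,
                          dialect: str = "internal_tsv") -> list[AlignmentBlock]:
    """Read alignment blocks from a tab-separated table.

    ``internal_tsv``
        the package's own 0-based half-open dialect (header optional).
    ``showcoords_tsv``
        the common tab-separated show-coords layout
        ``S1 E1 S2 E2 LEN1 LEN2 %IDY REF QRY`` with 1-based inclusive
        coordinates and reverse orientation encoded as S2 > E2.  Header and
        non-numeric preamble lines are skipped.
    """
    if dialect not in {"internal_tsv", "showcoords_tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if dialect == "internal_tsv":
                if cols[0] == _INTERNAL_HEADER[0]:
                    continue
                if len(cols) != 8:
                    raise FormatError(
                        f"{path}:{lineno}: expected 8 columns, got {len(cols)}")
                blocks.append(AlignmentBlock(
                    ref_seqid=cols[0], ref_start=int(cols[1]),
                    ref_end=int(cols[2]), qry_seqid=cols[3],
                    qry_start=int(cols[4]), qry_end=int(cols[5]),
                    orientation=cols[6], percent_identity=float(cols[7]),
                ))
            else:
                # skip show-coords preamble / header lines
                try:
                    int(cols[0])
                except ValueError:
                    continue
                if len(cols) < 9:
                    raise FormatError(
                        f"{path}:{lineno}: expected >= 9 columns, "
                        f"got {len(cols)}")
                s1, e1, s2, e2 = (int(c) for c in cols[:4])
                idy = float(cols[6])
                ref, qry = cols[-2], cols[-1]
                if s2 <= e2:
                    qs, qe, orient = s2 - 1, e2, "forward"
                else:
                    qs, qe, orient = e2 - 1, s2, "reverse"
                blocks.append(AlignmentBlock(
                    ref_seqid=ref, ref_start=s1 - 1, ref_end=e1,
                    qry_seqid=qry, qry_start=qs, qry_end=qe,
                    orientation=orient, percent_identity=idy,
                ))
    return blocks


def write_alignment_blocks(blocks: Iterable[AlignmentBlock],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_INTERNAL_HEADER) + "\n")
        for b in blocks:
            fh.write(
                f"{b.ref_seqid}\t{b.ref_start}\t{b.ref_end}\t{b.qry_seqid}"
                f"\t{b.qry_start}\t{b.qry_end}\t{b.orientation}"
                f"\t{b.percent_identity:.2f}\n"
            )


def write_bed(intervals: Iterable[tuple[str, int, int]] |
              Iterable[Sequence], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    """Write 0-based half-open intervals as BED3 (or BED4 with names)."""
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            seqid, start, end = iv[0], iv[1], iv[2]
            if names is not None:
                fh.write(f"{seqid}\t{start}\t{end}\t{names[i]}\n")
            else:
                fh.write(f"{seqid}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Trees (thin wrappers around dendropy)
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree as Newick; internal-node labels (bootstrap supports)
    are kept, branch lengths are written with 6 significant digits."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6g",
    ).strip()
    return text


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")
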