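"""Readers, writers and the internal coordinate convention.

Every interval inside the package is 0-based, half-open, on the forward
strand of the sequence it refers to; strand is carried as a separate flag.
External formats that use 1-based inclusive coordinates (tabular alignment
hits, GFF3) are converted on the way in and back on the way out.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gffutils
import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "SequenceRecord",
    "GenomeAssembly",
    "OrganelleGenome",
    "FeatureAnnotation",
    "HitRecord",
    "ASSEMBLY_LEVELS",
    "ORGANELLE_KINDS",
    "FEATURE_CLASSES",
    "read_fasta",
    "write_fasta",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_gff_features",
    "write_gff_features",
    "write_segments",
    "read_segments_bed",
    "read_newick",
    "to_zero_based",
    "to_one_based",
    "revcomp",
]

ASSEMBLY_LEVELS = ("contig", "scaffold", "chromosome", "complete")
ORGANELLE_KINDS = ("mitochondrion", "plastid")
FEATURE_CLASSES = ("CDS", "tRNA", "rRNA", "other")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_RESIDUES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_residues(residues: str) -> str:
    up = residues.upper()
    if set(up) <= _VALID_RESIDUES:
        return up
    return "".join(c if c in _VALID_RESIDUES else "N" for c in up)


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence; residues restricted to {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class GenomeAssembly:
    """A nuclear genome assembly plus its NCBI-style assembly level.

    The assembly level is user-supplied metadata, never inferred from the
    sequence itself.
    """

    species: str
    records: list[SequenceRecord]
    assembly_level: str = "scaffold"

    def __post_init__(self) -> None:
        if self.assembly_level not in ASSEMBLY_LEVELS:
            raise ValueError(
                f"unknown assembly level {self.assembly_level!r}; "
                f"expected one of {ASSEMBLY_LEVELS}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence id(s) in assembly: {dup}")
        self._by_id = {r.id: r for r in self.records}

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id


@dataclass(frozen=True)
class FeatureAnnotation:
    """A functional feature (CDS/tRNA/rRNA/other) on an organellar genome."""

    feature_id: str
    klass: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.klass not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.klass!r}")
        if not self.start < self.end:
            raise ValueError(f"empty feature interval [{self.start}, {self.end})")


@dataclass
class OrganelleGenome:
    """An organellar (mitochondrial or plastid) genome used as the query."""

    record: SequenceRecord
    kind: str
    circular: bool = False
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ORGANELLE_KINDS:
            raise ValueError(f"unknown organelle kind {self.kind!r}")
        for f in self.features:
            if f.start < 0 or f.end > self.record.length:
                raise ValueError(
                    f"feature {f.feature_id} [{f.start}, {f.end}) outside "
                    f"sequence of length {self.record.length}"
                )


@dataclass(frozen=True)
class HitRecord:
    """One retained local-alignment match: organellar query vs nuclear subject.

    ``strand == '-'`` means the alignment pairs the query forward strand with
    the reverse complement of the subject interval; both stored intervals are
    nonetheless forward-strand 0-based half-open.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity_pct: float
    aln_length: int
    bitscore: float
    evalue: float
    mismatch: int = 0
    gapopen: int = 0
    hit_id: str | None = None

    def __post_init__(self) -> None:
        if self.q_start >= self.q_end or self.s_start >= self.s_end:
            raise ValueError("hit intervals must be non-empty")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)

    @property
    def s_length(self) -> int:
        return self.s_end - self.s_start


# --- coordinate conversion -------------------------------------------------

def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (inverse of :func:`to_zero_based`)."""
    return start0 + 1, end0


# --- FASTA -----------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and anything outside {A,C,G,T} becomes N.
    Raises ``ValueError`` on an empty file or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    bio = [_BioRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# --- 12-column tabular hits (blastn -outfmt 6) ------------------------------

_HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_tabular_hits(path: str | os.PathLike) -> list[HitRecord]:
    """Read the de-facto 12-column tab-separated local-alignment hit format.

    Input coordinates are 1-based inclusive; subject coordinates in
    descending order denote a minus-strand match and are normalised to an
    ascending forward-strand interval with ``strand='-'``.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                pident = float(fields[2])
                aln_length = int(fields[3])
                mismatch = int(fields[4])
                gapopen = int(fields[5])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            q0 = to_zero_based(qstart, qend)
            if sstart <= send:
                s0, strand = to_zero_based(sstart, send), "+"
            else:
                s0, strand = to_zero_based(send, sstart), "-"
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    q_start=q0[0],
                    q_end=q0[1],
                    s_start=s0[0],
                    s_end=s0[1],
                    strand=strand,
                    identity_pct=pident,
                    aln_length=aln_length,
                    bitscore=bitscore,
                    evalue=evalue,
                    mismatch=mismatch,
                    gapopen=gapopen,
                    hit_id=f"hit{lineno}",
                )
            )
    return hits


def write_tabular_hits(hits: list[HitRecord], path: str | os.PathLike) -> None:
    """Write hits back to the 12-column format (inverse of :func:`read_tabular_hits`)."""
    with open(path, "w") as fh:
        for h in hits:
            qstart, qend = to_one_based(h.q_start, h.q_end)
            if h.strand == "+":
                sstart, send = to_one_based(h.s_start, h.s_end)
            else:
                one = to_one_based(h.s_start, h.s_end)
                sstart, send = one[1], one[0]
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, repr(h.identity_pct), h.aln_length,
                        h.mismatch, h.gapopen, qstart, qend, sstart, send,
                        repr(h.evalue), repr(h.bitscore),
                    )
                )
                + "\n"
            )


# --- GFF3 ------------------------------------------------------------------

_GFF_CLASS = {"cds": "CDS", "trna": "tRNA", "rrna": "rRNA"}


def read_gff_features(
    path: str | os.PathLike,
    target_id: str | None = None,
    seq_length: int | None = None,
) -> list[FeatureAnnotation]:
    """Read GFF3 features for one sequence.

    Types CDS/tRNA/rRNA are kept as such (case-insensitive); every other
    type maps to class ``other``. Coordinates convert from 1-based inclusive
    to the internal convention.
    """
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    out: list[FeatureAnnotation] = []
    for feat in db.all_features():
        if target_id is not None and feat.seqid != target_id:
            continue
        klass = _GFF_CLASS.get(feat.featuretype.lower(), "other")
        start, end = to_zero_based(feat.start, feat.end)
        if seq_length is not None and (start < 0 or end > seq_length):
            raise ValueError(
                f"feature {feat.id} [{feat.start}, {feat.end}] outside sequence "
                f"of length {seq_length}"
            )
        strand = feat.strand if feat.strand in "+-" else "+"
        out.append(FeatureAnnotation(feat.id, klass, start, end, strand))
    return out


def write_gff_features(
    features: list[FeatureAnnotation], seq_id: str, path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            start1, end1 = to_one_based(f.start, f.end)
            ftype = f.klass if f.klass != "other" else "region"
            fh.write(
                f"{seq_id}\tnorgscan\t{ftype}\t{start1}\t{end1}\t.\t{f.strand}\t.\t"
                f"ID={f.feature_id}\n"
            )


# --- segment output --------------------------------------------------------

def write_segments(segments, path: str | os.PathLike, format: str = "BED",
                   species: str = "") -> None:
    """Write deduplicated segments as BED (0-based half-open) or a TSV summary."""
    fmt = format.upper()
    if fmt not in ("BED", "TSV"):
        raise ValueError(f"unknown segment format {format!r}")
    with open(path, "w") as fh:
        if fmt == "BED":
            for i, seg in enumerate(segments):
                name = f"{seg.kind}_{i}"
                fh.write(
                    f"{seg.subject_id}\t{seg.start}\t{seg.end}\t{name}\t"
                    f"{seg.best_identity_pct:.2f}\t+\n"
                )
        else:
            fh.write(
                "species\tkind\tsubject_id\tstart\tend\tlength\t"
                "best_identity_pct\tn_hits\tfeature_classes\n"
            )
            for seg in segments:
                classes = ",".join(sorted(seg.feature_classes)) or "."
                fh.write(
                    f"{species}\t{seg.kind}\t{seg.subject_id}\t{seg.start}\t"
                    f"{seg.end}\t{seg.end - seg.start}\t{seg.best_identity_pct:.4f}\t"
                    f"{len(seg.contributing_hits)}\t{classes}\n"
                )


def read_segments_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    """Read a segments BED back as (subject_id, start, end, name) tuples."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return rows


# --- Newick ----------------------------------------------------------------

def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    """Read a single rooted Newick tree; every edge must carry a branch length.

    The comparative layer builds covariances from root-to-tip shared path
    lengths, so missing or negative branch lengths are an error.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("unlabeled tip in tree")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge length is optional
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal>"
            raise ValueError(f"missing branch length above node {name}")
        if edge.length < 0:
            raise ValueError("negative branch length in tree")
    return tree
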