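"""From retained hits to deduplicated NUMT/NUPT segments and content summaries.

The central bookkeeping rule: a nuclear region matched by several organellar
query regions is one insertion event and must be counted once.  Overlapping
hit intervals on the same nuclear sequence are therefore unioned into a
single segment before anything is counted or length-summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .seq_io import GenomeAssembly, HitRecord, OrganelleGenome

__all__ = [
    "ContaminationPolicy",
    "ContaminationReport",
    "NorgSegment",
    "ContentSummary",
    "IdentityHistogram",
    "flag_contamination",
    "merge_hits",
    "segments_to_hits",
    "summarize",
    "classify_features",
    "identity_distribution",
    "resolve_promiscuous",
    "KIND_BY_ORGANELLE",
]

# organelle kind -> segment kind
KIND_BY_ORGANELLE = {"mitochondrion": "NUMT", "plastid": "NUPT"}


@dataclass(frozen=True)
class ContaminationPolicy:
    """Defaults for the 'short contig completely matched' discard rule.

    The source method leaves "short" and "completely" unquantified; the
    defaults below (10 kb, 95% coverage) are explicit and configurable.
    """

    max_contig_length: int = 10_000
    min_covered_fraction: float = 0.95


@dataclass
class ContaminationReport:
    flagged: list[tuple[str, float, int]]  # (sequence id, covered fraction, length)
    policy: ContaminationPolicy
    removed_hits: int = 0

    @property
    def flagged_ids(self) -> set[str]:
        return {f[0] for f in self.flagged}

    @property
    def flagged_length(self) -> int:
        return sum(f[2] for f in self.flagged)


@dataclass
class NorgSegment:
    """A deduplicated nuclear interval of organellar origin (NUMT or NUPT)."""

    subject_id: str
    start: int
    end: int
    kind: str
    best_identity_pct: float
    contributing_hits: list[str] = field(default_factory=list)
    feature_classes: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ContentSummary:
    """Per species x organelle-kind abundance summary."""

    species: str
    kind: str
    count: int
    total_length_bp: int
    genome_size_bp: int

    @property
    def count_per_mb(self) -> float:
        return self.count / (self.genome_size_bp / 1e6)

    @property
    def length_per_mb(self) -> float:
        return self.total_length_bp / (self.genome_size_bp / 1e6)

    @property
    def total_length_kb(self) -> int:
        """Half-up integer kb, the human-readable presentation."""
        return int(np.floor(self.total_length_bp / 1000 + 0.5))


@dataclass(frozen=True)
class IdentityHistogram:
    bin_edges: tuple[float, ...]  # right-closed bins (edge[i], edge[i+1]]
    counts: tuple[int, ...]


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end_prev = -1
    for a, b in sorted(intervals):
        if a > end_prev:
            total += b - a
            end_prev = b
        elif b > end_prev:
            total += b - end_prev
            end_prev = b
    return total


def flag_contamination(
    hits: list[HitRecord],
    assembly: GenomeAssembly,
    policy: ContaminationPolicy | None = None,
) -> tuple[ContaminationReport, list[HitRecord]]:
    """Discard short nuclear sequences that are essentially all organellar.

    A sequence is flagged when BOTH hold: its length is at most
    ``policy.max_contig_length`` and the union of organellar hits covers at
    least ``policy.min_covered_fraction`` of it.  All hits on flagged
    sequences are removed; density computations should subtract the flagged
    length from the genome size (see :attr:`ContaminationReport.flagged_length`).
    """
    policy = policy or ContaminationPolicy()
    by_subject: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        if h.subject_id not in assembly:
            raise ValueError(f"hit refers to unknown sequence {h.subject_id!r}")
        by_subject.setdefault(h.subject_id, []).append(h.s_interval)
    flagged: list[tuple[str, float, int]] = []
    for sid, ivs in sorted(by_subject.items()):
        length = assembly[sid].length
        if length > policy.max_contig_length:
            continue
        frac = _union_length(ivs) / length
        if frac >= policy.min_covered_fraction:
            flagged.append((sid, frac, length))
    flagged_ids = {f[0] for f in flagged}
    retained = [h for h in hits if h.subject_id not in flagged_ids]
    report = ContaminationReport(flagged, policy, removed_hits=len(hits) - len(retained))
    return report, retained


def merge_hits(hits: list[HitRecord], kind: str, merge_gap: int = 0) -> list[NorgSegment]:
    """Union overlapping subject intervals into counted segments.

    Intervals overlapping by >= 1 bp or book-ended (zero bases between
    them) merge, matching the per-base coverage view of the nuclear genome
    (and the default of bedtools merge); ``merge_gap > 0`` additionally
    joins intervals separated by at most that many bases.  Each segment
    keeps the ids of its contributing hits and the maximum identity among
    them.  Output order is deterministic: subject id, then start.
    """
    if kind not in ("NUMT", "NUPT"):
        raise ValueError(f"unknown segment kind {kind!r}")
    by_subject: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_subject.setdefault(h.subject_id, []).append(h)
    segments: list[NorgSegment] = []
    for sid in sorted(by_subject):
        group = sorted(by_subject[sid], key=lambda h: (h.s_start, h.s_end))
        cur: NorgSegment | None = None
        for idx, h in enumerate(group):
            hid = h.hit_id or f"{sid}:{idx}"
            merges = cur is not None and h.s_start - cur.end <= merge_gap
            if merges:
                cur.end = max(cur.end, h.s_end)
                cur.best_identity_pct = max(cur.best_identity_pct, h.identity_pct)
                cur.contributing_hits.append(hid)
            else:
                if cur is not None:
                    segments.append(cur)
                cur = NorgSegment(sid, h.s_start, h.s_end, kind,
                                  h.identity_pct, [hid])
        if cur is not None:
            segments.append(cur)
    return segments


def segments_to_hits(segments: list[NorgSegment], query_id: str = "seg") -> list[HitRecord]:
    """Re-express segments as synthetic hits (used to test dedup idempotence)."""
    return [
        HitRecord(
            query_id=query_id, subject_id=s.subject_id,
            q_start=0, q_end=s.length,
            s_start=s.start, s_end=s.end, strand="+",
            identity_pct=s.best_identity_pct, aln_length=s.length,
            bitscore=0.0, evalue=0.0, hit_id=f"seg:{s.subject_id}:{s.start}",
        )
        for s in segments
    ]


def summarize(segments: list[NorgSegment], species: str, kind: str,
              genome_size_bp: int) -> ContentSummary:
    """Count and length-sum segments of one kind for one species."""
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    for s in segments:
        if s.kind != kind:
            raise ValueError(f"segment of kind {s.kind} in a {kind} summary")
    return ContentSummary(
        species=species, kind=kind, count=len(segments),
        total_length_bp=sum(s.length for s in segments),
        genome_size_bp=genome_size_bp,
    )


def classify_features(
    segments: list[NorgSegment],
    hits: list[HitRecord],
    organelle: OrganelleGenome,
    species: str = "",
    genome_size_bp: int | None = None,
) -> dict[str, ContentSummary]:
    """Attribute segments to organellar feature classes and summarise per class.

    A segment carries class c when any contributing hit's query interval
    overlaps a feature of class c by >= 1 bp; a segment may carry several
    classes, and segments with no annotated overlap carry {'other'}.
    Feature-class sets are stored on the segments in place.
    """
    ftree = IntervalTree()
    for f in organelle.features:
        ftree[f.start:f.end] = f.klass
    L = organelle.record.length
    hit_by_id = {h.hit_id: h for h in hits if h.hit_id}
    for seg in segments:
        classes: set[str] = set()
        for hid in seg.contributing_hits:
            h = hit_by_id.get(hid)
            if h is None:
                continue
            # circular queries may carry q_end beyond L (origin-spanning)
            spans = [(h.q_start, min(h.q_end, L))]
            if h.q_end > L:
                spans.append((0, h.q_end - L))
            for a, b in spans:
                for iv in ftree[a:b]:
                    classes.add(iv.data)
        seg.feature_classes = classes or {"other"}
    out: dict[str, ContentSummary] = {}
    gsize = genome_size_bp or 1
    kind = segments[0].kind if segments else "NUMT"
    for klass in ("CDS", "tRNA", "rRNA", "other"):
        subset = [s for s in segments if klass in s.feature_classes]
        out[klass] = summarize(subset, species, kind, gsize)
    return out


def identity_distribution(segments: list[NorgSegment], bin_width_pct: float = 5.0,
                          low: float | None = None) -> IdentityHistogram:
    """Histogram of per-segment best identities in right-closed bins up to 100%."""
    if bin_width_pct <= 0 or 100.0 % bin_width_pct != 0:
        raise ValueError("bin width must positively divide 100")
    idents = [s.best_identity_pct for s in segments]
    if low is None:
        lo = min(idents, default=100.0)
        low = bin_width_pct * np.floor((lo - 1e-9) / bin_width_pct)
        low = max(0.0, float(low))
    edges = np.arange(low, 100.0 + bin_width_pct / 2, bin_width_pct)
    counts = [0] * (len(edges) - 1)
    for x in idents:
        # right-closed: bin i is (edges[i], edges[i+1]]
        i = int(np.ceil((x - low) / bin_width_pct)) - 1
        i = min(max(i, 0), len(counts) - 1)
        counts[i] += 1
    return IdentityHistogram(tuple(float(e) for e in edges), tuple(counts))


def resolve_promiscuous(
    mito_hits: list[HitRecord], plastid_hits: list[HitRecord]
) -> tuple[list[HitRecord], list[HitRecord], list[tuple[HitRecord, HitRecord]]]:
    """Partition nuclear regions matched by both organelles ('promiscuous' DNA).

    For each overlapping mito/plastid hit pair on the same nuclear sequence,
    the lower-bitscore hit is dropped.  Returns (mito kept, plastid kept,
    ambiguous pairs) so callers can report the conflicts.
    """
    trees: dict[str, IntervalTree] = {}
    for i, h in enumerate(mito_hits):
        trees.setdefault(h.subject_id, IntervalTree())[h.s_start:h.s_end] = i
    ambiguous: list[tuple[HitRecord, HitRecord]] = []
    drop_m: set[int] = set()
    drop_p: set[int] = set()
    for j, p in enumerate(plastid_hits):
        tree = trees.get(p.subject_id)
        if tree is None:
            continue
        for iv in tree[p.s_start:p.s_end]:
            m = mito_hits[iv.data]
            ambiguous.append((m, p))
            if p.bitscore > m.bitscore:
                drop_m.add(iv.data)
            else:
                drop_p.add(j)
    kept_m = [h for i, h in enumerate(mito_hits) if i not in drop_m]
    kept_p = [h for j, h in enumerate(plastid_hits) if j not in drop_p]
    return kept_m, kept_p, ambiguous
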