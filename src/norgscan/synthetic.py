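"""Synthetic inputs with known ground truth.

Generates every input the pipeline consumes: nuclear backgrounds carrying
planted organellar fragments at controlled lengths and identities, verbatim
contaminant contigs, pure-birth trees, traits evolving with a Pagel's-lambda
covariance, and paired lineage designs under null and shifted alternatives.

Planted insertions replace a background slice (the nuclear length is
unchanged), are separated by at least ``word_size - 1`` bases so alignment
seeds cannot chain across distinct truths, and are flanked by a few guard
bases forced to mismatch the adjacent organellar residues (in register and
under small gap shifts) so that a local alignment of a perfect insertion
terminates exactly at the truth boundary.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.model import birthdeath

from .comparative import PhyloCovariance
from .pipeline import NorgSegment
from .seq_io import (
    FeatureAnnotation,
    GenomeAssembly,
    OrganelleGenome,
    SequenceRecord,
    revcomp,
)

__all__ = [
    "InsertionTruth",
    "SimulationConfig",
    "TraitSimConfig",
    "RecoveryReport",
    "random_sequence",
    "simulate_organelle",
    "plant_insertions",
    "make_contaminant_contigs",
    "simulate_tree",
    "simulate_traits",
    "make_paired_design",
    "evaluate_recovery",
]

_BASES = "ACGT"
_COMPLEMENT_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class InsertionTruth:
    """Ground truth for one planted organellar fragment."""

    subject_id: str
    start: int
    end: int
    kind: str  # NUMT | NUPT
    source_start: int
    source_end: int
    strand: str
    target_identity_pct: float
    realized_identity_pct: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic detection experiment."""

    nuclear_size: int = 2_000_000
    gc_fraction: float = 0.5
    n_insertions: int = 50
    insertion_min_len: int = 200
    insertion_max_len: int = 2_000
    identity_min_pct: float = 85.0
    identity_max_pct: float = 100.0
    contamination_contigs: tuple[int, ...] = ()
    min_spacing: int = 10  # word_size - 1
    guard_bases: int = 4
    seed: int = 0


@dataclass
class TraitSimConfig:
    tree: dendropy.Tree
    lambda_pagel_true: float
    slope_true: float
    sigma2: float
    predictor: np.ndarray
    intercept: float = 0.0
    seed: int = 0


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(_BASES[i] for i in idx)


def simulate_organelle(length: int, gc: float = 0.45, circular: bool = True,
                       n_features: int = 30, seed: int = 0,
                       kind: str = "mitochondrion") -> OrganelleGenome:
    """An i.i.d.-composition organellar genome with disjoint CDS/tRNA/rRNA features.

    Feature lengths follow typical organellar gene sizes (CDS 300-1500 bp,
    tRNA 70-90 bp, rRNA 1200-2800 bp) and are placed uniformly without
    overlap; impossible packings raise after bounded retries.
    """
    if length < 1000:
        raise ValueError("organelle length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    seq = random_sequence(length, gc, rng)
    classes = ["CDS", "tRNA", "rRNA"]
    len_ranges = {"CDS": (300, 1500), "tRNA": (70, 90), "rRNA": (900, 1600)}
    wanted = []
    for i in range(n_features):
        klass = classes[i % 3]
        lo, hi = len_ranges[klass]
        wanted.append((i, klass, int(rng.integers(lo, hi + 1))))
    if sum(w[2] for w in wanted) > 0.85 * length:
        raise ValueError(
            "could not place features without overlap: requested features "
            "exceed 85% of the genome; reduce n_features or enlarge the genome"
        )
    placed: list[tuple[int, int]] = []
    features: list[FeatureAnnotation] = []
    # place longest first so big rRNA/CDS blocks are not squeezed out
    for i, klass, flen in sorted(wanted, key=lambda w: -w[2]):
        ok = False
        for _ in range(500):
            start = int(rng.integers(0, length - flen))
            end = start + flen
            if all(end <= a or start >= b for a, b in placed):
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place feature {i} ({klass}) without overlap; "
                "reduce n_features or enlarge the genome"
            )
        placed.append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(FeatureAnnotation(f"{klass.lower()}_{i}", klass, start, end, strand))
    features.sort(key=lambda f: f.start)
    rec = SequenceRecord(f"{kind[:4]}_genome", seq)
    return OrganelleGenome(rec, kind, circular, features)


def _mutate(fragment: str, divergence: float, rng: np.random.Generator) -> str:
    """Per-site substitutions at the given rate, transitions:transversions 2:1."""
    if divergence <= 0:
        return fragment
    chars = list(fragment)
    for i, c in enumerate(chars):
        if c not in _TRANSITION:
            continue
        if rng.random() < divergence:
            if rng.random() < 2.0 / 3.0:
                chars[i] = _TRANSITION[c]
            else:
                chars[i] = _TRANSVERSIONS[c][int(rng.integers(0, 2))]
    return "".join(chars)


def _identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    m = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return 100.0 * m / len(a)


def plant_insertions(
    background: SequenceRecord,
    organelle: OrganelleGenome,
    config: SimulationConfig,
    species: str = "synthetic",
    assembly_level: str = "chromosome",
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[GenomeAssembly, list[InsertionTruth]]:
    """Copy random organellar substrings into non-overlapping nuclear positions.

    Fragments replace a background slice of equal length; each gets a target
    identity, point substitutions at rate (100 - identity)/100, a random
    orientation, and flanking guard bases (see module docstring).  Truth
    records carry both the requested and the realised identity.  ``occupied``
    lists intervals that must stay untouched (e.g. truths of a previous
    planting round on the same background).
    """
    rng = np.random.default_rng(config.seed)
    kind = "NUMT" if organelle.kind == "mitochondrion" else "NUPT"
    nuc = list(background.residues)
    L = len(nuc)
    org = organelle.record.residues
    org_len = len(org)
    if config.insertion_max_len >= org_len:
        raise ValueError("insertions cannot exceed the organellar genome length")
    placed: list[tuple[int, int]] = list(occupied or [])
    truths: list[InsertionTruth] = []
    spacing = config.min_spacing + config.guard_bases
    for i in range(config.n_insertions):
        ok = False
        for _ in range(500):
            flen = int(rng.integers(config.insertion_min_len, config.insertion_max_len + 1))
            start = int(rng.integers(config.guard_bases, L - flen - config.guard_bases))
            end = start + flen
            if all(end + spacing <= a or start - spacing >= b for a, b in placed):
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place insertion {i} after bounded retries; "
                "reduce n_insertions or enlarge the nuclear background"
            )
        placed.append((start, end))
        src_start = int(rng.integers(0, org_len - flen))
        src_end = src_start + flen
        target_ident = float(rng.uniform(config.identity_min_pct, config.identity_max_pct))
        fragment = org[src_start:src_end]
        mutated = _mutate(fragment, (100.0 - target_ident) / 100.0, rng)
        realized = _identity(mutated, fragment)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = mutated if strand == "+" else revcomp(mutated)
        nuc[start:end] = planted

        # Guard bases: rewrite the flanking nuclear residues so they
        # mismatch the organellar residues that would continue the
        # alignment past the truth boundary -- both in register (shift 0)
        # and under small gap shifts (+-1, +-2), which would otherwise let
        # a chance flank match re-anchor the alignment via a cheap gap.
        def paired_org_base(npos: int, shift: int) -> str | None:
            if strand == "+":
                o = src_start + (npos - start) + shift
            else:
                o = src_end - 1 - (npos - start) + shift
            if organelle.circular:
                o %= org_len
            elif not 0 <= o < org_len:
                return None
            base = org[o]
            return _COMPLEMENT_BASE.get(base, base) if strand == "-" else base

        for g in range(1, config.guard_bases + 1):
            for npos in (start - g, end - 1 + g):
                if not 0 <= npos < L:
                    continue
                avoid_strict = {paired_org_base(npos, d) for d in (-1, 0, 1)}
                avoid_all = avoid_strict | {paired_org_base(npos, d) for d in (-2, 2)}
                choices = [b for b in _BASES if b not in avoid_all] or \
                          [b for b in _BASES if b not in avoid_strict]
                if nuc[npos] not in choices:
                    nuc[npos] = choices[int(rng.integers(0, len(choices)))]
        truths.append(
            InsertionTruth(
                subject_id=background.id, start=start, end=end, kind=kind,
                source_start=src_start, source_end=src_end, strand=strand,
                target_identity_pct=target_ident, realized_identity_pct=realized,
            )
        )
    truths.sort(key=lambda t: t.start)
    rec = SequenceRecord(background.id, "".join(nuc))
    assembly = GenomeAssembly(species, [rec], assembly_level)
    return assembly, truths


def make_contaminant_contigs(
    organelle: OrganelleGenome,
    lengths: tuple[int, ...],
    seed: int = 0,
    prefix: str = "contam",
) -> list[SequenceRecord]:
    """Short contigs that are verbatim organellar substrings (assembly contamination)."""
    rng = np.random.default_rng(seed)
    org = organelle.record.residues
    out = []
    for i, ln in enumerate(lengths):
        if ln >= len(org):
            raise ValueError("contaminant contig must be shorter than the organelle")
        start = int(rng.integers(0, len(org) - ln))
        out.append(SequenceRecord(f"{prefix}_{i}", org[start:start + ln]))
    return out


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with exponential waiting times and n_tips tips."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips, rng=rng,
    )
    # the process stops at the n-th birth, which leaves the two newest tips
    # with zero-length edges; run the clock one more exponential waiting
    # time so every terminal edge is strictly positive (still ultrametric)
    extra = rng.expovariate(birth_rate * n_tips)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        leaf.taxon.label = f"t{i}"
    return tree


def simulate_traits(config: TraitSimConfig,
                    cov: PhyloCovariance | None = None) -> np.ndarray:
    """y = intercept + slope * x + eps with eps ~ MVN(0, sigma2 * V(lambda_true)).

    The noise is drawn through the Cholesky factor of V(lambda_true); a
    non-positive-definite V is an error.
    """
    from .comparative import build_covariance  # local import to avoid cycle

    x = np.asarray(config.predictor, dtype=float)
    if cov is None:
        tips = [leaf.taxon.label for leaf in config.tree.leaf_node_iter()]
        if len(tips) != len(x):
            raise ValueError("predictor must be defined on every tip")
        cov = build_covariance(config.tree, tips)
    v = cov.with_lambda(config.lambda_pagel_true)
    try:
        chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError as exc:
        raise ValueError("V(lambda_true) is not positive definite") from exc
    rng = np.random.default_rng(config.seed)
    if config.sigma2 == 0:
        eps = np.zeros(len(x))
    else:
        eps = math.sqrt(config.sigma2) * (chol @ rng.standard_normal(len(x)))
    return config.intercept + config.slope_true * x + eps


def make_paired_design(n_pairs: int, effect_delta: float = 0.0,
                       noise_law: str = "lognormal", seed: int = 0,
                       **law_kwargs) -> "pd.DataFrame":
    """Paired tolerant/control metric values under a null or shifted design.

    Control values are i.i.d. draws from ``noise_law`` ("lognormal" with
    mean 0/sigma 1 on the log scale by default, or "normal"); tolerant
    values are independent draws from the same law plus ``effect_delta``.
    ``n_pairs = 24`` mirrors the published lineage-pair design size.
    """
    import pandas as pd

    if n_pairs < 5:
        raise ValueError("need at least 5 pairs")
    rng = np.random.default_rng(seed)
    if noise_law == "lognormal":
        draw = lambda: rng.lognormal(law_kwargs.get("mean", 0.0),
                                     law_kwargs.get("sigma", 1.0), n_pairs)
    elif noise_law == "normal":
        draw = lambda: rng.normal(law_kwargs.get("mean", 0.0),
                                  law_kwargs.get("sigma", 1.0), n_pairs)
    else:
        raise ValueError(f"unknown noise law {noise_law!r}")
    control = draw()
    tolerant = draw() + effect_delta
    return pd.DataFrame({
        "pair_id": [f"pair{i}" for i in range(n_pairs)],
        "tolerant": tolerant,
        "control": control,
    })


@dataclass(frozen=True)
class RecoveryReport:
    n_truth: int
    n_recovered: int
    n_exact: int
    precision_bases: float
    recall_bases: float

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else float("nan")


def evaluate_recovery(segments: list[NorgSegment], truths: list[InsertionTruth],
                      min_overlap_fraction: float = 0.9) -> RecoveryReport:
    """Compare detected segments against planted truth.

    A truth insertion is recovered when some segment of the correct kind
    overlaps at least ``min_overlap_fraction`` of it; per-base precision is
    the fraction of segment bases lying inside a truth interval of the same
    kind, per-base recall the fraction of truth bases covered by segments.
    """
    by_key: dict[tuple[str, str], list[NorgSegment]] = {}
    for s in segments:
        by_key.setdefault((s.subject_id, s.kind), []).append(s)
    n_recovered = 0
    n_exact = 0
    covered_truth = 0
    total_truth = 0
    for t in truths:
        segs = by_key.get((t.subject_id, t.kind), [])
        overlaps = [max(0, min(s.end, t.end) - max(s.start, t.start)) for s in segs]
        best = max(overlaps, default=0)
        if best >= min_overlap_fraction * t.length:
            n_recovered += 1
        if any(s.start == t.start and s.end == t.end for s in segs):
            n_exact += 1
        # per-base recall: union of segment coverage within the truth interval
        marks = np.zeros(t.length, dtype=bool)
        for s in segs:
            a = max(s.start, t.start) - t.start
            b = min(s.end, t.end) - t.start
            if b > a:
                marks[a:b] = True
        covered_truth += int(marks.sum())
        total_truth += t.length
    total_seg = sum(s.length for s in segments)
    in_truth = 0
    truth_by_key: dict[tuple[str, str], list[InsertionTruth]] = {}
    for t in truths:
        truth_by_key.setdefault((t.subject_id, t.kind), []).append(t)
    for s in segments:
        for t in truth_by_key.get((s.subject_id, s.kind), []):
            in_truth += max(0, min(s.end, t.end) - max(s.start, t.start))
    precision = in_truth / total_seg if total_seg else 1.0
    recall_bases = covered_truth / total_truth if total_truth else 1.0
    return RecoveryReport(len(truths), n_recovered, n_exact, precision, recall_bases)
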