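"""Self-contained validation experiments on synthetic data.

Each function builds its inputs with the :mod:`norgscan.synthetic`
generators, runs the corresponding part of the pipeline, and measures the
result against ground truth or an independent oracle.  They are used by the
test suite, the numbered analysis drivers, and the acceptance script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .comparative import build_covariance, pgls_fit, spearman, wilcoxon_signed_rank
from .local_search import (
    ScoringScheme,
    has_perfect_word,
    seed_and_extend,
    search_assembly,
    smith_waterman_full,
    solve_karlin_altschul,
)
from .pipeline import (
    ContaminationPolicy,
    flag_contamination,
    merge_hits,
)
from .seq_io import GenomeAssembly, HitRecord, SequenceRecord
from .synthetic import (
    RecoveryReport,
    SimulationConfig,
    TraitSimConfig,
    evaluate_recovery,
    make_contaminant_contigs,
    make_paired_design,
    plant_insertions,
    random_sequence,
    simulate_organelle,
    simulate_traits,
    simulate_tree,
)

__all__ = [
    "worked_example_segments",
    "dedup_oracle_agreement",
    "aligner_oracle_check",
    "DetectionBenchmark",
    "detection_benchmark",
    "pgls_recovery",
    "wilcoxon_null_calibration",
    "wilcoxon_power",
    "contamination_agreement",
    "abundance_genome_size_correlation",
]


# --- the published five-hit worked example ----------------------------------

def worked_example_segments():
    """Two organellar sequences (M1, M2) hitting four nuclear chromosomes.

    M1 matches N1 and N2; M2 matches the same N2 interval plus N3 and N4.
    The N2 region must be counted once, for four segments in total.
    """
    def hit(query, subject, a, b, hid):
        return HitRecord(query, subject, 0, b - a, a, b, "+", 95.0, b - a,
                         100.0, 1e-10, hit_id=hid)

    hits = [
        hit("M1", "N1", 100, 400, "m1n1"),
        hit("M1", "N2", 200, 500, "m1n2"),
        hit("M2", "N2", 200, 500, "m2n2"),
        hit("M2", "N3", 0, 300, "m2n3"),
        hit("M2", "N4", 50, 350, "m2n4"),
    ]
    return merge_hits(hits, "NUMT")


# --- dedup vs per-base marking oracle ---------------------------------------

def dedup_oracle_agreement(n_sets: int = 100, max_intervals: int = 500,
                           seed: int = 0) -> float:
    """Fraction of random hit sets where merge_hits matches a per-base
    boolean-marking oracle in both segment count and union length."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_sets):
        n = int(rng.integers(1, max_intervals + 1))
        starts = rng.integers(0, 20_000, n)
        lens = rng.integers(1, 800, n)
        intervals = [(int(a), int(a + l)) for a, l in zip(starts, lens)]
        hits = [
            HitRecord("q", "c", 0, b - a, a, b, "+", 90.0, b - a, 50.0, 1e-9,
                      hit_id=f"h{i}")
            for i, (a, b) in enumerate(intervals)
        ]
        segs = merge_hits(hits, "NUMT")
        marks = np.zeros(21_000, dtype=bool)
        for a, b in intervals:
            marks[a:b] = True
        edges = np.diff(np.concatenate([[0], marks.astype(np.int8), [0]]))
        if len(segs) == int((edges == 1).sum()) and \
                sum(s.length for s in segs) == int(marks.sum()):
            agree += 1
    return agree / n_sets


# --- seed-and-extend vs exact Smith-Waterman --------------------------------

def aligner_oracle_check(n_pairs: int = 100, seed: int = 0,
                         scheme: ScoringScheme | None = None) -> dict:
    """Best seed-and-extend score vs the exact DP on seeded random pairs.

    Pairs share a planted, lightly mutated fragment; the comparison only
    counts pairs whose optimal alignment contains an exact word of the
    configured seed length.  Also verifies E-value monotonicity in score.
    """
    scheme = scheme or ScoringScheme()
    params = solve_karlin_altschul(scheme)
    rng = np.random.default_rng(seed)

    def rseq(n):
        return random_sequence(n, 0.5, rng)

    tested = agree = 0
    for _ in range(n_pairs):
        s = rseq(int(rng.integers(150, 301)))
        pos = int(rng.integers(0, len(s) - 80))
        frag = list(s[pos:pos + int(rng.integers(40, 81))])
        for i in range(len(frag)):
            if rng.random() < 0.05:
                frag[i] = "ACGT"[int(rng.integers(0, 4))]
        q = rseq(int(rng.integers(5, 16))) + "".join(frag) + rseq(int(rng.integers(5, 16)))
        opt = smith_waterman_full(q, s, scheme)
        if opt is None or not has_perfect_word(q, s, opt, scheme.word_size):
            continue
        tested += 1
        hits = seed_and_extend(SequenceRecord("q", q), SequenceRecord("s", s),
                               scheme, params)
        best = max(
            (round((h.bitscore * math.log(2) + math.log(params.k_ka))
                   / params.lambda_ka) for h in hits),
            default=0,
        )
        if best == opt.score:
            agree += 1
    from .local_search import evalue_of

    evs = [evalue_of(sc, 16_000, 100_000_000, params) for sc in range(0, 300)]
    monotone = all(a > b for a, b in zip(evs, evs[1:]))
    return {"tested": tested, "agree": agree, "evalue_monotone": monotone}


# --- planted-insertion recovery ---------------------------------------------

@dataclass
class DetectionBenchmark:
    numt: RecoveryReport
    nupt: RecoveryReport
    n_zero_divergence: int
    n_zero_divergence_exact: int

    @property
    def recall(self) -> float:
        n = self.numt.n_truth + self.nupt.n_truth
        return (self.numt.n_recovered + self.nupt.n_recovered) / n

    @property
    def precision_bases(self) -> float:
        # length-weighted combination of the per-kind precisions
        return min(self.numt.precision_bases, self.nupt.precision_bases)


def detection_benchmark(seed: int = 0, nuclear_size: int = 2_000_000,
                        n_per_organelle: int = 25, n_exact_identity: int = 5,
                        min_overlap_fraction: float = 0.9) -> DetectionBenchmark:
    """Full detection run on a synthetic nuclear genome with planted truth.

    Plants ``n_per_organelle`` mitochondrial and plastid insertions each
    (200-2000 bp), of which ``n_exact_identity`` per organelle are exact
    copies (0% divergence) and the rest draw identities uniformly from
    85-100%, then runs the complete search-and-merge pipeline and scores
    recovery against truth.
    """
    rng = np.random.default_rng(seed)
    mito = simulate_organelle(16_000, gc=0.45, seed=seed + 1,
                              kind="mitochondrion", n_features=12)
    plastid = simulate_organelle(120_000, gc=0.38, seed=seed + 2,
                                 kind="plastid", n_features=60)
    bg = SequenceRecord("chr1", random_sequence(nuclear_size, 0.41, rng))

    truths = []
    asm = None
    n_div = n_per_organelle - n_exact_identity
    for i, (org, lo, hi, n_ins) in enumerate([
        (mito, 85.0, 100.0, n_div),
        (mito, 100.0, 100.0, n_exact_identity),
        (plastid, 85.0, 100.0, n_div),
        (plastid, 100.0, 100.0, n_exact_identity),
    ]):
        cfg = SimulationConfig(
            nuclear_size=nuclear_size, n_insertions=n_ins,
            insertion_min_len=200, insertion_max_len=2_000,
            identity_min_pct=lo, identity_max_pct=hi, seed=seed + 10 + i,
        )
        base = bg if asm is None else asm.records[0]
        occupied = [(t.start, t.end) for t in truths]
        asm, t = plant_insertions(base, org, cfg, occupied=occupied)
        truths.extend(t)
    truths.sort(key=lambda t: t.start)

    scheme = ScoringScheme()
    params = solve_karlin_altschul(scheme)
    segs = {}
    for org, kind in ((mito, "NUMT"), (plastid, "NUPT")):
        hits = search_assembly(org, asm, scheme, params)
        segs[kind] = merge_hits(hits, kind)
    truth_m = [t for t in truths if t.kind == "NUMT"]
    truth_p = [t for t in truths if t.kind == "NUPT"]
    rep_m = evaluate_recovery(segs["NUMT"], truth_m, min_overlap_fraction)
    rep_p = evaluate_recovery(segs["NUPT"], truth_p, min_overlap_fraction)
    zero = [t for t in truths if t.target_identity_pct >= 100.0]
    zero_exact = sum(
        1 for t in zero
        if any(s.start == t.start and s.end == t.end for s in segs[t.kind])
    )
    return DetectionBenchmark(rep_m, rep_p, len(zero), zero_exact)


# --- PGLS parameter recovery -------------------------------------------------

def pgls_recovery(n_reps: int = 200, n_tips: int = 100, lambda_true: float = 0.8,
                  slope_true: float = 1.0, sigma2: float = 1.0,
                  seed: int = 0) -> dict:
    """Mean ML estimates of slope and lambda over Brownian-motion replicates."""
    tree = simulate_tree(n_tips, seed=seed)
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    cov = build_covariance(tree, tips)
    rng = np.random.default_rng(seed + 1)
    slopes, lams = [], []
    for rep in range(n_reps):
        x = rng.standard_normal(n_tips)
        cfg = TraitSimConfig(tree, lambda_true, slope_true, sigma2, x,
                             seed=seed + 100 + rep)
        y = simulate_traits(cfg, cov)
        res = pgls_fit(y, x, cov)
        slopes.append(res.slope)
        lams.append(res.lambda_pagel)
    return {
        "mean_slope": float(np.mean(slopes)),
        "mean_lambda": float(np.mean(lams)),
        "n_reps": n_reps,
    }


# --- Wilcoxon calibration and power -----------------------------------------

def wilcoxon_null_calibration(n_reps: int = 2000, n_pairs: int = 24,
                              alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I error of the paired test under an i.i.d. null design."""
    rejections = 0
    for rep in range(n_reps):
        df = make_paired_design(n_pairs, 0.0, seed=seed + rep)
        res = wilcoxon_signed_rank(list(zip(df["tolerant"], df["control"])))
        if res.p_two_tailed <= alpha:
            rejections += 1
    half = 1.96 * math.sqrt(alpha * (1 - alpha) / n_reps)
    return {
        "rejection_rate": rejections / n_reps,
        "ci_low": alpha - half,
        "ci_high": alpha + half,
        "n_reps": n_reps,
    }


def wilcoxon_power(delta: float = 20.0, n_reps: int = 200, n_pairs: int = 24,
                   seed: int = 0) -> float:
    """Fraction of shifted designs detected at p < 0.01."""
    detected = 0
    for rep in range(n_reps):
        df = make_paired_design(n_pairs, delta, seed=seed + rep)
        res = wilcoxon_signed_rank(list(zip(df["tolerant"], df["control"])))
        if res.p_two_tailed < 0.01:
            detected += 1
    return detected / n_reps


# --- contamination filter ----------------------------------------------------

def contamination_agreement(n_configs: int = 20, seed: int = 0) -> dict:
    """Planted verbatim contaminant contigs vs the default discard policy.

    Each configuration holds a large scaffold with genuine insertions, a
    clean short contig, and 1-4 verbatim organellar contigs; agreement means
    the flagged set equals the planted contaminant set exactly.
    """
    agree = 0
    scheme = ScoringScheme()
    params = solve_karlin_altschul(scheme)
    for c in range(n_configs):
        rng = np.random.default_rng(seed + 17 * c)
        org = simulate_organelle(12_000, seed=seed + 1000 + c, n_features=9)
        bg = SequenceRecord("scaf1", random_sequence(60_000, 0.42, rng))
        cfg = SimulationConfig(nuclear_size=60_000, n_insertions=3,
                               insertion_min_len=200, insertion_max_len=1_000,
                               seed=seed + 2000 + c)
        asm, _ = plant_insertions(bg, org, cfg)
        n_contam = int(rng.integers(1, 5))
        lengths = tuple(int(rng.integers(1_000, 9_000)) for _ in range(n_contam))
        contams = make_contaminant_contigs(org, lengths, seed=seed + 3000 + c)
        clean = SequenceRecord("clean", random_sequence(4_000, 0.42, rng))
        full = GenomeAssembly("sp", list(asm.records) + contams + [clean],
                              "scaffold")
        hits = search_assembly(org, full, scheme, params)
        report, _ = flag_contamination(hits, full, ContaminationPolicy())
        if report.flagged_ids == {x.id for x in contams}:
            agree += 1
    return {"agree": agree, "n_configs": n_configs}


# --- abundance vs genome size -------------------------------------------------

def abundance_genome_size_correlation(n_species: int = 40, seed: int = 0) -> dict:
    """Spearman correlation of simulated NUMT abundance with genome size.

    Insertion counts are drawn Poisson with mean proportional to genome size
    (larger genomes present more integration sites) times a lognormal
    species effect, mirroring the expectation that abundance tracks size.
    """
    rng = np.random.default_rng(seed)
    sizes = rng.lognormal(mean=np.log(3e8), sigma=1.0, size=n_species)
    noise = rng.lognormal(0.0, 0.6, size=n_species)
    counts = rng.poisson(sizes / 5e6 * noise)
    lengths = counts * rng.lognormal(np.log(500.0), 0.3, size=n_species)
    r_count = spearman(sizes, counts.astype(float))
    r_len = spearman(sizes, lengths)
    return {
        "rho_count": r_count.rho, "p_count": r_count.p_value,
        "rho_length": r_len.rho, "p_length": r_len.p_value,
        "n": n_species,
    }
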