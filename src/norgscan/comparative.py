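"""Comparative statistical layer.

Lineage averaging for the paired desiccation-tolerant vs control design,
two-tailed Wilcoxon signed-rank tests, phylogenetic generalized least
squares (PGLS) with Pagel's lambda estimated by maximum likelihood, the
assembly-level coding schemes, and Spearman rank correlation.

The phylogenetic covariance of tips i and j is the shared root-to-tip path
length; Pagel's lambda multiplies the off-diagonal entries, so lambda = 0
recovers ordinary least squares and lambda = 1 a full Brownian-motion
covariance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhyloCovariance",
    "PGLSResult",
    "WilcoxonResult",
    "SpearmanResult",
    "LineageValue",
    "average_lineage",
    "wilcoxon_signed_rank",
    "build_covariance",
    "pgls_fit",
    "code_assembly_levels",
    "spearman",
    "run_paper_comparisons",
    "COMPARISON_METRICS",
]

COMPARISON_METRICS = ("count", "total_length", "count_per_mb", "length_per_mb")


# --- lineage averaging ------------------------------------------------------

@dataclass(frozen=True)
class LineageValue:
    lineage_id: str
    species: tuple[str, ...]
    value: float


def average_lineage(metrics: dict[str, float],
                    grouping: dict[str, list[str]]) -> list[LineageValue]:
    """Arithmetic mean of the member species' metric per lineage.

    Lineages hold one or two species; a single-species lineage passes its
    value through unchanged.  A species without a value is an error.
    """
    out = []
    for lineage_id, members in grouping.items():
        if not 1 <= len(members) <= 2:
            raise ValueError(f"lineage {lineage_id!r} must have 1-2 species")
        vals = []
        for sp in members:
            if sp not in metrics:
                raise ValueError(f"missing metric value for species {sp!r}")
            vals.append(metrics[sp])
        out.append(LineageValue(lineage_id, tuple(members), float(np.mean(vals))))
    return out


# --- Wilcoxon signed-rank ---------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    w_statistic: float
    n_effective: int
    p_two_tailed: float
    method: str  # "exact" | "normal_approx"


def wilcoxon_signed_rank(pairs: list[tuple[float, float]]) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon's original treatment); the
    statistic is W = min(sum of positive ranks, sum of negative ranks) over
    mid-ranks of |differences|.  The p-value is exact (full sign-assignment
    distribution) when the effective n is <= 25 and there are no ties in
    |differences|, otherwise a normal approximation with tie and continuity
    corrections is used.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    d = np.asarray([a - b for a, b in pairs], dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 0, 1.0, "exact")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= 25 and not has_ties:
        method = "exact"
        res = stats.wilcoxon(d, alternative="two-sided", method="exact",
                             zero_method="wilcox")
    else:
        method = "normal_approx"
        res = stats.wilcoxon(d, alternative="two-sided", method="approx",
                             correction=True, zero_method="wilcox")
    return WilcoxonResult(w, n, float(res.pvalue), method)


# --- phylogenetic covariance and PGLS ---------------------------------------

@dataclass
class PhyloCovariance:
    """Shared-path-length covariance for an ordered tip list.

    ``tips`` may contain a species twice (the 'two samples' rule for a
    species contributing both a NUMT and a NUPT observation); duplicated
    tips share their full root-to-tip path minus a negligible epsilon so
    the matrix stays non-singular.
    """

    tips: tuple[str, ...]
    v_matrix: np.ndarray

    def with_lambda(self, lam: float) -> np.ndarray:
        v = self.v_matrix * lam
        np.fill_diagonal(v, np.diag(self.v_matrix))
        return v


def build_covariance(tree: dendropy.Tree, tips: list[str],
                     dup_epsilon: float = 1e-8) -> PhyloCovariance:
    """V[i, j] = root-to-MRCA path length of tips i and j; diag = tip depth."""
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaf_by_label = {}
    for leaf in tree.leaf_node_iter():
        leaf_by_label[leaf.taxon.label] = leaf
    for t in tips:
        if t not in leaf_by_label:
            raise ValueError(f"tip {t!r} not present in tree")

    # ancestor path (as id set) and depth per needed species
    paths: dict[str, list] = {}
    for t in set(tips):
        node = leaf_by_label[t]
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths[t] = path[::-1]  # root .. leaf

    n = len(tips)
    v = np.zeros((n, n))
    for i in range(n):
        pi = paths[tips[i]]
        v[i, i] = pi[-1].root_distance
        for j in range(i + 1, n):
            if tips[i] == tips[j]:
                shared = pi[-1].root_distance - dup_epsilon
            else:
                pj = paths[tips[j]]
                shared = 0.0
                for a, b in zip(pi, pj):
                    if a is b:
                        shared = a.root_distance
                    else:
                        break
            v[i, j] = v[j, i] = shared
    return PhyloCovariance(tuple(tips), v)


@dataclass(frozen=True)
class PGLSResult:
    lambda_pagel: float
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    log_likelihood: float


def _gls_profile(y: np.ndarray, x_design: np.ndarray, cov: PhyloCovariance,
                 lam: float):
    """GLS fit at fixed lambda; returns (loglik, beta, se_slope, r2)."""
    n = len(y)
    v = cov.with_lambda(lam)
    try:
        chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        # duplicated-tip designs sit at the edge of positive definiteness;
        # retry with a jitter far below any branch length of interest
        jitter = 1e-10 * float(np.diag(v).mean())
        try:
            chol = np.linalg.cholesky(v + jitter * np.eye(len(v)))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"V(lambda={lam}) is not positive definite") from exc
    yw = np.linalg.solve(chol, y)
    xw = np.linalg.solve(chol, x_design)
    beta, _, rank, _ = np.linalg.lstsq(xw, yw, rcond=None)
    if rank < x_design.shape[1]:
        raise ValueError("singular design (constant predictor?)")
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdet = 2.0 * float(np.log(np.diag(chol)).sum())
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + logdet + n)
    # slope inference with the unbiased variance estimate
    xtx_inv = np.linalg.inv(xw.T @ xw)
    sigma2 = rss / (n - x_design.shape[1])
    se_slope = math.sqrt(sigma2 * xtx_inv[1, 1]) if x_design.shape[1] > 1 else float("nan")
    # R^2 against the GLS intercept-only model, in the whitened space
    ones_w = np.linalg.solve(chol, np.ones(n))
    mu = float((ones_w @ yw) / (ones_w @ ones_w))
    tss = float(((yw - mu * ones_w) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    return loglik, beta, se_slope, r2


def pgls_fit(y, x, cov: PhyloCovariance, lambda_mode: str | float = "ml",
             transform: str | None = None) -> PGLSResult:
    """PGLS regression of trait y on predictor x under V(lambda).

    ``lambda_mode`` is "ml" (profile maximum likelihood over [0, 1] on a
    0.01 grid plus golden-section refinement) or a fixed value in [0, 1].
    The slope p-value uses a t distribution with n - 2 degrees of freedom;
    R^2 compares against the GLS intercept-only model in the whitened space.
    ``transform="log10p1"`` applies log10(1 + y) to the trait first.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be equal-length vectors")
    n = len(y)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("singular design: constant predictor")
    if transform == "log10p1":
        y = np.log10(1.0 + y)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    xd = np.column_stack([np.ones(n), x])

    if lambda_mode == "ml":
        grid = np.linspace(0.0, 1.0, 101)
        lls = np.array([_gls_profile(y, xd, cov, g)[0] for g in grid])
        best = int(np.argmax(lls))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        # golden-section refinement on [lo, hi]
        invphi = (math.sqrt(5) - 1) / 2
        a, b = lo, hi
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = _gls_profile(y, xd, cov, c)[0]
        fd = _gls_profile(y, xd, cov, d)[0]
        for _ in range(40):
            if fc > fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = _gls_profile(y, xd, cov, c)[0]
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = _gls_profile(y, xd, cov, d)[0]
            if b - a < 1e-6:
                break
        lam = 0.5 * (a + b)
        if _gls_profile(y, xd, cov, lam)[0] < lls[best]:
            lam = float(grid[best])
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")

    loglik, beta, se_slope, r2 = _gls_profile(y, xd, cov, lam)
    t_stat = beta[1] / se_slope
    p = 2.0 * float(stats.t.sf(abs(t_stat), n - 2))
    return PGLSResult(
        lambda_pagel=float(lam), slope=float(beta[1]), intercept=float(beta[0]),
        r_squared=float(r2), p_value=p, n=n, log_likelihood=float(loglik),
    )


# --- assembly-level coding ---------------------------------------------------

def code_assembly_levels(levels: dict[str, str], scheme: str) -> dict[str, int]:
    """Numeric codes for assembly levels per the two published schemes.

    ``contig_vs_rest``: contig -> 1, everything higher -> 2.
    ``scaffold_vs_higher``: scaffold -> 3, chromosome/complete -> 4, and
    contig-level species are excluded from the returned map.
    """
    out: dict[str, int] = {}
    for sp, level in levels.items():
        if level not in ("contig", "scaffold", "chromosome", "complete"):
            raise ValueError(f"unknown assembly level {level!r} for {sp!r}")
        if scheme == "contig_vs_rest":
            out[sp] = 1 if level == "contig" else 2
        elif scheme == "scaffold_vs_higher":
            if level == "contig":
                continue
            out[sp] = 3 if level == "scaffold" else 4
        else:
            raise ValueError(f"unknown coding scheme {scheme!r}")
    return out


# --- Spearman ----------------------------------------------------------------

@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


def spearman(x, y, exact_max_n: int = 9) -> SpearmanResult:
    """Spearman rank correlation: Pearson correlation of mid-ranked vectors.

    p-value by full permutation enumeration for n <= ``exact_max_n``,
    otherwise the usual t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        rhos = []
        for perm in itertools.permutations(ry):
            rhos.append(np.corrcoef(rx, perm)[0, 1])
        rhos = np.asarray(rhos)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return SpearmanResult(rho, min(p, 1.0), n)


# --- the full paired-comparison table ----------------------------------------

def run_paper_comparisons(
    pair_table: pd.DataFrame,
    metrics: tuple[str, ...] = COMPARISON_METRICS,
    subgroup_column: str = "group",
    genome_size_column: str = "mean_genome_size",
) -> pd.DataFrame:
    """One two-tailed Wilcoxon signed-rank test per metric, plus subgroup reruns.

    ``pair_table`` holds one row per lineage pair with columns
    ``tolerant_<metric>`` and ``control_<metric>`` for every metric, an
    optional subgroup column (e.g. invertebrates/plants/fungi) and an
    optional mean genome size column used to split pairs into small/large
    halves.  Pairs with missing data for a metric are dropped for that
    metric.  Returns a tidy table: subset, metric, n_pairs, W, p, method.
    """
    rows = []

    def _run(subset_name: str, df: pd.DataFrame):
        for metric in metrics:
            tcol, ccol = f"tolerant_{metric}", f"control_{metric}"
            if tcol not in df or ccol not in df:
                continue
            sub = df[[tcol, ccol]].dropna()
            if len(sub) == 0:
                continue
            res = wilcoxon_signed_rank(list(zip(sub[tcol], sub[ccol])))
            rows.append({
                "subset": subset_name, "metric": metric, "n_pairs": len(sub),
                "n_effective": res.n_effective, "w_statistic": res.w_statistic,
                "p_two_tailed": res.p_two_tailed, "method": res.method,
            })

    _run("all", pair_table)
    if subgroup_column in pair_table:
        for name, df in pair_table.groupby(subgroup_column):
            _run(str(name), df)
    if genome_size_column in pair_table and pair_table[genome_size_column].notna().all():
        median = pair_table[genome_size_column].median()
        _run("small_genomes", pair_table[pair_table[genome_size_column] <= median])
        _run("large_genomes", pair_table[pair_table[genome_size_column] > median])
    return pd.DataFrame(rows)
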