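"""Self-contained seed-and-extend local search with Karlin-Altschul E-values.

The search reproduces a megablast-style configuration (match +2, mismatch
-3, gap existence 5, extension 2, word size 11, E <= 1e-4) so the pipeline
can be exercised end to end without an external aligner.  Externally
produced 12-column hit tables remain drop-in replacements (see
:mod:`norgscan.seq_io`).

Two alignment routes are provided on purpose: the production
seed-and-extend path (:func:`seed_and_extend`), and an exact affine-gap
Smith-Waterman (:func:`smith_waterman_full`) that serves as its oracle on
small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seq_io import HitRecord, SequenceRecord, revcomp

__all__ = [
    "ScoringScheme",
    "KarlinAltschulParams",
    "LocalAlignment",
    "solve_karlin_altschul",
    "evalue_of",
    "bitscore_of",
    "min_significant_score",
    "smith_waterman_full",
    "seed_and_extend",
    "search_assembly",
    "rescore_alignment",
    "has_perfect_word",
]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringScheme:
    """Integer local-alignment scoring configuration.

    ``gap_includes_first_extend=True`` means a gap of length g costs
    ``gap_open + gap_extend * g`` (the convention of the search tool the
    defaults mirror); set it to False for ``gap_open + gap_extend * (g-1)``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 11
    evalue_max: float = 1e-4
    xdrop: int = 20
    band_width: int = 16
    gapped_trigger: int = 25
    gap_includes_first_extend: bool = True
    dust_filter: bool = False  # placeholder, not implemented

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("need match > 0 and mismatch < 0")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")

    @property
    def gap_first(self) -> int:
        """Cost of the first residue of a gap."""
        return self.gap_open + (self.gap_extend if self.gap_includes_first_extend else 0)


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Ungapped Karlin-Altschul parameters for E = K * m * n * exp(-lambda*S)."""

    lambda_ka: float
    k_ka: float
    h: float
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)


def _score_pmf(scheme: ScoringScheme, background) -> tuple[np.ndarray, int]:
    """Distribution of the per-column score of two random letters.

    Returns (probs, offset) with probs[i] = P(S = i + offset).
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9) or (bg < 0).any():
        raise ValueError("background must be 4 non-negative frequencies summing to 1")
    p_match = float((bg**2).sum())
    lo = min(scheme.mismatch, scheme.match)
    hi = max(scheme.mismatch, scheme.match)
    probs = np.zeros(hi - lo + 1)
    probs[scheme.match - lo] += p_match
    probs[scheme.mismatch - lo] += 1.0 - p_match
    return probs, lo


def solve_karlin_altschul(
    scheme: ScoringScheme, background=(0.25, 0.25, 0.25, 0.25)
) -> KarlinAltschulParams:
    """Solve for the ungapped Karlin-Altschul parameters of a scoring scheme.

    lambda is the unique positive root of sum_ij p_i p_j exp(lambda*s_ij) = 1,
    found by bisection to 1e-12.  K uses the classical lattice-case series

        K = delta * lambda * exp(-2*sigma) / (H * (1 - exp(-lambda*delta)))
        sigma = sum_{k>=1} (1/k) * [ P(S_k >= 0) + E(exp(lambda*S_k); S_k < 0) ]

    with the series truncated once a term falls below 1e-12 (at most 80
    convolutions of the per-column score distribution).  Gapped searches
    reuse these ungapped values as an approximation, which keeps every
    E-value internally consistent even though the absolute scale differs
    from a tool with empirically fitted gapped parameters.
    """
    probs, offset = _score_pmf(scheme, background)
    support = np.arange(len(probs)) + offset
    expected = float(probs @ support)
    if expected >= 0:
        raise ValueError("invalid scoring scheme: expected per-column score must be negative")

    def mgf_minus_one(lam: float) -> float:
        return float(probs @ np.exp(lam * support)) - 1.0

    hi = 0.5
    while mgf_minus_one(hi) <= 0:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("failed to bracket lambda")
    lo = 1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mgf_minus_one(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-13:
            break
    lam = 0.5 * (lo + hi)

    # relative entropy H = lambda * E_q[S] with q the lambda-tilted measure
    q = probs * np.exp(lam * support)
    h_param = float(lam * (q @ support))

    # lattice period of the attainable scores
    nz = support[probs > 0].astype(int)
    delta = 0
    for s in nz:
        delta = math.gcd(delta, abs(int(s)))
    delta = max(delta, 1)

    # work on the rescaled lattice (scores / delta, lambda * delta)
    lam_d = lam * delta
    probs_d = np.zeros((len(probs) - 1) // delta + 1)
    probs_d[(nz - int(support[0])) // delta] = probs[probs > 0]
    off_d = int(support[0]) // delta

    sigma = 0.0
    pmf = np.array([1.0])
    pmf_off = 0
    for k in range(1, 81):
        pmf = np.convolve(pmf, probs_d)
        pmf_off += off_d
        vals = np.arange(len(pmf)) + pmf_off
        neg = vals < 0
        term = float(pmf[~neg].sum() + (pmf[neg] * np.exp(lam_d * vals[neg])).sum()) / k
        sigma += term
        if term < 1e-12:
            break
    k_ka = lam_d * math.exp(-2.0 * sigma) / (h_param * (1.0 - math.exp(-lam_d)))
    return KarlinAltschulParams(lam, k_ka, h_param, tuple(float(b) for b in background))


def evalue_of(score: float, m: int, n: int, params: KarlinAltschulParams) -> float:
    """Expected number of chance alignments scoring >= score in an m x n search."""
    if score < 0:
        raise ValueError("score must be non-negative")
    return params.k_ka * m * n * math.exp(-params.lambda_ka * score)


def bitscore_of(score: float, params: KarlinAltschulParams) -> float:
    return (params.lambda_ka * score - math.log(params.k_ka)) / math.log(2.0)


def min_significant_score(m: int, n: int, params: KarlinAltschulParams,
                          evalue_max: float) -> int:
    """Smallest integer score whose E-value is <= evalue_max (direct inversion)."""
    s = math.log(params.k_ka * m * n / evalue_max) / params.lambda_ka
    s_int = max(0, math.ceil(s))
    while evalue_of(s_int, m, n, params) > evalue_max:
        s_int += 1
    return s_int


# --- sequence encoding -----------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode(seq: str, n_code: int = 4) -> np.ndarray:
    """Encode to uint8; N gets ``n_code``.  Using different N codes for query
    (4) and subject (5) makes N a universal mismatch, never a match."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), n_code, dtype=np.uint8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[arr == ord(base)] = code
    return out


# --- alignments ------------------------------------------------------------

@dataclass
class LocalAlignment:
    """A scored local alignment with an explicit path (CIGAR).

    CIGAR ops: M consumes both sequences (match or mismatch), I consumes the
    query only, D consumes the subject only.  The score is recomputable from
    the path via :func:`rescore_alignment`.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: int
    n_matches: int
    aln_length: int
    n_gaps: int
    n_gap_opens: int
    cigar: str
    strand: str = "+"

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.n_matches / self.aln_length if self.aln_length else 0.0


def _cigar_items(cigar: str):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def rescore_alignment(query: str, subject: str, aln: LocalAlignment,
                      scheme: ScoringScheme) -> int:
    """Recompute an alignment's score by walking its stored path."""
    qi, si = aln.q_start, aln.s_start
    score = 0
    for length, op in _cigar_items(aln.cigar):
        if op == "M":
            for _ in range(length):
                a, b = query[qi], subject[si]
                score += scheme.match if (a == b and a != "N") else scheme.mismatch
                qi += 1
                si += 1
        elif op in "ID":
            score -= scheme.gap_first + scheme.gap_extend * (length - 1)
            if op == "I":
                qi += length
            else:
                si += length
        else:  # pragma: no cover
            raise ValueError(f"bad CIGAR op {op}")
    return score


def _ops_to_cigar(ops: list[str]) -> str:
    out = []
    prev, run = None, 0
    for op in ops:
        if op == prev:
            run += 1
        else:
            if prev is not None:
                out.append(f"{run}{prev}")
            prev, run = op, 1
    if prev is not None:
        out.append(f"{run}{prev}")
    return "".join(out)


def has_perfect_word(query: str, subject: str, aln: LocalAlignment, k: int) -> bool:
    """True if the alignment path contains a run of >= k exact match columns."""
    qi, si = aln.q_start, aln.s_start
    run = 0
    for length, op in _cigar_items(aln.cigar):
        if op == "M":
            for _ in range(length):
                if query[qi] == subject[si] and query[qi] != "N":
                    run += 1
                    if run >= k:
                        return True
                else:
                    run = 0
                qi += 1
                si += 1
        else:
            run = 0
            if op == "I":
                qi += length
            else:
                si += length
    return False


# --- exact Smith-Waterman (oracle) -----------------------------------------

def smith_waterman_full(query: str, subject: str, scheme: ScoringScheme,
                        max_cells: int = 4_000_000) -> LocalAlignment | None:
    """Exact optimal local alignment with affine gaps; the test oracle.

    Quadratic in time and memory, guarded by ``max_cells``.  Ties on the
    optimal score are broken deterministically: lowest subject start, then
    lowest query start, then lowest subject/query end.  Returns None when no
    alignment scores above zero.
    """
    lq, ls = len(query), len(subject)
    if (lq + 1) * (ls + 1) > max_cells:
        raise ValueError(f"problem size {lq}x{ls} exceeds max_cells={max_cells}")
    q = encode(query, 4)
    s = encode(subject, 5)
    ma, mi = scheme.match, scheme.mismatch
    gf, ge = scheme.gap_first, scheme.gap_extend

    # DP over subject rows i (1..ls), query cols j (1..lq)
    H = [[0] * (lq + 1) for _ in range(ls + 1)]
    # pointers: for H 0=stop 1=diag 2=E(up) 3=F(left); E/F bit 1 => extend
    PH = [bytearray(lq + 1) for _ in range(ls + 1)]
    PE = [bytearray(lq + 1) for _ in range(ls + 1)]
    PF = [bytearray(lq + 1) for _ in range(ls + 1)]
    E = [_NEG_INF] * (lq + 1)
    best = 0
    best_cells: list[tuple[int, int]] = []
    for i in range(1, ls + 1):
        Hp = H[i - 1]
        Hc = H[i]
        ph, pe, pf = PH[i], PE[i], PF[i]
        si = s[i - 1]
        F = _NEG_INF
        for j in range(1, lq + 1):
            e_open = Hp[j] - gf
            e_ext = E[j] - ge
            if e_ext > e_open:
                E[j] = e_ext
                pe[j] = 1
            else:
                E[j] = e_open
                pe[j] = 0
            f_open = Hc[j - 1] - gf
            f_ext = F - ge
            if f_ext > f_open:
                F = f_ext
                pf[j] = 1
            else:
                F = f_open
                pf[j] = 0
            diag = Hp[j - 1] + (ma if q[j - 1] == si else mi)
            h, p = 0, 0
            if diag > h:
                h, p = diag, 1
            if E[j] > h:
                h, p = E[j], 2
            if F > h:
                h, p = F, 3
            Hc[j] = h
            ph[j] = p
            if h > best:
                best = h
                best_cells = [(i, j)]
            elif h == best and h > 0:
                best_cells.append((i, j))

    if best <= 0:
        return None

    def traceback(i: int, j: int) -> LocalAlignment:
        ops: list[str] = []
        n_match = 0
        state = "H"
        ei, ej = i, j
        while True:
            if state == "H":
                p = PH[i][j]
                if p == 0:
                    break
                if p == 1:
                    ops.append("M")
                    if q[j - 1] == s[i - 1]:
                        n_match += 1
                    i -= 1
                    j -= 1
                elif p == 2:
                    state = "E"
                else:
                    state = "F"
            elif state == "E":  # gap in query, consumes subject
                ext = PE[i][j]
                ops.append("D")
                i -= 1
                state = "E" if ext else "H"
            else:  # F: gap in subject, consumes query
                ext = PF[i][j]
                ops.append("I")
                j -= 1
                state = "F" if ext else "H"
        ops.reverse()
        cigar = _ops_to_cigar(ops)
        n_gaps = sum(1 for o in ops if o != "M")
        n_opens = sum(1 for k_, o in _cigar_items(cigar) if o != "M")
        return LocalAlignment(
            q_start=j, q_end=ej, s_start=i, s_end=ei, score=best,
            n_matches=n_match, aln_length=len(ops), n_gaps=n_gaps,
            n_gap_opens=n_opens, cigar=cigar,
        )

    candidates = [traceback(i, j) for i, j in best_cells]
    candidates.sort(key=lambda a: (a.s_start, a.q_start, a.s_end, a.q_end))
    return candidates[0]


# --- banded affine local DP (gapped extension stage) ------------------------

def _banded_local(q: np.ndarray, s: np.ndarray, scheme: ScoringScheme,
                  q_lo: int, q_hi: int, d_lo: int, d_hi: int) -> LocalAlignment | None:
    """Best clamp-at-zero local alignment inside a diagonal band.

    The band is the parallelogram {(j, i): q_lo <= j < q_hi,
    d_lo <= i - j <= d_hi} in query/subject coordinates.
    """
    ls = len(s)
    ma, mi = scheme.match, scheme.mismatch
    gf, ge = scheme.gap_first, scheme.gap_extend
    width = d_hi - d_lo + 1
    nrow = q_hi - q_lo
    if nrow <= 0 or width <= 0:
        return None
    H_prev = [0.0] * width
    H_rows: list[list[float]] = []
    PH = [bytearray(width) for _ in range(nrow)]
    PE = [bytearray(width) for _ in range(nrow)]
    PF = [bytearray(width) for _ in range(nrow)]
    F_prev = [_NEG_INF] * width
    best = 0.0
    best_cell = None
    for r in range(nrow):
        j = q_lo + r  # query index of the column consumed at this row
        qc = q[j]
        Hc = [0.0] * width
        Fc = [_NEG_INF] * width
        ph, pe, pf = PH[r], PE[r], PF[r]
        e_run = _NEG_INF  # E within the row, from d-1
        h_left = 0.0  # H[r][d-1]
        for d in range(width):
            i = j + d_lo + d  # subject index consumed
            if i < 0 or i >= ls:
                Hc[d] = 0.0
                e_run = _NEG_INF
                h_left = 0.0
                continue
            # E: gap in query (consume subject only) -> same row, d-1
            e_open = h_left - gf
            e_ext = e_run - ge
            if e_ext > e_open:
                e_run = e_ext
                pe[d] = 1
            else:
                e_run = e_open
                pe[d] = 0
            # F: gap in subject (consume query only) -> prev row, d+1
            if d + 1 < width:
                f_open = H_prev[d + 1] - gf
                f_ext = F_prev[d + 1] - ge
            else:
                f_open = f_ext = _NEG_INF
            if f_ext > f_open:
                Fc[d] = f_ext
                pf[d] = 1
            else:
                Fc[d] = f_open
                pf[d] = 0
            diag = H_prev[d] + (ma if qc == s[i] else mi)
            h, p = 0.0, 0
            if diag > h:
                h, p = diag, 1
            if e_run > h:
                h, p = e_run, 2
            if Fc[d] > h:
                h, p = Fc[d], 3
            Hc[d] = h
            ph[d] = p
            h_left = h
            if h > best:
                best = h
                best_cell = (r, d)
        H_rows.append(Hc)
        H_prev = Hc
        F_prev = Fc
    if best_cell is None or best <= 0:
        return None

    r, d = best_cell
    ops: list[str] = []
    n_match = 0
    end_q = q_lo + r + 1
    end_s = q_lo + r + d_lo + d + 1
    state = "H"
    while r >= 0:
        if state == "H":
            p = PH[r][d]
            if p == 0:
                break
            if p == 1:
                ops.append("M")
                if q[q_lo + r] == s[q_lo + r + d_lo + d]:
                    n_match += 1
                r -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ext = PE[r][d]
            ops.append("D")
            d -= 1
            state = "E" if ext else "H"
        else:
            ext = PF[r][d]
            ops.append("I")
            r -= 1
            d += 1
            state = "F" if ext else "H"
        if d < 0 or d >= width:
            break
    ops.reverse()
    start_q = q_lo + r + 1
    start_s = start_q + d_lo + d
    cigar = _ops_to_cigar(ops)
    n_gaps = sum(1 for o in ops if o != "M")
    n_opens = sum(1 for k_, o in _cigar_items(cigar) if o != "M")
    return LocalAlignment(
        q_start=start_q, q_end=end_q, s_start=start_s, s_end=end_s,
        score=int(best), n_matches=n_match, aln_length=len(ops),
        n_gaps=n_gaps, n_gap_opens=n_opens, cigar=cigar,
    )


# --- seed and extend --------------------------------------------------------

def _kmer_hashes(arr: np.ndarray, k: int) -> np.ndarray:
    """Hash every k-window; windows containing N get hash -1."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(arr, k)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    h = win.astype(np.int64) @ weights
    h[(win >= 4).any(axis=1)] = -1
    return h


def _ungapped_extend(q: np.ndarray, s: np.ndarray, q0: int, s0: int, k: int,
                     scheme: ScoringScheme) -> tuple[int, int, int]:
    """X-drop ungapped extension of an exact word seed.

    Returns (score, q_left, q_right) with the extended query extent
    [q_left, q_right); the subject extent follows on the same diagonal.
    """
    ma, mi, xd = scheme.match, scheme.mismatch, scheme.xdrop
    lq, ls = len(q), len(s)
    score = ma * k
    # right
    cur = 0
    best = 0
    best_off = 0
    qi, si = q0 + k, s0 + k
    off = 0
    while qi + off < lq and si + off < ls:
        cur += ma if q[qi + off] == s[si + off] else mi
        off += 1
        if cur > best:
            best, best_off = cur, off
        elif best - cur > xd:
            break
    right = best
    q_right = q0 + k + best_off
    # left
    cur = 0
    best = 0
    best_off = 0
    off = 1
    while q0 - off >= 0 and s0 - off >= 0:
        cur += ma if q[q0 - off] == s[s0 - off] else mi
        if cur > best:
            best, best_off = cur, off
        elif best - cur > xd:
            break
        off += 1
    return score + right + best, q0 - best_off, q_right


def seed_and_extend(query: SequenceRecord, subject: SequenceRecord,
                    scheme: ScoringScheme | None = None,
                    params: KarlinAltschulParams | None = None,
                    circular: bool = False) -> list[HitRecord]:
    """Word-seeded local search of an organellar query against one subject.

    Exact ``word_size``-mers seed an ungapped X-drop extension; promising
    seeds are refined by a banded affine-gap DP around the seed diagonal
    (the band is widened and the window re-run if the alignment touches its
    edge).  Both subject strands are searched; hits with E-value above
    ``scheme.evalue_max`` are dropped; overlapping hits from the same seed
    chain are reported once with the highest score.

    With ``circular=True`` the query is logically doubled; hits starting in
    the second copy are discarded and query coordinates are reported modulo
    the genome length (``q_end`` may exceed it for origin-spanning hits).
    """
    scheme = scheme or ScoringScheme()
    if params is None:
        params = solve_karlin_altschul(scheme)
    k = scheme.word_size
    qlen_true = query.length
    qseq = query.residues * 2 if circular else query.residues
    qarr = encode(qseq, 4)
    m, n = qlen_true, subject.length
    if m == 0 or n == 0:
        return []
    qh = _kmer_hashes(qarr, k)
    qindex: dict[int, list[int]] = {}
    for pos, h in enumerate(qh.tolist()):
        if h >= 0:
            qindex.setdefault(h, []).append(pos)
    if not qindex:
        return []
    qkeys = np.fromiter(qindex.keys(), dtype=np.int64, count=len(qindex))

    smin = min_significant_score(m, n, params, scheme.evalue_max)
    trigger = min(scheme.gapped_trigger, smin)
    hits: list[HitRecord] = []
    counter = 0

    for strand in "+-":
        sseq = subject.residues if strand == "+" else revcomp(subject.residues)
        sarr = encode(sseq, 5)
        sh = _kmer_hashes(sarr, k)
        cand = np.nonzero(np.isin(sh, qkeys))[0]
        coverage: dict[int, int] = {}
        alns: list[LocalAlignment] = []
        for s_pos in cand.tolist():
            for q_pos in qindex[sh[s_pos]]:
                diag = s_pos - q_pos
                if s_pos < coverage.get(diag, 0):
                    continue
                score, q_l, q_r = _ungapped_extend(qarr, sarr, q_pos, s_pos, k, scheme)
                coverage[diag] = max(coverage.get(diag, 0), q_r + diag)
                if score < trigger:
                    continue
                aln = _refine_banded(qarr, sarr, scheme, q_l, q_r, diag)
                if aln is None:
                    continue
                if evalue_of(aln.score, m, n, params) > scheme.evalue_max:
                    continue
                for d in range(diag - scheme.band_width, diag + scheme.band_width + 1):
                    coverage[d] = max(coverage.get(d, 0), aln.s_end)
                aln.strand = strand
                alns.append(aln)

        # drop alignments fully contained in a better one (same seed chain)
        alns.sort(key=lambda a: (-a.score, a.s_start, a.q_start))
        kept: list[LocalAlignment] = []
        for a in alns:
            contained = any(
                a.q_start >= b.q_start and a.q_end <= b.q_end
                and a.s_start >= b.s_start and a.s_end <= b.s_end
                for b in kept
            )
            if not contained:
                kept.append(a)

        for a in kept:
            if strand == "+":
                s0, s1 = a.s_start, a.s_end
            else:
                s0, s1 = n - a.s_end, n - a.s_start
            q0, q1 = a.q_start, a.q_end
            if circular:
                if q0 >= qlen_true:
                    continue  # duplicate from the second copy
            ev = evalue_of(a.score, m, n, params)
            counter += 1
            hits.append(
                HitRecord(
                    query_id=query.id, subject_id=subject.id,
                    q_start=q0, q_end=q1, s_start=s0, s_end=s1,
                    strand=strand, identity_pct=a.identity_pct,
                    aln_length=a.aln_length,
                    bitscore=round(bitscore_of(a.score, params), 2),
                    evalue=ev,
                    mismatch=a.aln_length - a.n_matches - a.n_gaps,
                    gapopen=a.n_gap_opens,
                    hit_id=f"{query.id}:{subject.id}:{strand}:{counter}",
                )
            )
    if circular:
        # the doubled query can rediscover the same nuclear locus from the
        # second copy; keep only the highest-scoring covering hit per locus
        hits.sort(key=lambda h: (-h.bitscore, h.s_start, h.s_end))
        kept_hits: list[HitRecord] = []
        for h in hits:
            if any(
                h.strand == b.strand and h.s_start >= b.s_start and h.s_end <= b.s_end
                for b in kept_hits
            ):
                continue
            kept_hits.append(h)
        hits = kept_hits
    hits.sort(key=lambda h: (h.subject_id, h.s_start, h.s_end, h.strand))
    return hits


def _refine_banded(qarr: np.ndarray, sarr: np.ndarray, scheme: ScoringScheme,
                   q_l: int, q_r: int, diag: int) -> LocalAlignment | None:
    """Banded gapped refinement around an ungapped extension, growing the
    window when the optimum touches its boundary."""
    pad = scheme.xdrop + scheme.band_width
    band = scheme.band_width
    for _ in range(4):
        q_lo = max(0, q_l - pad)
        q_hi = min(len(qarr), q_r + pad)
        aln = _banded_local(qarr, sarr, scheme, q_lo, q_hi,
                            diag - band, diag + band)
        if aln is None:
            return None
        touches = (
            (aln.q_start <= q_lo and q_lo > 0)
            or (aln.q_end >= q_hi and q_hi < len(qarr))
            or (aln.s_start - aln.q_start <= diag - band)
            or (aln.s_end - aln.q_end >= diag + band)
        )
        if not touches:
            return aln
        pad *= 2
        band *= 2
    return aln


def search_assembly(organelle, assembly, scheme: ScoringScheme | None = None,
                    params: KarlinAltschulParams | None = None) -> list[HitRecord]:
    """Run the organellar query against every nuclear record of an assembly."""
    scheme = scheme or ScoringScheme()
    if params is None:
        params = solve_karlin_altschul(scheme)
    hits: list[HitRecord] = []
    for rec in assembly.records:
        hits.extend(
            seed_and_extend(organelle.record, rec, scheme, params,
                            circular=organelle.circular)
        )
    return hits
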