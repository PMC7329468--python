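"""Alignment engine: Karlin-Altschul statistics, the exact Smith-Waterman
oracle, and the seed-and-extend search checked against it."""

import math

import numpy as np
import pytest

from norgscan.local_search import (
    ScoringScheme,
    bitscore_of,
    evalue_of,
    has_perfect_word,
    min_significant_score,
    rescore_alignment,
    search_assembly,
    seed_and_extend,
    smith_waterman_full,
    solve_karlin_altschul,
)
from norgscan.seq_io import OrganelleGenome, GenomeAssembly, SequenceRecord, revcomp

from conftest import make_seq


def _bisect_lambda(p_match, match, mismatch, tol=1e-12):
    """Independent bisection oracle for the root of E[exp(lambda*S)] = 1."""
    f = lambda l: p_match * math.exp(l * match) + (1 - p_match) * math.exp(l * mismatch) - 1
    lo, hi = 1e-9, 10.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2


class TestKarlinAltschul:
    def test_plus1_minus1_closed_form(self):
        p = solve_karlin_altschul(ScoringScheme(match=1, mismatch=-1, word_size=4))
        assert p.lambda_ka == pytest.approx(math.log(3), abs=1e-9)

    def test_default_scheme_matches_bisection_oracle(self, scheme, ka_params):
        lam = _bisect_lambda(0.25, scheme.match, scheme.mismatch)
        assert ka_params.lambda_ka == pytest.approx(lam, abs=1e-9)
        # frozen from the oracle: root of 0.25*e^(2l) + 0.75*e^(-3l) = 1
        assert ka_params.lambda_ka == pytest.approx(0.6337314430979, abs=1e-9)

    def test_root_identity_holds(self, scheme, ka_params):
        pm = 0.25
        val = pm * math.exp(ka_params.lambda_ka * scheme.match) + \
            (1 - pm) * math.exp(ka_params.lambda_ka * scheme.mismatch)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_k_reproduces_published_ungapped_value(self):
        # NCBI's ungapped (match=1, mismatch=-2) constants: lambda 1.33, K 0.621
        p = solve_karlin_altschul(ScoringScheme(match=1, mismatch=-2, word_size=4))
        assert p.lambda_ka == pytest.approx(1.33, abs=0.01)
        assert p.k_ka == pytest.approx(0.621, abs=0.01)

    def test_lambda_monotone_in_gc(self, scheme):
        lams = []
        for gc in (0.3, 0.4, 0.5):
            bg = ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)
            lams.append(solve_karlin_altschul(scheme, bg).lambda_ka)
        # skewed composition raises the chance-match probability, which
        # makes high scores easier and lambda smaller; uniform GC maximises it
        assert lams[0] < lams[1] < lams[2]

    def test_non_negative_expected_score_rejected(self):
        with pytest.raises(ValueError, match="invalid scoring"):
            solve_karlin_altschul(ScoringScheme(match=9, mismatch=-1, word_size=4))


class TestEvalue:
    def test_zero_score_identity(self, ka_params):
        assert evalue_of(0, 100, 1000, ka_params) == \
            pytest.approx(ka_params.k_ka * 100 * 1000)

    def test_linear_in_search_space(self, ka_params):
        assert evalue_of(50, 100, 2000, ka_params) == \
            pytest.approx(2 * evalue_of(50, 100, 1000, ka_params))

    def test_strictly_decreasing_in_score(self, ka_params):
        es = [evalue_of(s, 16_000, 100_000_000, ka_params) for s in range(0, 200)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_threshold_score_by_direct_inversion(self, scheme, ka_params):
        m, n = 16_000, 100_000_000
        s_min = min_significant_score(m, n, ka_params, scheme.evalue_max)
        assert evalue_of(s_min, m, n, ka_params) <= scheme.evalue_max
        assert evalue_of(s_min - 1, m, n, ka_params) > scheme.evalue_max
        # closed-form inversion: s >= ln(K*m*n/E)/lambda
        closed = math.ceil(
            math.log(ka_params.k_ka * m * n / scheme.evalue_max) / ka_params.lambda_ka
        )
        assert s_min == closed


class TestSmithWaterman:
    def test_identical_sequences(self, scheme):
        a = smith_waterman_full("ACGTACGTAC", "ACGTACGTAC", scheme)
        assert a.score == 20 and a.identity_pct == 100.0 and a.cigar == "10M"

    def test_single_letter_best(self, scheme):
        a = smith_waterman_full("ACGT", "TTTT", scheme)
        assert a.score == 2 and a.aln_length == 1

    def test_no_positive_alignment(self, scheme):
        assert smith_waterman_full("AAAA", "CCCC", scheme) is None

    def test_symmetry_under_swap(self, scheme):
        for seed in range(5):
            q, s = make_seq(60, seed), make_seq(90, seed + 100)
            a = smith_waterman_full(q, s, scheme)
            b = smith_waterman_full(s, q, scheme)
            assert (a.score if a else 0) == (b.score if b else 0)

    def test_score_recomputable_from_path(self, scheme):
        q = make_seq(80, 1)
        s = make_seq(50, 2) + q[10:60] + make_seq(40, 3)
        a = smith_waterman_full(q, s, scheme)
        assert rescore_alignment(q, s, a, scheme) == a.score

    def test_n_is_universal_mismatch(self, scheme):
        a = smith_waterman_full("ACGTNNNACGT", "ACGTNNNACGT", scheme)
        # the N block scores as mismatches, so the best local alignment is
        # one clean ACGT block
        assert a.score == 8

    def test_agrees_with_independent_implementation(self, scheme):
        balign = pytest.importorskip("biotite.sequence.align")
        import biotite.sequence as bseq

        alph = bseq.NucleotideSequence.alphabet_unamb
        sm = np.full((4, 4), scheme.mismatch, dtype=np.int32)
        np.fill_diagonal(sm, scheme.match)
        mat = balign.SubstitutionMatrix(alph, alph, sm)
        rng = np.random.default_rng(99)
        for t in range(25):
            q = make_seq(int(rng.integers(20, 70)), 1000 + t)
            s = make_seq(int(rng.integers(40, 120)), 2000 + t)
            if t % 2:
                q = q[:5] + s[10:50] + q[5:]
            mine = smith_waterman_full(q, s, scheme)
            ref = balign.align_optimal(
                bseq.NucleotideSequence(q), bseq.NucleotideSequence(s), mat,
                gap_penalty=(-(scheme.gap_open + scheme.gap_extend), -scheme.gap_extend),
                local=True,
            )[0].score
            assert (mine.score if mine else 0) == max(ref, 0)

    def test_cap_enforced(self, scheme):
        with pytest.raises(ValueError, match="max_cells"):
            smith_waterman_full("A" * 100, "A" * 100, scheme, max_cells=1000)


class TestSeedAndExtend:
    def test_perfect_substring_single_hit(self, scheme, ka_params, small_subject):
        q = SequenceRecord("q", small_subject.residues[1000:1500])
        hits = seed_and_extend(q, small_subject, scheme, ka_params)
        assert len(hits) == 1
        h = hits[0]
        assert h.s_interval == (1000, 1500) and h.identity_pct == 100.0
        assert h.strand == "+" and h.evalue <= scheme.evalue_max

    def test_no_shared_word_no_hits(self, scheme, ka_params):
        q = SequenceRecord("q", "A" * 80)  # no shared 11-mer on either strand
        s = SequenceRecord("s", "C" * 400)
        assert seed_and_extend(q, s, scheme, ka_params) == []

    def test_minus_strand_hit_and_rc_symmetry(self, scheme, ka_params, small_subject):
        q = SequenceRecord("q", revcomp(small_subject.residues[500:900]))
        hits = seed_and_extend(q, small_subject, scheme, ka_params)
        assert [h.s_interval for h in hits] == [(500, 900)]
        assert hits[0].strand == "-"
        # searching the reverse-complemented subject finds the same interval
        # on the plus strand, reflected
        rc = SequenceRecord("rc", revcomp(small_subject.residues))
        mirror = seed_and_extend(q, rc, scheme, ka_params)
        n = small_subject.length
        assert [(n - h.s_end, n - h.s_start) for h in mirror] == [(500, 900)]
        assert mirror[0].strand == "+"

    def test_matches_oracle_on_seeded_instances(self, scheme, ka_params):
        rng = np.random.default_rng(4242)
        tested = 0
        for t in range(60):
            s = make_seq(int(rng.integers(150, 300)), 3000 + t)
            pos = int(rng.integers(0, len(s) - 80))
            frag = list(s[pos:pos + int(rng.integers(40, 80))])
            for i in range(len(frag)):
                if rng.random() < 0.05:
                    frag[i] = "ACGT"[int(rng.integers(0, 4))]
            q = make_seq(8, 4000 + t) + "".join(frag) + make_seq(8, 5000 + t)
            opt = smith_waterman_full(q, s, scheme)
            if opt is None or not has_perfect_word(q, s, opt, scheme.word_size):
                continue
            tested += 1
            hits = seed_and_extend(SequenceRecord("q", q), SequenceRecord("s", s),
                                   scheme, ka_params)
            best = max(
                (round((h.bitscore * math.log(2) + math.log(ka_params.k_ka))
                       / ka_params.lambda_ka) for h in hits),
                default=0,
            )
            assert best == opt.score
        assert tested >= 20  # the check must actually exercise seeded cases

    def test_circular_query_spans_origin_once(self, scheme, ka_params):
        org = make_seq(1200, 8)
        q = SequenceRecord("org", org)
        subj = SequenceRecord(
            "s", make_seq(500, 9) + org[1000:] + org[:150] + make_seq(500, 10)
        )
        hits = seed_and_extend(q, subj, scheme, ka_params, circular=True)
        assert len(hits) == 1
        h = hits[0]
        assert h.q_start == 1000 and h.q_end == 1350  # wraps past the origin
        assert h.s_interval == (500, 850)


class TestSearchAssembly:
    def test_multiple_records(self, scheme, ka_params):
        org_seq = make_seq(4000, 20)
        org = OrganelleGenome(SequenceRecord("mt", org_seq), "mitochondrion", False)
        asm = GenomeAssembly(
            "sp",
            [
                SequenceRecord("c1", make_seq(2000, 21) + org_seq[100:600] + make_seq(500, 22)),
                SequenceRecord("c2", make_seq(1500, 23)),
            ],
            "scaffold",
        )
        hits = search_assembly(org, asm, scheme, ka_params)
        assert {h.subject_id for h in hits} == {"c1"}
        assert hits[0].s_interval == (2000, 2500)
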