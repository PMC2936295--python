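"""PWM construction, scanning, conservation overlap, operon expansion."""

import numpy as np
import pytest

from dinet.motifs import (
    GenomicInterval,
    MotifHit,
    build_pwm,
    best_hit,
    conservation_fraction,
    operon_expand,
    pwm_information_content,
    scan_sequence,
    validate_interaction,
)
from dinet.thresholding import Interaction, ReferenceNetwork

# deliberately non-palindromic so strand assignment is unambiguous
CONSENSUS = "ACGGTACATCAGTTGC"
COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _rc(seq):
    return seq.translate(COMPLEMENT)[::-1]


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def pwm():
    rng = np.random.default_rng(5)
    sites = []
    for _ in range(8):
        s = list(CONSENSUS)
        for i in range(len(s)):
            if rng.random() < 0.1:
                s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
        sites.append("".join(s))
    return build_pwm(sites, 0.5)


class TestBuildPwm:
    def test_zero_pseudocount_pure_counts(self):
        pwm = build_pwm(["ACGT", "ACGT"], pseudocount=0.0)
        assert pwm.probs[0, 0] == 1.0  # P(A) at position 1

    def test_pseudocount_arithmetic(self):
        pwm = build_pwm(["ACAC", "ACAC"], pseudocount=0.5)
        assert pwm.probs[0, 0] == pytest.approx(2.5 / 4.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            build_pwm(["ACGT", "ACGTG"])

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT"])

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACNT", "ACGT"])


class TestInformationContent:
    def test_uniform_deterministic_and_half_columns(self):
        pwm = build_pwm(["AAAA", "AACA", "TAGC", "CAAG"], pseudocount=0.0)
        ic = pwm_information_content(pwm)
        # column 2 is all A: 2 bits; column 1 has A,A,T,C; compute directly
        assert ic[1] == pytest.approx(2.0)
        p = np.array([0.5, 0.25, 0.0, 0.25])
        expected = 2 + sum(q * np.log2(q) for q in p if q > 0)
        assert ic[0] == pytest.approx(expected)

    def test_two_base_column_gives_one_bit(self):
        pwm = build_pwm(["AAAA", "AAAA", "CAAA", "CAAA"], pseudocount=0.0)
        assert pwm_information_content(pwm)[0] == pytest.approx(1.0)


class TestScan:
    def test_planted_consensus_is_top_hit(self, pwm, rng):
        seq = _random_seq(rng, 7) + CONSENSUS + _random_seq(rng, 40)
        top = scan_sequence(pwm, seq)[0]
        assert (top.start, top.strand) == (7, "+")

    def test_reverse_complement_found_on_minus_strand(self, pwm, rng):
        flank_a, flank_b = _random_seq(rng, 11), _random_seq(rng, 30)
        plus = flank_a + CONSENSUS + flank_b
        minus = flank_a + _rc(CONSENSUS) + flank_b
        top_plus = scan_sequence(pwm, plus)[0]
        top_minus = scan_sequence(pwm, minus)[0]
        assert top_minus.strand == "-"
        assert top_minus.start == 11
        assert top_minus.score == pytest.approx(top_plus.score, abs=1e-12)

    def test_full_hit_list_matches_bruteforce_enumeration(self, pwm, rng):
        seq = _random_seq(rng, 100)
        lo = np.log(pwm.probs / 0.25)
        expected = []
        for start in range(100 - pwm.width + 1):
            window = seq[start : start + pwm.width]
            sp = sum(lo[k, "ACGT".index(b)] for k, b in enumerate(window))
            sm = sum(lo[k, "ACGT".index(b)] for k, b in enumerate(_rc(window)))
            expected.append((start, "+", sp))
            expected.append((start, "-", sm))
        hits = scan_sequence(pwm, seq)
        assert len(hits) == len(expected)
        by_site = {(h.start, h.strand): h.score for h in hits}
        for start, strand, score in expected:
            assert by_site[start, strand] == pytest.approx(score, abs=1e-9)
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_strand_symmetry_of_whole_scan(self, pwm, rng):
        seq = _random_seq(rng, 60)
        fwd = scan_sequence(pwm, seq)
        rev = scan_sequence(pwm, _rc(seq))
        # mirrored hit list: same multiset of scores
        np.testing.assert_allclose(
            sorted(h.score for h in fwd), sorted(h.score for h in rev), atol=1e-9
        )

    def test_non_acgt_positions_scored_as_background(self, pwm):
        seq = "N" * pwm.width
        with pytest.warns(UserWarning, match="non-ACGT"):
            hits = scan_sequence(pwm, seq)
        assert hits[0].score == 0.0


class TestBestHit:
    def test_consensus_passes_default_threshold(self, pwm, rng):
        seq = _random_seq(rng, 20) + CONSENSUS + _random_seq(rng, 20)
        assert best_hit(pwm, seq) is not None

    def test_background_sequence_fails_high_threshold(self, pwm, rng):
        assert best_hit(pwm, _random_seq(rng, 100), score_threshold=1e6) is None

    def test_minus_infinity_threshold_returns_scan_top(self, pwm, rng):
        seq = _random_seq(rng, 50)
        assert best_hit(pwm, seq, score_threshold=-np.inf) == scan_sequence(pwm, seq)[0]

    def test_default_threshold_passes_all_training_sites(self, pwm):
        for site in pwm.sites:
            assert best_hit(pwm, site) is not None


class TestConservationFraction:
    def test_full_and_half_overlap(self):
        hit = MotifHit("g", 100, 120, "+", 5.0)
        assert conservation_fraction(hit, [GenomicInterval("g", 100, 120)]) == 1.0
        assert conservation_fraction(hit, [GenomicInterval("g", 110, 130)]) == 0.5

    def test_union_of_disjoint_pieces(self):
        hit = MotifHit("g", 100, 120, "+", 5.0)
        pieces = [GenomicInterval("g", 100, 105), GenomicInterval("g", 115, 130)]
        assert conservation_fraction(hit, pieces) == 0.5

    def test_invariant_to_splitting_intervals(self, rng):
        hit = MotifHit("g", 50, 70, "+", 0.0)
        for _ in range(50):
            start = int(rng.integers(30, 70))
            end = int(rng.integers(start + 2, 90))
            whole = conservation_fraction(hit, [GenomicInterval("g", start, end)])
            cut = int(rng.integers(start + 1, end))
            split = conservation_fraction(
                hit, [GenomicInterval("g", start, cut), GenomicInterval("g", cut, end)]
            )
            assert split == pytest.approx(whole, abs=1e-15)

    def test_matches_interval_union_oracle(self, rng):
        for _ in range(200):
            start = int(rng.integers(0, 380))
            hit = MotifHit("g", start, start + 20, "+", 0.0)
            ivs = []
            for _ in range(rng.integers(0, 4)):
                a = int(rng.integers(0, 395))
                b = int(rng.integers(a + 1, 400))
                ivs.append(GenomicInterval("g", a, b))
            base_covered = sum(
                1
                for pos in range(hit.start, hit.end)
                if any(iv.start <= pos < iv.end for iv in ivs)
            )
            assert conservation_fraction(hit, ivs) == pytest.approx(
                base_covered / 20, abs=1e-15
            )

    def test_other_sequences_ignored(self):
        hit = MotifHit("g", 0, 10, "+", 0.0)
        assert conservation_fraction(hit, [GenomicInterval("other", 0, 10)]) == 0.0


class TestValidateInteraction:
    def test_planted_conserved_consensus_accepted(self, pwm, rng):
        seq = _random_seq(rng, 30) + CONSENSUS + _random_seq(rng, 30)
        edge = Interaction("tfA", "gX", 2.0, False)
        rec = validate_interaction(
            edge, pwm, seq, [GenomicInterval("gX", 25, 60)]
        )
        assert rec.accepted and rec.reason == "ok"

    def test_exactly_half_conserved_rejected(self, pwm, rng):
        seq = _random_seq(rng, 30) + CONSENSUS + _random_seq(rng, 30)
        hit = best_hit(pwm, seq, score_threshold=-np.inf)
        half = GenomicInterval("gX", hit.start, hit.start + pwm.width // 2)
        rec = validate_interaction(
            Interaction("tfA", "gX", 2.0, False), pwm, seq, [half]
        )
        assert not rec.accepted
        assert rec.conservation == pytest.approx(0.5)
        assert rec.reason == "not_conserved"

    def test_no_site_above_threshold_reports_reason(self, pwm, rng):
        rec = validate_interaction(
            Interaction("tfA", "gX", 2.0, False),
            pwm,
            _random_seq(rng, 100),
            [GenomicInterval("gX", 0, 100)],
            score_threshold=1e6,
        )
        assert not rec.accepted and rec.reason == "no_site"


class TestOperonExpand:
    def test_promoter_proximal_target_expanded(self):
        accepted = [Interaction("A", "g1", 3.0, False)]
        out = operon_expand(accepted, [["g1", "g2", "g3"]])
        pairs = {(e.regulator, e.target) for e in out}
        assert pairs == {("A", "g1"), ("A", "g2"), ("A", "g3")}
        assert all(e.operon_derived for e in out if e.target != "g1")

    def test_target_not_in_operon_unchanged(self):
        accepted = [Interaction("A", "gX", 3.0, False)]
        assert operon_expand(accepted, [["g1", "g2"]]) == accepted

    def test_mid_operon_target_not_expanded(self):
        accepted = [Interaction("A", "g2", 3.0, False)]
        assert operon_expand(accepted, [["g1", "g2", "g3"]]) == accepted

    def test_reference_annotates_derived_edges(self):
        accepted = [Interaction("A", "g1", 3.0, False)]
        ref = ReferenceNetwork({("A", "g2")})
        out = operon_expand(accepted, [["g1", "g2"]], ref)
        derived = next(e for e in out if e.target == "g2")
        assert derived.known
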