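import math

import numpy as np
import pytest

from lossmark import (
    FormatError,
    HseArrayModel,
    IupacMotif,
    MotifHit,
    assign_promoter,
    build_pwm,
    calibrate_threshold,
    expand_hse_array,
    merge_nearby_hits,
    parse_pwm_text,
    regulon_precision,
    reverse_complement,
    scan_iupac,
    scan_pwm,
)
from lossmark.io_core import IUPAC_CODES, Gene, GenomeAnnotation, SequenceRecord
from lossmark.motif_models import WeightMatrix


def brute_force_scan(seq: str, motif: IupacMotif) -> list[tuple[int, str]]:
    """Independent per-window matcher: test every window on each strand,
    collapsing palindromic both-strand matches to one '+' locus."""
    L = len(motif)
    rc = IupacMotif(reverse_complement(motif.pattern))
    out = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        plus = all(b in IUPAC_CODES[c] for b, c in zip(window, motif.pattern))
        minus = all(b in IUPAC_CODES[c] for b, c in zip(window, rc.pattern))
        if plus and minus:
            out.append((i, "+"))
        elif plus:
            out.append((i, "+"))
        elif minus:
            out.append((i, "-"))
    return out


def random_pattern(rng) -> IupacMotif:
    codes = list("ACGTYRN")
    weights = [0.17, 0.17, 0.17, 0.17, 0.11, 0.11, 0.10]
    length = int(rng.integers(5, 12))
    return IupacMotif("".join(rng.choice(codes, size=length, p=weights)))


class TestScanIupac:
    def test_hand_checked_hit(self):
        hits = scan_iupac(SequenceRecord("s", "GGTTCCAGAAGG"), IupacMotif("TTCYRGAA"))
        assert [(h.start, h.end, h.strand) for h in hits] == [(2, 10, "+")]

    def test_strand_symmetry_on_reverse_complement(self):
        seq = "GGACGTTCTAGAACCTT"  # non-palindromic context
        motif = IupacMotif("TTCTAGAA")
        fwd = scan_iupac(SequenceRecord("s", seq), motif)
        rev = scan_iupac(SequenceRecord("s", reverse_complement(seq)), motif)
        assert len(fwd) == len(rev) == 1
        # mirrored coordinates
        assert rev[0].start == len(seq) - fwd[0].end

    def test_equals_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            motif = random_pattern(rng)
            hits = scan_iupac(SequenceRecord("s", seq), motif)
            assert [(h.start, h.strand) for h in hits] == brute_force_scan(seq, motif)

    def test_palindromic_count_invariant_under_genome_revcomp(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        motif = IupacMotif("TTCYRGAANNTTCYRGAA")
        assert motif.is_palindromic
        n_fwd = len(scan_iupac(SequenceRecord("s", seq), motif))
        n_rev = len(scan_iupac(SequenceRecord("s", reverse_complement(seq)), motif))
        assert n_fwd == n_rev

    def test_motif_longer_than_sequences_warns_empty(self):
        assert scan_iupac(SequenceRecord("s", "ACGT"), IupacMotif("ACGTACGT")) == []

    def test_dot_is_alias_for_n(self):
        assert IupacMotif("TTC..GAA").pattern == "TTCNNGAA"

    def test_invalid_code_rejected(self):
        with pytest.raises(FormatError):
            IupacMotif("TTCXGAA")


def test_merge_nearby_hits_collapses_adjacent_offsets():
    hits = [
        MotifHit("c", 10, 28, "+", "m"),
        MotifHit("c", 12, 30, "+", "m"),  # offset 2 < 5: merged
        MotifHit("c", 40, 58, "+", "m"),  # separate locus
    ]
    merged = merge_nearby_hits(hits)
    assert [(h.start, h.end) for h in merged] == [(10, 30), (40, 58)]


class TestPwm:
    def test_counting_with_pseudocount(self):
        pwm = build_pwm(["AC", "AG"], pseudocount=0.3)
        # position 0: A=2.3, others 0.3; position 1: C=G=1.3, A=T=0.3
        assert pwm.weights[0, 0] == pytest.approx(2.3)
        assert pwm.weights[1, 1] == pytest.approx(1.3)
        assert pwm.weights[3, 1] == pytest.approx(0.3)

    def test_zero_pseudocount_single_site_is_one_hot(self):
        pwm = build_pwm(["ACGT"], pseudocount=0.0)
        assert pwm.weights.sum() == 4
        assert pwm.score("ACGT") == 4

    def test_huge_pseudocount_approaches_uniform(self):
        pwm = build_pwm(["AAAA"], pseudocount=1e6)
        ratios = pwm.weights.max(axis=0) / pwm.weights.min(axis=0)
        assert np.allclose(ratios, 1.0, atol=1e-5)

    def test_unequal_site_lengths_rejected(self):
        with pytest.raises(FormatError):
            build_pwm(["AC", "ACG"], 0.1)

    def test_calibrated_threshold_recovers_single_training_site(self):
        pwm = calibrate_threshold(build_pwm(["ACGTAC"], 0.3), ["ACGTAC"])
        assert pwm.threshold == pytest.approx(pwm.score("ACGTAC"))
        hits = scan_pwm(SequenceRecord("s", "TTTTACGTACTTTT"), pwm)
        assert any(h.start == 4 and h.score >= pwm.threshold for h in hits)

    def test_hit_count_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        seq = "".join(
            rng.choice(list("ACGT"), size=20000, p=[0.31, 0.19, 0.19, 0.31])
        )
        sites = ["TTCTAGAA", "TTCCAGAA", "TTCTGGAA"]
        pwm = calibrate_threshold(build_pwm(sites, 0.3), sites)
        rec = SequenceRecord("s", seq)
        n_hi = len(scan_pwm(rec, pwm))
        lower = WeightMatrix(pwm.weights, pwm.pseudocount, threshold=pwm.threshold - 1)
        assert len(scan_pwm(rec, lower)) >= n_hi

    def test_all_n_genome_has_no_hits(self):
        pwm = calibrate_threshold(build_pwm(["ACGT"], 0.3), ["ACGT"])
        assert scan_pwm(SequenceRecord("s", "N" * 100), pwm) == []

    def test_infinite_threshold_empty(self):
        pwm = WeightMatrix(np.ones((4, 4)), 0.0, threshold=math.inf)
        assert scan_pwm(SequenceRecord("s", "ACGTACGT"), pwm) == []

    def test_uncalibrated_scan_is_error(self):
        with pytest.raises(FormatError, match="calibrate"):
            scan_pwm(SequenceRecord("s", "ACGT"), build_pwm(["ACGT"], 0.1))

    def test_parse_printed_digit_rows(self):
        text = (
            "T:555500000052550500000, C:000055000001005000000, "
            "G:000000050001000005005, A:000000505501000050550."
        )
        pwm = parse_pwm_text(text, pseudocount=0.3)
        assert len(pwm) == 21
        # column 0: T=5 (+psi), others psi
        assert pwm.weights[3, 0] == pytest.approx(5.3)
        assert pwm.weights[0, 0] == pytest.approx(0.3)


class TestHseArrays:
    def test_hse4_no_skips(self):
        assert expand_hse_array(HseArrayModel(4))[0].pattern == "TTCNNGAANNTTCNNGAA"

    def test_hse4_with_skipped_third_unit(self):
        assert expand_hse_array(HseArrayModel(4, {2: 0}))[0].pattern == "TTCNNGAANNNNNNNGAA"

    def test_hse5_with_partial_skip(self):
        model = HseArrayModel(5, {3: 1})  # GAA reduced to G..
        assert expand_hse_array(model)[0].pattern == "TTCNNGAANNTTCNNGNNNNTTC"

    def test_end_clipped_hse4(self):
        assert expand_hse_array(HseArrayModel(4, end_clip=(2, 2)))[0].pattern == "CNNGAANNTTCNNG"

    def test_too_many_skips_rejected(self):
        with pytest.raises(FormatError, match="3 intact"):
            HseArrayModel(4, {1: 0, 2: 0})


@pytest.fixture
def annotation():
    ann = GenomeAnnotation()
    ann.add(Gene("alpha", "chr1", "+", 1000, 1600))
    ann.add(Gene("beta", "chr1", "-", 2000, 2600))
    return ann


class TestAssignPromoter:
    def test_upstream_hit_assigned_with_distance(self, annotation):
        hit = MotifHit("chr1", 782, 800, "+", "m")  # ends 200 bp before ORF
        (a,) = assign_promoter([hit], annotation, 1000)
        assert (a.gene_id, a.zone, a.distance) == ("alpha", "promoter", 200)

    def test_cds_overlap_wins(self, annotation):
        (a,) = assign_promoter([MotifHit("chr1", 1100, 1118, "+", "m")], annotation)
        assert (a.gene_id, a.zone) == ("alpha", "CDS")

    def test_minus_strand_upstream_is_right_of_cds(self, annotation):
        hit = MotifHit("chr1", 2700, 2718, "+", "m")  # 100 bp right of beta's ORF end
        (a,) = assign_promoter([hit], annotation)
        assert (a.gene_id, a.zone, a.distance) == ("beta", "promoter", 100)

    def test_far_hit_is_intergenic(self, annotation):
        (a,) = assign_promoter([MotifHit("chr1", 4000, 4018, "+", "m")], annotation)
        assert (a.gene_id, a.zone) == (None, "intergenic")

    def test_equidistant_divergent_genes_tie_breaks_lexicographically(self):
        ann = GenomeAnnotation()
        ann.add(Gene("zeta", "chr1", "-", 0, 100))  # upstream side right of 100
        ann.add(Gene("eta", "chr1", "+", 320, 400))  # upstream side left of 320
        hit = MotifHit("chr1", 200, 220, "+", "m")  # 100 from both ORF starts
        (a,) = assign_promoter([hit], ann, 1000)
        assert a.gene_id == "eta"  # 'eta' < 'zeta'


class TestRegulonPrecision:
    def _mk(self, gene, zone):
        return_hit = MotifHit("c", 0, 10, "+", "m")
        from lossmark.motif_models import LocusAssignment

        return LocusAssignment(return_hit, gene, zone, 100 if zone == "promoter" else None)

    def test_two_of_two(self):
        assignments = [self._mk("HSP104", "promoter"), self._mk("HSP78", "promoter")]
        assert regulon_precision(assignments, {"HSP104", "HSP78"}) == (2, 2, 1.0)

    def test_cds_hits_count_in_denominator_only(self):
        assignments = [self._mk(g, "promoter") for g in "ABCD"] + [self._mk("X", "CDS")]
        num, den, prec = regulon_precision(assignments, {"A", "B"})
        assert (num, den) == (2, 5)
        assert prec == pytest.approx(0.4)

    def test_adding_cds_hit_never_increases_precision(self):
        base = [self._mk("A", "promoter"), self._mk("B", "promoter")]
        _, _, p0 = regulon_precision(base, {"A"})
        _, _, p1 = regulon_precision(base + [self._mk("Y", "CDS")], {"A"})
        assert p1 <= p0

    def test_empty_assignments_flagged_undefined(self):
        num, den, prec = regulon_precision([], {"A"})
        assert (num, den) == (0, 0) and math.isnan(prec)
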