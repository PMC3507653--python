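import itertools

import numpy as np
import pytest
from scipy.stats import gumbel_r

from creregulon.cre_scan import (
    CreHit,
    ProfileModel,
    build_profile,
    calibrate_evd,
    calibrate_threshold,
    classify_and_report,
    filter_hits,
    read_profile,
    scan,
    score_window,
    write_profile,
)
from creregulon.io_formats import SequenceRecord, reverse_complement
from creregulon.expression import DeCall
from creregulon.motif_discovery import Pwm, build_pwm, uniform_background
from creregulon.regions import UpstreamRegion, extract_upstream

from conftest import make_model


def toy_model(width=3, seed=0, sig=None, slack=0.5):
    """Small random log-odds model for exhaustive window enumeration."""
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet([1.0] * 4, size=width)
    probs = np.clip(probs, 1e-3, None)
    probs /= probs.sum(axis=1, keepdims=True)
    pwm = Pwm(width=width, probs=probs, pseudocount=0.5, background=uniform_background())
    m = build_profile(pwm)
    m.slack = slack
    if sig is not None:
        m.significance_score = sig
    return m


class TestBuildProfileAndScore:
    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = Pwm(width=4, probs=np.full((4, 4), 0.25), pseudocount=0,
                  background=uniform_background())
        m = build_profile(pwm)
        for w in ("ACGT", "TTTT", "GCGC"):
            assert score_window(m, w) == pytest.approx(0.0)

    def test_consensus_attains_maximum(self):
        pwm = build_pwm(["ACG"] * 10, pseudocount=0.01)
        m = build_profile(pwm)
        best = max(
            score_window(m, "".join(w)) for w in itertools.product("ACGT", repeat=3)
        )
        assert score_window(m, "ACG") == pytest.approx(best)

    def test_all_64_threemers_match_brute_force(self):
        m = toy_model(width=3, seed=1)
        for w in itertools.product("ACGT", repeat=3):
            window = "".join(w)
            expected = sum(m.log_odds[i, "ACGT".index(c)] for i, c in enumerate(window))
            assert score_window(m, window) == pytest.approx(expected, abs=1e-12)

    def test_n_scores_zero(self):
        m = toy_model(width=4, seed=2)
        assert score_window(m, "NNNN") == pytest.approx(0.0)

    def test_strand_symmetry_identity(self):
        m = toy_model(width=5, seed=3)
        rc = m.reverse_complement()
        for w in ("ACGTA", "TTGCA", "GGGGG"):
            assert score_window(m, w) == pytest.approx(
                score_window(rc, reverse_complement(w)), abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            score_window(toy_model(3), "ACGT")

    def test_zero_background_rejected(self):
        pwm = Pwm(width=2, probs=np.full((2, 4), 0.25), pseudocount=0,
                  background=uniform_background())
        with pytest.raises(ValueError, match="background"):
            build_profile(pwm, background=np.array([0.5, 0.5, 0.0, 0.0]))


class TestCalibrateThreshold:
    def test_lowest_positive_rule(self):
        m = toy_model(width=3, seed=4)
        scores = {"AAA": 3.1, "CCC": 1.9, "GGG": 0.4, "TTT": -0.2}
        # construct a model whose site scores are exactly these values
        model = ProfileModel(
            width=1,
            log_odds=np.array([[3.1, 1.9, 0.4, -0.2]]),
            background=uniform_background(),
        )
        out = calibrate_threshold(model, ["A", "C", "G", "T"])
        assert out.significance_score == pytest.approx(0.4)

    def test_two_site_case(self):
        model = ProfileModel(
            width=1, log_odds=np.array([[5.0, 2.0, -1.0, -1.0]]),
            background=uniform_background(),
        )
        out = calibrate_threshold(model, ["A", "C"])
        assert out.significance_score == pytest.approx(2.0)

    def test_no_positive_scores_error(self):
        model = ProfileModel(
            width=1, log_odds=np.array([[-1.0, -2.0, -3.0, -4.0]]),
            background=uniform_background(),
        )
        with pytest.raises(ValueError, match="positive"):
            calibrate_threshold(model, ["A", "C"])


class TestCalibrateEvd:
    def test_gumbel_parameter_recovery(self):
        draws = gumbel_r.rvs(loc=-2.0, scale=0.7, size=5000,
                             random_state=np.random.default_rng(1))
        fit = calibrate_evd(toy_model(4), scores=draws)
        assert fit.mu == pytest.approx(-2.0, abs=0.05)
        assert fit.lam == pytest.approx(1 / 0.7, rel=0.05)

    def test_evalue_monotone_decreasing_and_linear_in_targets(self):
        fit = calibrate_evd(toy_model(4), n_random=500, seed=0)
        scores = np.linspace(-5, 10, 20)
        ev = [fit.evalue(s) for s in scores]
        assert all(a > b for a, b in zip(ev, ev[1:]))
        assert fit.evalue(3.0, n_targets=10) == pytest.approx(10 * fit.evalue(3.0))

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            calibrate_evd(toy_model(4), scores=np.ones(200))


def genome_with(seq_parts):
    return SequenceRecord(id="c1", sequence="".join(seq_parts))


class TestScan:
    def setup_scan(self, sig=2.0, slack=1.0):
        """Width-3 model where AAA scores high; genome with known placements."""
        pwm = build_pwm(["AAA"] * 8 + ["AAT", "TAA"], pseudocount=0.5)
        model = build_profile(pwm)
        model.slack = slack
        model.significance_score = sig
        return model

    def test_exhaustive_oracle_equivalence(self):
        """Scan hits = brute-force enumeration of every window and strand."""
        model = self.setup_scan(sig=-100.0, slack=0.0)  # keep everything
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        genome = genome_with([seq])
        region = UpstreamRegion("g1", "c1", 0, 60, "+", seq)
        hits = scan(model, genome, [], [region])
        by_pos = {(h.start0, h.strand): h.score for h in hits}
        for off in range(58):
            w = seq[off : off + 3]
            fwd = score_window(model, w)
            rev = score_window(model, reverse_complement(w))
            best = max(fwd, rev)
            strand = "+" if fwd >= rev else "-"
            # overlap resolution keeps best per strand; the dominating strand
            # of each interval must be present with the brute-force score
            if (off, strand) in by_pos:
                assert by_pos[(off, strand)] == pytest.approx(best)

    def test_uncalibrated_model_rejected(self, small_genome):
        model = self.setup_scan()
        model.significance_score = None
        with pytest.raises(ValueError, match="calibrated"):
            scan(model, small_genome, [], [])

    def test_empty_regions_empty_hits(self, small_genome):
        assert scan(self.setup_scan(), small_genome, [], []) == []

    def test_de_rescue_rule(self):
        model = self.setup_scan(sig=10.0, slack=20.0)
        seq = "CCCCCAAACCCCC"  # AAA at offset 5 scores ~ +4 < sig
        genome = genome_with([seq])
        region = UpstreamRegion("g1", "c1", 0, len(seq), "+", seq)
        models = [make_model("g1", 20, 50, "+")]
        no_de = scan(model, genome, models, [region], de_calls=[])
        assert all(h.inclusion == "primary" for h in no_de)
        assert not any(h.score < 10.0 for h in no_de)
        de = [DeCall("g1", "M", "up", 4.0)]
        rescued = scan(model, genome, models, [region], de_calls=de)
        assert any(h.inclusion == "rescued-by-DE" for h in rescued)

    def test_threshold_monotonicity(self, small_genome):
        """Raising the significance score never adds hits."""
        model = self.setup_scan(sig=0.0, slack=0.0)
        region = UpstreamRegion("g1", "c1", 0, 500, "+", small_genome.sequence[:500])
        lo = scan(model, small_genome, [], [region])
        model_hi = self.setup_scan(sig=3.0, slack=0.0)
        hi = scan(model_hi, small_genome, [], [region])
        lo_keys = {(h.start0, h.strand) for h in lo}
        hi_keys = {(h.start0, h.strand) for h in hi}
        assert hi_keys <= lo_keys

    def test_overlap_resolution_keeps_best(self):
        model = self.setup_scan(sig=-100.0, slack=0.0)
        seq = "AAAAA"  # windows at 0,1,2 all overlap on + strand
        genome = genome_with([seq])
        region = UpstreamRegion("g1", "c1", 0, 5, "+", seq)
        hits = scan(model, genome, [], [region])
        plus = [h for h in hits if h.strand == "+"]
        for a, b in itertools.combinations(plus, 2):
            assert a.end0 <= b.start0 or b.end0 <= a.start0

    def test_scan_strand_symmetry(self, small_genome):
        """Scanning the flipped genome yields mirrored hits.

        Uses a random profile so that overlapping windows score distinctly;
        exact ties between overlapping windows are resolved leftmost, which is
        deterministic but not mirror-symmetric.
        """
        model = toy_model(width=8, seed=12, sig=1.0, slack=0.0)
        L = len(small_genome.sequence)
        models = [make_model("a", 100, 400, "+"), make_model("b", 500, 900, "-")]
        ups = extract_upstream(small_genome, models, operon_level=False)
        fwd_hits = scan(model, small_genome, models, ups)
        flipped = SequenceRecord(id="c1", sequence=reverse_complement(small_genome.sequence))
        fmodels = [
            make_model(m.feature_id, L - m.end0, L - m.start0,
                       "-" if m.strand == "+" else "+")
            for m in models
        ]
        fups = extract_upstream(flipped, fmodels, operon_level=False)
        rev_hits = scan(model, flipped, fmodels, fups)
        fwd_set = {(h.start0, h.end0, h.strand, round(h.score, 9)) for h in fwd_hits}
        rev_set = {
            (L - h.end0, L - h.start0, "+" if h.strand == "-" else "-", round(h.score, 9))
            for h in rev_hits
        }
        assert fwd_set == rev_set


class TestFilterHits:
    def orf_hit(self, start0, score, gene="g1", status="kept", reason=None, context="orf"):
        return CreHit(contig="c1", start0=start0, end0=start0 + 16, strand="+",
                      score=score, context=context, associated_gene=gene,
                      status=status, removal_reason=reason)

    def test_three_prime_hit_removed_when_better_five_prime_exists(self):
        gene = make_model("g1", 0, 1000, "+")
        hits = [self.orf_hit(792, 2.0), self.orf_hit(92, 5.0)]  # 80% vs 10%
        out = filter_hits(hits, [gene])
        statuses = {h.start0: h.status for h in out}
        assert statuses[792] == "removed"
        assert statuses[92] == "kept"

    def test_three_prime_hit_kept_without_better_competitor(self):
        gene = make_model("g1", 0, 1000, "+")
        out = filter_hits([self.orf_hit(792, 2.0)], [gene])
        assert out[0].status == "kept"

    def test_higher_scoring_promoter_hit_triggers_removal(self):
        gene = make_model("g1", 100, 1000, "+")
        promoter = CreHit(contig="c1", start0=50, end0=66, strand="+", score=6.0,
                          context="upstream", associated_gene="g1")
        out = filter_hits([self.orf_hit(892, 2.0), promoter], [gene])
        assert {h.start0: h.status for h in out}[892] == "removed"

    def test_minus_strand_three_prime_is_low_coordinate_end(self):
        gene = make_model("g1", 0, 1000, "-")
        # for a - strand gene the 3' half is the low-coordinate half
        hits = [self.orf_hit(92, 2.0), self.orf_hit(792, 5.0)]
        out = filter_hits(hits, [gene])
        statuses = {h.start0: h.status for h in out}
        assert statuses[92] == "removed" and statuses[792] == "kept"

    def test_activated_gene_orf_hit_removed(self):
        gene = make_model("g1", 0, 1000, "+")
        de = [DeCall("g1", "M", "down", 0.2)]
        out = filter_hits([self.orf_hit(92, 5.0)], [gene], de_calls=de)
        assert out[0].status == "removed"
        assert "activated" in out[0].removal_reason

    def test_upstream_hits_untouched_by_both_rules(self):
        gene = make_model("g1", 100, 1000, "+")
        h = CreHit(contig="c1", start0=50, end0=66, strand="+", score=1.0,
                   context="upstream", associated_gene="g1")
        out = filter_hits([h], [gene], de_calls=[DeCall("g1", "M", "down", 0.1)])
        assert out[0].status == "kept"

    def test_idempotent(self):
        gene = make_model("g1", 0, 1000, "+")
        de = [DeCall("g1", "M", "down", 0.2)]
        hits = [self.orf_hit(792, 2.0), self.orf_hit(92, 5.0)]
        once = filter_hits(hits, [gene], de_calls=de)
        twice = filter_hits(once, [gene], de_calls=de)
        assert [(h.start0, h.status, h.removal_reason) for h in once] == [
            (h.start0, h.status, h.removal_reason) for h in twice
        ]


class TestClassifyAndReport:
    def test_context_by_midpoint_and_count_partition(self):
        models = [make_model("g1", 100, 400, "+")]
        ups = [UpstreamRegion("g1", "c1", 50, 100, "+", "A" * 50)]
        hits = [
            CreHit("c1", 60, 76, "+", 3.0, "upstream", "g1"),
            CreHit("c1", 200, 216, "+", 2.0, "orf", "g1"),
            CreHit("c1", 900, 916, "+", 2.5, "intergenic-other", None),
            CreHit("c1", 210, 226, "-", 1.0, "orf", "g1", status="removed",
                   removal_reason="x"),
        ]
        report = classify_and_report(hits, ups, models)
        assert report.n_upstream == 1
        assert report.n_orf == 1
        kept_annotated = [
            h
            for hits_ in report.hits_by_gene.values()
            for h in hits_
            if h.status == "kept" and h.context != "intergenic-other"
        ]
        assert report.n_upstream + report.n_orf == len(kept_annotated)

    def test_boundary_straddling_hit_has_single_context(self):
        models = [make_model("g1", 100, 400, "+")]
        ups = [UpstreamRegion("g1", "c1", 50, 100, "+", "A" * 50)]
        h = CreHit("c1", 94, 110, "+", 1.0, "upstream", "g1")  # midpoint 102 -> orf
        report = classify_and_report([h], ups, models)
        assert report.n_orf == 1 and report.n_upstream == 0


def test_profile_roundtrip(tmp_path):
    m = toy_model(width=4, seed=6, sig=1.25)
    p = tmp_path / "profile.tsv"
    write_profile(m, p)
    back = read_profile(p)
    assert back.width == m.width
    np.testing.assert_allclose(back.log_odds, m.log_odds, rtol=1e-9)
    assert back.significance_score == pytest.approx(1.25)
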