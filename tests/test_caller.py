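"""Caller core: realignment, poly tracts, clustering, resolution,
transduction attribution, somatic status, intersection, binomial CI."""

import numpy as np
import pytest
from scipy import stats

from l1recall import caller, evidence, sim
from l1recall.caller import RTCall
from l1recall.evidence import ClipEvidence, DiscordantEvidence, L1Interval


class TestRealignClip:
    def test_exact_substring_maps_forward(self, consensus):
        clip = consensus.sequence[2400:2460]
        aln = caller.realign_clip(clip, consensus)
        assert aln is not None
        assert aln.orientation == "+"
        assert aln.c_start == 2400 and aln.c_end == 2460
        assert aln.identity == 1.0

    def test_reverse_complement_maps_minus(self, consensus):
        clip = sim.revcomp(consensus.sequence[100:160])
        aln = caller.realign_clip(clip, consensus)
        assert aln is not None
        assert aln.orientation == "-"
        assert aln.c_start == 100

    def test_random_sequence_rejected(self, consensus):
        rng = np.random.default_rng(42)
        rejected = 0
        for _ in range(100):
            clip = sim.random_sequence(60, rng)
            if caller.realign_clip(clip, consensus) is None:
                rejected += 1
        # empirical null: a random 60-mer essentially never reaches the
        # score threshold against an unrelated consensus
        assert rejected >= 99


class TestDetectPolyTract:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("T" * 15, "polyT"),
            ("A" * 15, "polyA"),
            ("ACGTACGTACGT", "none"),
            ("TTTTTTTTTCTTTTTTTTTC", "polyT"),  # 18 T + 2 C: purity 0.9
            ("T" * 7, "none"),                  # below min length
        ],
    )
    def test_prefix_detection(self, seq, expected):
        assert caller.detect_poly_tract(seq, min_len=10, purity=0.8) == expected or (
            len(seq) < 10 and expected == "none"
        )

    def test_suffix_end(self):
        assert caller.detect_poly_tract("GCGCGC" + "A" * 12, end="suffix") == "polyA"
        assert caller.detect_poly_tract("GCGCGC" + "A" * 12, end="prefix") == "none"

    def test_total_function_on_junk(self):
        for s in ("", "N", "A", "X" * 40):
            assert caller.detect_poly_tract(s) in ("polyA", "polyT", "none")


def _clip(pos, side, seq="G" * 30, chrom="chr1", rid="r"):
    return ClipEvidence(rid, chrom, pos, side, seq)


class TestClusterEvidence:
    def test_two_right_clips_same_position_merge(self):
        clusters = caller.cluster_evidence(
            [_clip(1000, "right", rid="a"), _clip(1000, "right", rid="b")]
        )
        assert len(clusters) == 1
        assert clusters[0].clip_support == 2

    def test_distant_clips_stay_separate(self):
        clusters = caller.cluster_evidence(
            [_clip(1000, "right"), _clip(1200, "right")], window=50
        )
        assert len(clusters) == 2

    def test_left_right_pairing_within_max_tsd(self):
        clusters = caller.cluster_evidence(
            [_clip(1000, "left"), _clip(1015, "right")], max_tsd=30
        )
        assert len(clusters) == 1
        c = clusters[0]
        assert c.left_bp == 1000 and c.right_bp == 1015

    def test_empty_input_empty_output(self):
        assert caller.cluster_evidence([]) == []

    def test_discordants_attached_within_window(self):
        disc = [DiscordantEvidence("d", "chr1", 1300, "+", "L1_a")]
        clusters = caller.cluster_evidence(
            [_clip(1000, "left"), _clip(1010, "left")], disc, discordant_window=800
        )
        assert len(clusters[0].discordants) == 1


def _simulate_and_call(genome, sources, consensus, specs, seed=33, coverage=30,
                       error=0.0):
    hap, truths = sim.apply_insertions(genome, specs, consensus, sources, "t")
    frags = sim.simulate_reads(
        [hap], sim.ReadSimParams(coverage=coverage, seed=seed, base_error_rate=error)
    )
    import io, tempfile, os

    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "t.sam")
        sim.oracle_align(frags, [hap], len(genome), sources, path)
        recs = list(evidence.iter_records(path))
    clips = evidence.extract_clips(recs)
    ivs = [L1Interval(s.id, s.chrom, s.start, s.end) for s in sources]
    disc = evidence.extract_discordant(recs, ivs)
    clusters = caller.cluster_evidence(clips, disc)
    calls = [
        c for c in (caller.resolve_call(cl, consensus) for cl in clusters) if c
    ]
    return caller.mask_l1_regions(calls, ivs), truths


class TestResolveCall:
    def test_canonical_length_and_tsd_recovered(self, reference, consensus):
        genome, sources = reference
        specs = [
            sim.InsertionSpec("chr1", 40_000, 12, "+", 1500, polyA_len=14),
            sim.InsertionSpec("chr1", 90_000, 7, "-", 2200, polyA_len=14),
        ]
        calls, truths = _simulate_and_call(genome, sources, consensus, specs)
        for t in truths:
            m = [c for c in calls if abs(c.pos0 - t.left_bp) <= 5]
            assert m, f"missed insertion at {t.left_bp}"
            assert m[0].call_class == "canonical"
            assert m[0].inserted_length == t.spec.inserted_len
            assert m[0].tsd_len == t.spec.tsd_len
            assert m[0].polyA_support

    def test_inversion_class_and_second_priming(self, reference, consensus):
        genome, sources = reference
        L = consensus.length
        j = L - 700
        specs = [
            sim.InsertionSpec(
                "chr1", 40_000, 10, "+", 1800, inversion_junction=j, polyA_len=14
            )
        ]
        calls, truths = _simulate_and_call(genome, sources, consensus, specs)
        m = [c for c in calls if abs(c.pos0 - 40_000) <= 5]
        assert m and m[0].call_class == "inversion"
        assert m[0].inserted_length is None
        assert abs(m[0].second_priming - j) <= 5

    def test_min_support_gate(self, consensus):
        cl = caller.BreakpointCluster(
            "chr1", 1000, 1010, [_clip(1000, "left", consensus.sequence[:40])], []
        )
        assert caller.resolve_call(cl, consensus) is None  # 1 clip, 0 discordant


class TestAttributeTransduction:
    def test_simulated_transduction_assigned_to_source(self, reference, consensus):
        genome, sources = reference
        specs = [
            sim.InsertionSpec(
                "chr1", 40_000, 10, "+", 2000, polyA_len=14,
                transduction_source=sources[1].id, transduction_len=150,
            )
        ]
        calls, truths = _simulate_and_call(genome, sources, consensus, specs)
        m = [c for c in calls if abs(c.pos0 - 40_000) <= 5]
        assert m
        call = caller.attribute_transduction(
            m[0], consensus, genome, sources,
            [L1Interval(s.id, s.chrom, s.start, s.end) for s in sources],
        )
        assert call.transduction is not None
        assert call.transduction.source_id == sources[1].id

    def test_sources_within_1kb_grouped(self, reference, consensus):
        genome, sources = reference
        src = sources[0]
        twin = sim.SourceLocus(
            "twin", src.chrom, src.start - 800, src.end - 800, "+",
            genome[src.end - 800 : src.end - 800 + 300],
        )
        registry = [src, twin]
        specs = [
            sim.InsertionSpec(
                "chr1", 40_000, 10, "+", 2000, polyA_len=14,
                transduction_source=src.id, transduction_len=150,
            )
        ]
        calls, _ = _simulate_and_call(genome, sources, consensus, specs)
        m = [c for c in calls if abs(c.pos0 - 40_000) <= 5]
        call = caller.attribute_transduction(m[0], consensus, genome, registry)
        assert call.transduction is not None
        assert call.transduction.source_id == f"{src.id}+twin"

    def test_segment_in_l1_annotation_keeps_call_drops_annotation(
        self, reference, consensus
    ):
        genome, sources = reference
        src = sources[0]
        specs = [
            sim.InsertionSpec(
                "chr1", 40_000, 10, "+", 2000, polyA_len=14,
                transduction_source=src.id, transduction_len=150,
            )
        ]
        calls, _ = _simulate_and_call(genome, sources, consensus, specs)
        m = [c for c in calls if abs(c.pos0 - 40_000) <= 5]
        # annotate the landing region itself as L1 sequence
        blocking = [L1Interval("L1_block", src.chrom, src.end, src.end + 500)]
        call = caller.attribute_transduction(
            m[0], consensus, genome, sources, blocking
        )
        assert call is m[0]                      # the RT call is kept
        assert call.transduction.source_id is None
        assert call.transduction.multimap


def _call(pos, sample="s1", chrom="chr1", cls="canonical"):
    return RTCall(sample, chrom, pos, cls, None, None, False, 2, 0)


class TestClassifySomatic:
    def test_normal_clip_marks_pseudo_germline(self):
        calls = [_call(1001)]
        normal = [_clip(1010, "left")]
        caller.classify_somatic(calls, normal, [], normal_depth=lambda c, p: 30)
        assert calls[0].status == "pseudo-germline"

    def test_no_support_good_coverage_is_somatic(self):
        calls = [_call(1001)]
        caller.classify_somatic(calls, [], [], normal_depth=lambda c, p: 30)
        assert calls[0].status == "somatic"

    def test_zero_normal_coverage_unresolved(self):
        calls = [_call(1001)]
        caller.classify_somatic(calls, [], [], normal_depth=lambda c, p: 0)
        assert calls[0].status == "unresolved"

    def test_missing_normal_errors(self):
        with pytest.raises(ValueError):
            caller.classify_somatic([_call(1)], None)

    def test_status_partition(self, reference, consensus):
        genome, sources = reference
        specs = [
            sim.InsertionSpec("chr1", 30_000, 8, "+", 1500),
            sim.InsertionSpec("chr1", 90_000, 8, "-", 2500),
        ]
        calls, _ = _simulate_and_call(genome, sources, consensus, specs)
        caller.classify_somatic(calls, [], [], normal_depth=lambda c, p: 30)
        assert all(
            c.status in ("somatic", "pseudo-germline", "unresolved") for c in calls
        )


class TestIntersectCallsets:
    def test_offsets_against_window_rule(self):
        offsets = [0, 10, 49, 50, 51, 100]
        a = [_call(10_000 + 1000 * i) for i in range(len(offsets))]
        b = [_call(10_000 + 1000 * i + off) for i, off in enumerate(offsets)]
        res = caller.intersect_callsets(a, b, window=50)
        assert len(res["shared"]) == 4            # offsets 0, 10, 49, 50
        assert len(res["a_only"]) == 2
        assert len(res["b_only"]) == 2

    def test_different_samples_never_shared(self):
        res = caller.intersect_callsets(
            [_call(1000, sample="s1")], [_call(1000, sample="s2")]
        )
        assert res["shared"] == []

    def test_self_intersection_all_shared(self):
        a = [_call(1000 * i) for i in range(1, 6)]
        res = caller.intersect_callsets(a, list(a))
        assert len(res["shared"]) == 5
        assert res["a_only"] == [] and res["b_only"] == []

    def test_symmetric_under_swap(self):
        a = [_call(1000), _call(5000)]
        b = [_call(1020), _call(9000)]
        ab = caller.intersect_callsets(a, b)
        ba = caller.intersect_callsets(b, a)
        assert len(ab["shared"]) == len(ba["shared"]) == 1
        assert [c.position for c in ab["a_only"]] == [
            c.position for c in ba["b_only"]
        ]

    def test_duplicate_ids_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            caller.intersect_callsets([_call(1000), _call(1000)], [])


def _grid_oracle(k, n, level=0.99, resolution=1e-5):
    """Brute-force Clopper-Pearson: scan a p-grid for binomial tail crossings."""
    alpha = (1 - level) / 2
    grid = np.arange(0.0, 1.0 + resolution, resolution)
    upper_tail = stats.binom.sf(k - 1, n, grid)   # P(X >= k)
    lower_tail = stats.binom.cdf(k, n, grid)      # P(X <= k)
    lo = 0.0 if k == 0 else grid[upper_tail >= alpha].min()
    hi = 1.0 if k == n else grid[lower_tail >= alpha].max()
    return lo, hi


class TestInversionRateCI:
    def test_boundary_cases(self):
        assert caller.inversion_rate_ci(0, 10)[0] == 0.0
        assert caller.inversion_rate_ci(10, 10)[1] == 1.0

    def test_matches_grid_search_oracle(self):
        lo, hi = caller.inversion_rate_ci(5, 10, level=0.99)
        olo, ohi = _grid_oracle(5, 10)
        assert lo == pytest.approx(olo, abs=1e-4)
        assert hi == pytest.approx(ohi, abs=1e-4)

    def test_interval_contains_point_estimate(self):
        for n in (1, 7, 30):
            for k in range(n + 1):
                lo, hi = caller.inversion_rate_ci(k, n)
                assert lo <= k / n <= hi

    def test_n_zero_undefined(self):
        with pytest.raises(ValueError):
            caller.inversion_rate_ci(0, 0)
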