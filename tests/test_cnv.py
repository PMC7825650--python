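"""Segmentation, classification, filtering, and gene-level CNV summaries."""

import itertools

import numpy as np
import pytest

from pgxcombine import (
    ClassifierThresholds,
    CnvStatus,
    GadaSegmenter,
    GeneRegion,
    ProbeSeries,
    Segment,
    SegmentationParams,
    backward_eliminate,
    classify_segment,
    cnv_frequency_table,
    filter_regions,
    gene_cnv_status,
    sbl_segment,
    segment_series,
)


def _make_segment(mean, start=1000, end=5000, chrom="1", n_probes=10, status=None):
    seg = Segment(
        chrom=chrom, start_pos=start, end_pos=end,
        n_probes=n_probes, mean_log2=mean,
    )
    return classify_segment(seg) if status is None else seg


class TestSblSegment:
    def test_constant_series_has_no_surviving_breakpoints(self):
        fit = sbl_segment(np.zeros(24), SegmentationParams())
        bps = backward_eliminate(np.zeros(24), fit.active, fit.sigma2)
        assert bps == []

    def test_noiseless_step_puts_dominant_weight_at_breakpoint(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        fit = sbl_segment(y, SegmentationParams())
        assert np.argmax(np.abs(fit.weights)) + 1 == 10
        assert fit.sigma2 < 1e-6

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            sbl_segment(np.zeros(8), SegmentationParams(min_seg_len=6))

    def test_nonfinite_rejected(self):
        y = np.zeros(20)
        y[3] = np.nan
        with pytest.raises(ValueError):
            sbl_segment(y, SegmentationParams())


class TestBackwardElimination:
    def test_no_significant_breakpoint_gives_single_segment(self, rng):
        y = rng.normal(0, 0.15, 30)
        seg = GadaSegmenter().fit(y)
        assert seg.breakpoints_ == []
        assert len(seg.segments_) == 1

    def test_noiseless_staircase_recovers_exact_segments(self):
        y = np.r_[np.zeros(8), 0.5 * np.ones(8), 1.5 * np.ones(8)]
        seg = GadaSegmenter(min_seg_len=6).fit(y)
        assert seg.breakpoints_ == [8, 16]
        assert [s.mean_log2 for s in seg.segments_] == [0.0, 0.5, 1.5]
        assert [s.n_probes for s in seg.segments_] == [8, 8, 8]

    def test_min_seg_len_enforced(self, rng):
        y = np.r_[np.zeros(20), np.ones(3), np.zeros(20)] + rng.normal(0, 0.05, 43)
        seg = GadaSegmenter(min_seg_len=6).fit(y)
        assert all(s.n_probes >= 6 for s in seg.segments_)

    def test_surviving_breakpoints_exceed_threshold(self, rng):
        params = SegmentationParams()
        y = np.r_[np.zeros(15), np.ones(15)] + rng.normal(0, 0.15, 30)
        seg = GadaSegmenter().fit(y)
        from pgxcombine.cnv import _t_scores

        if seg.breakpoints_:
            t = _t_scores(y, seg.breakpoints_, np.sqrt(seg.sigma2_))
            assert (t >= params.T).all()

    def test_partition_property(self, rng):
        """Segments are contiguous, non-overlapping, and cover all probes."""
        for trial in range(5):
            y = rng.normal(0, 0.2, 40)
            y[10:20] += rng.choice([-1.0, 1.0])
            seg = GadaSegmenter().fit(y)
            covered = []
            for s in seg.segments_:
                covered.extend(range(s.start_idx, s.end_idx + 1))
            assert covered == list(range(40))


def _min_rss_oracle(y: np.ndarray, k: int) -> list[int]:
    """Exhaustive minimum-RSS segmentation with exactly k breakpoints."""
    best, best_rss = [], np.inf
    for bps in itertools.combinations(range(1, y.size), k):
        bounds = [0, *bps, y.size]
        rss = sum(
            ((y[a:b] - y[a:b].mean()) ** 2).sum()
            for a, b in zip(bounds[:-1], bounds[1:])
        )
        if rss < best_rss - 1e-12:
            best_rss, best = rss, list(bps)
    return best


class TestRssOracleEquivalence:
    @pytest.mark.parametrize("m", [8, 10, 12])
    @pytest.mark.parametrize("cuts", [(3,), (4, 8), (2, 6)])
    def test_noiseless_instances_match_min_rss(self, m, cuts):
        """On short noiseless series the segmentation equals the exhaustive
        minimum-RSS solution with the same number of breakpoints."""
        cuts = tuple(c for c in cuts if c < m - 1)
        y = np.zeros(m)
        level = 0.0
        for i, c in enumerate(cuts):
            level += 1.0 if i % 2 == 0 else -2.0
            y[c:] = level
        seg = GadaSegmenter(min_seg_len=2).fit(y)
        k = len(seg.breakpoints_)
        assert seg.breakpoints_ == _min_rss_oracle(y, k)
        assert k == len(cuts)


class TestClassifySegment:
    @pytest.mark.parametrize(
        "mean, expected",
        [
            (0.0, CnvStatus.NEUTRAL),
            (0.30, CnvStatus.GAIN),
            (-0.85, CnvStatus.DELETION),
            (-1.0, CnvStatus.DELETION),
            (-0.4, CnvStatus.LOSS),
            (0.4, CnvStatus.GAIN),
            (1.0, CnvStatus.AMPLIFICATION),
            # boundary semantics: cutoffs belong to the outer class
            (0.25, CnvStatus.GAIN),
            (0.8, CnvStatus.AMPLIFICATION),
            (-0.25, CnvStatus.LOSS),
            (-0.8, CnvStatus.DELETION),
            (0.2499, CnvStatus.NEUTRAL),
            (-0.2499, CnvStatus.NEUTRAL),
        ],
    )
    def test_classification(self, mean, expected):
        assert classify_segment(mean) is expected

    def test_partition_is_total_and_exclusive(self):
        """Every mean on a fine grid lands in exactly one status class."""
        for mean in np.linspace(-2, 2, 1601):
            status = classify_segment(float(mean))
            assert isinstance(status, CnvStatus)
        statuses = {classify_segment(m).value for m in (-1, -0.4, 0, 0.4, 1)}
        assert statuses == {"deletion", "loss", "neutral", "gain", "amplification"}

    def test_nonfinite_mean_rejected(self):
        with pytest.raises(ValueError):
            classify_segment(float("nan"))


class TestFilterRegions:
    def test_neutral_dropped(self):
        assert filter_regions([_make_segment(0.0)]) == []

    def test_exactly_50_bp_dropped(self):
        seg = _make_segment(0.4, start=1000, end=1049)  # spans exactly 50 bp
        assert seg.length_bp == 50
        assert filter_regions([seg]) == []
        kept = _make_segment(0.4, start=1000, end=1050)  # 51 bp
        assert filter_regions([kept]) == [kept]

    def test_hand_enumerated_set(self):
        segs = [
            _make_segment(0.4, 1000, 2000),    # keep
            _make_segment(0.0, 3000, 4000),    # neutral -> drop
            _make_segment(-0.9, 5000, 5049),   # 50 bp -> drop
            _make_segment(-0.3, 6000, 7000),   # keep
            _make_segment(1.2, 8000, 9000),    # keep
        ]
        assert filter_regions(segs) == [segs[0], segs[3], segs[4]]


class TestGeneCnvStatus:
    REGION = GeneRegion("G", "1", 10_000, 20_000, pad=0)

    def test_no_overlap_is_neutral(self):
        statuses, summary = gene_cnv_status(
            [_make_segment(0.4, 30_000, 40_000)], self.REGION
        )
        assert statuses == {CnvStatus.NEUTRAL}
        assert summary is CnvStatus.NEUTRAL

    def test_one_bp_overlap_counts(self):
        statuses, summary = gene_cnv_status(
            [_make_segment(0.4, 5_000, 10_000)], self.REGION
        )
        assert statuses == {CnvStatus.GAIN}
        assert summary is CnvStatus.GAIN

    def test_other_chromosome_ignored(self):
        statuses, _ = gene_cnv_status(
            [_make_segment(0.4, 10_000, 20_000, chrom="2")], self.REGION
        )
        assert statuses == {CnvStatus.NEUTRAL}

    def test_summary_is_most_extreme_mean(self):
        segs = [
            _make_segment(0.3, 10_000, 12_000),
            _make_segment(-0.9, 15_000, 16_000),
        ]
        statuses, summary = gene_cnv_status(segs, self.REGION)
        assert statuses == {CnvStatus.GAIN, CnvStatus.DELETION}
        assert summary is CnvStatus.DELETION


class TestCnvFrequencyTable:
    def test_nobody_altered(self):
        table = cnv_frequency_table({"TPMT": [{CnvStatus.NEUTRAL}] * 10}, 10)
        row = table.iloc[0]
        assert (row.gain_pct, row.loss_pct) == (0.0, 0.0)

    def test_counting_oracle(self):
        """947-subject cohort with 490 planted losses -> 51.74%."""
        per_subject = [{CnvStatus.LOSS}] * 490 + [{CnvStatus.NEUTRAL}] * 457
        table = cnv_frequency_table({"TPMT": per_subject}, 947)
        assert table.iloc[0].loss_pct == pytest.approx(51.74)
        assert table.iloc[0].gain_pct == 0.0

    def test_subject_counts_in_both_columns(self):
        per_subject = [{CnvStatus.GAIN, CnvStatus.DELETION}] + [{CnvStatus.NEUTRAL}] * 3
        table = cnv_frequency_table({"DMD": per_subject}, 4)
        assert (table.iloc[0].gain_n, table.iloc[0].loss_n) == (1, 1)


class TestEndToEndSegmentation:
    def test_noiseless_planted_event_recovered_exactly(self):
        positions = np.arange(1_000, 41_000, 1_000)
        log2r = np.zeros(40)
        log2r[10:30] = -1.0
        series = ProbeSeries("S0", "6", positions, log2r)
        segments = [classify_segment(s) for s in segment_series(series)]
        assert [s.status for s in segments] == [
            CnvStatus.NEUTRAL, CnvStatus.DELETION, CnvStatus.NEUTRAL,
        ]
        assert (segments[1].start_pos, segments[1].end_pos) == (11_000, 30_000)
        assert segments[1].mean_log2 == pytest.approx(-1.0)
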