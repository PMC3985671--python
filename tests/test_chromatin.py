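"""Chromatin window scores, Fisher enrichment, quartile splits, segmentation
and CUT/SUT annotation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asrna.chromatin import (Segment, annotate_ncrnas, promoter_enrichment,
                             segment_track, set1_effect_split,
                             set1_split_counts, window_score)
from asrna.classify import ClassAssignment
from asrna.model import GeneRecord, GenomicWindow, SignalTrack


def fisher_two_sided_oracle(a, b, c, d):
    """Hypergeometric enumeration: sum P(table) over all tables with the same
    margins whose point probability <= that of the observed table."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    def prob(x):
        return (math.comb(row1, x) * math.comb(row2, col1 - x)
                / math.comb(n, col1))
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def strandless_track(length, values):
    t = SignalTrack("h3")
    t.set_block("c", ".", np.arange(length), values)
    return t


class TestWindowScore:
    def test_constant_track(self):
        t = strandless_track(2000, np.full(2000, 1.7))
        gene = GeneRecord("g", "c", 500, 1500, "+")
        scores = window_score(t, [gene], GenomicWindow("TTS", -300, 0, "sense"))
        assert scores["g"] == pytest.approx(1.7)

    def test_arithmetic_series_mean(self):
        # per-bp values 1..300 over the queried 300-bp window
        vals = np.zeros(2000)
        gene = GeneRecord("g", "c", 500, 1500, "+")  # window [1200, 1500)
        vals[1200:1500] = np.arange(1, 301)
        t = strandless_track(2000, vals)
        scores = window_score(t, [gene], GenomicWindow("TTS", -300, 0, "sense"))
        assert scores["g"] == pytest.approx(150.5)

    def test_minus_strand_tts_window_maps_downstream_of_start(self):
        # for a - gene, 0..-300 of the TTS is genomic [tts, tts+300)
        vals = np.zeros(2000)
        vals[500:800] = 2.0
        t = strandless_track(2000, vals)
        gene = GeneRecord("g", "c", 500, 1500, "-")  # tts = 500
        scores = window_score(t, [gene], GenomicWindow("TTS", -300, 0, "sense"))
        assert scores["g"] == pytest.approx(2.0)

    def test_empty_window_is_missing(self):
        t = strandless_track(100, np.ones(100))
        gene = GeneRecord("g", "c", 10, 60, "+")
        scores = window_score(t, [gene], GenomicWindow("TSS", -400, -200, "sense"))
        assert scores["g"] is None


def make_assignment(classes):
    return ClassAssignment(dict(classes), {}, [], {g: True for g in classes})


class TestPromoterEnrichment:
    def test_sample_odds_ratio_and_enumerated_p(self):
        # class table [[10,5],[20,100]]
        classes = {f"i{k}": "I" for k in range(15)}
        classes.update({f"o{k}": "unclassified" for k in range(120)})
        feat = {f"i{k}": int(k < 10) for k in range(15)}
        feat.update({f"o{k}": int(k < 20) for k in range(120)})
        prom = pd.DataFrame({"tata": pd.Series(feat)})
        res = [r for r in promoter_enrichment(make_assignment(classes), prom,
                                              "tata") if r.class_label == "I"]
        (r,) = res
        assert r.table == ((10, 5), (20, 100))
        assert r.odds_ratio == pytest.approx(10.0)
        assert r.p_two_sided == pytest.approx(
            fisher_two_sided_oracle(10, 5, 20, 100), rel=1e-9)
        assert r.starred == (r.p_two_sided < 0.05)

    def test_identical_proportions_give_null_result(self):
        classes = {f"i{k}": "I" for k in range(10)}
        classes.update({f"o{k}": "III" for k in range(10)})
        feat = {g: int(g[1:] in {"0", "1", "2", "3", "4"}) for g in classes}
        prom = pd.DataFrame({"tata": pd.Series(feat)})
        res = promoter_enrichment(make_assignment(classes), prom, "tata")
        for r in res:
            assert r.odds_ratio == pytest.approx(1.0)
            assert r.p_two_sided == pytest.approx(1.0)
            assert not r.starred

    def test_zero_margin_gives_missing_odds_and_p_one(self):
        classes = {"a": "I", "b": "I", "c": "unclassified"}
        prom = pd.DataFrame({"tata": pd.Series({"a": 0, "b": 0, "c": 0})})
        res = [r for r in promoter_enrichment(make_assignment(classes), prom,
                                              "tata") if r.class_label == "I"]
        assert res[0].odds_ratio is None and res[0].p_two_sided == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_fisher_p_matches_enumeration_for_margins_up_to_50(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(rng.integers(0, 26)) for _ in range(4))
        _or, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a + b, c + d, a + c, b + d) == 0:
            assert p == pytest.approx(1.0)
        else:
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d),
                                      rel=1e-9)


class TestSet1Split:
    def test_threshold_example(self):
        de = dict(zip("abcdefgh", [-2.0, -1.5, 0.0, 0.0, 0.0, 0.0, 1.2, 3.0]))
        expr = {g: float(i) for i, g in enumerate("abcdefgh")}
        split = set1_effect_split(expr, de, fold_threshold=2.0)
        counts = split["group"].value_counts()
        assert counts["silenced"] == 2
        assert counts["overexpressed"] == 2
        assert counts["not_affected"] == 4

    def test_all_zero_de_not_affected(self):
        de = {f"g{i}": 0.0 for i in range(8)}
        expr = {f"g{i}": float(i) for i in range(8)}
        split = set1_effect_split(expr, de)
        assert (split["group"] == "not_affected").all()

    def test_quartiles_partition_the_universe(self):
        rng = np.random.default_rng(7)
        expr = {f"g{i}": float(rng.normal()) for i in range(103)}
        de = {f"g{i}": float(rng.normal()) for i in range(103)}
        split = set1_effect_split(expr, de)
        assert len(split) == 103
        sizes = split["quartile"].value_counts().sort_index()
        assert sizes.sum() == 103
        assert sizes.max() - sizes.min() <= 1
        counts = set1_split_counts(split)
        assert counts.to_numpy().sum() == 103
        # quartile order respects expression order
        merged = split.set_index("transcript")
        ordered = sorted(expr, key=lambda g: (expr[g], g))
        qs = [merged.loc[g, "quartile"] for g in ordered]
        assert all(q1 <= q2 for q1, q2 in zip(qs, qs[1:]))

    def test_too_few_transcripts_error(self):
        with pytest.raises(ValueError):
            set1_effect_split({"a": 1.0}, {"a": 0.0})


def probe_track(blocks, step=10, sample="t", cond="rrp6"):
    """blocks: {(chrom, strand): (positions, values)}"""
    t = SignalTrack(sample, cond)
    for (chrom, strand), (pos, val) in blocks.items():
        t.set_block(chrom, strand, pos, val)
    return t


def scanline_segments_oracle(pos, val, min_level, max_gap, min_len, step):
    segs = []
    run = []
    for p, v in zip(pos, val):
        if v < min_level:
            continue
        if run and p - run[-1] >= max_gap:
            segs.append(run)
            run = []
        run.append(p)
    if run:
        segs.append(run)
    return [(r[0], r[-1] + step) for r in segs if r[-1] + step - r[0] >= min_len]


class TestSegmentation:
    def test_uniform_high_signal_yields_single_segment(self):
        pos = np.arange(0, 1000, 10)
        t = probe_track({("c", "+"): (pos, np.full(pos.size, 8.0))})
        segs = segment_track(t, 6.0, 50, 50)
        assert [(s.start, s.end) for s in segs] == [(0, 1000)]

    def test_gap_beyond_threshold_splits_segments(self):
        pos = np.arange(0, 1000, 10)
        val = np.full(pos.size, 8.0)
        val[30:45] = 0.0  # 150-bp low gap
        t = probe_track({("c", "+"): (pos, val)})
        segs = segment_track(t, 6.0, 50, 50)
        assert [(s.start, s.end) for s in segs] == [(0, 300), (450, 1000)]

    def test_matches_exhaustive_scanline_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            pos = np.arange(0, 2000, 10)
            val = rng.choice([2.0, 8.0], size=pos.size, p=[0.4, 0.6])
            t = probe_track({("c", "+"): (pos, val)})
            segs = segment_track(t, 6.0, 40, 30)
            oracle = scanline_segments_oracle(pos, val, 6.0, 40, 30, 10)
            assert [(s.start, s.end) for s in segs] == oracle

    def test_idempotent_on_reconstructed_track(self):
        rng = np.random.default_rng(9)
        pos = np.arange(0, 3000, 10)
        val = rng.choice([2.0, 8.0], size=pos.size, p=[0.3, 0.7])
        t = probe_track({("c", "+"): (pos, val)})
        segs = segment_track(t, 6.0, 60, 40)
        # rebuild a track holding high signal exactly over the segments
        pos2, val2 = [], []
        for s in segs:
            p = np.arange(s.start, s.end, 10)
            pos2.append(p)
            val2.append(np.full(p.size, 8.0))
        t2 = probe_track({("c", "+"): (np.concatenate(pos2),
                                       np.concatenate(val2))})
        segs2 = segment_track(t2, 6.0, 60, 40)
        assert [(s.start, s.end, s.strand) for s in segs] == \
            [(s.start, s.end, s.strand) for s in segs2]


class TestNcRNAAnnotation:
    def setup_tracks(self, level_wt, level_rrp6, length=2000, step=10):
        pos = np.arange(0, length, step)
        wt = probe_track({("c", "+"): (pos, np.full(pos.size, level_wt))},
                         cond="wt")
        rp = probe_track({("c", "+"): (pos, np.full(pos.size, level_rrp6))},
                         cond="rrp6")
        return [wt], [rp]

    def test_sub_200bp_segment_rejected(self):
        wt, rp = self.setup_tracks(4.0, 7.0)
        segs = [Segment("c", 100, 250, "+")]
        assert annotate_ncrnas(segs, [], wt, rp) == []

    def test_two_point_five_fold_up_segment_is_cut(self):
        wt, rp = self.setup_tracks(5.0, 5.0 + np.log2(2.5))
        segs = [Segment("c", 100, 400, "+")]
        (nc,) = annotate_ncrnas(segs, [], wt, rp)
        assert nc.category == "CUT"
        assert nc.log2_ratio == pytest.approx(np.log2(2.5))

    def test_flat_detectable_segment_is_sut(self):
        wt, rp = self.setup_tracks(6.8, 6.8)
        (nc,) = annotate_ncrnas([Segment("c", 100, 400, "+")], [], wt, rp,
                                min_level=6.0)
        assert nc.category == "SUT"

    def test_flat_undetectable_segment_is_other(self):
        wt, rp = self.setup_tracks(4.5, 4.5)
        (nc,) = annotate_ncrnas([Segment("c", 100, 400, "+")], [], wt, rp,
                                min_level=6.0)
        assert nc.category == "ncRNA-other"

    def test_same_strand_catalog_overlap_drops_segment(self):
        wt, rp = self.setup_tracks(4.0, 7.0)
        catalog = [GeneRecord("g", "c", 300, 800, "+")]
        segs = [Segment("c", 100, 400, "+"), Segment("c", 100, 400, "-")]
        out = annotate_ncrnas(segs, catalog, wt, rp)
        # the + segment overlaps the + gene; the - segment survives
        assert len(out) == 1 and out[0].strand == "-"

    def test_raising_thresholds_never_adds_cuts(self):
        rng = np.random.default_rng(10)
        pos = np.arange(0, 5000, 10)
        wt_vals = rng.normal(5.5, 1.0, pos.size)
        rp_vals = wt_vals + rng.normal(0.8, 0.8, pos.size)
        wt = [probe_track({("c", "+"): (pos, wt_vals)}, cond="wt")]
        rp = [probe_track({("c", "+"): (pos, rp_vals)}, cond="rrp6")]
        segs = [Segment("c", s, s + int(ln), "+")
                for s, ln in zip(range(0, 4500, 500),
                                 rng.integers(150, 500, size=9))]
        def cuts(min_len, fold):
            return {n.id for n in annotate_ncrnas(segs, [], wt, rp,
                                                  min_len=min_len,
                                                  fold_threshold=fold)
                    if n.category == "CUT"}
        base_ids = [(n.chrom, n.start, n.end) for n in
                    annotate_ncrnas(segs, [], wt, rp) if n.category == "CUT"]
        for min_len, fold in [(250, 2.0), (200, 3.0), (300, 4.0)]:
            stricter = [(n.chrom, n.start, n.end) for n in
                        annotate_ncrnas(segs, [], wt, rp, min_len=min_len,
                                        fold_threshold=fold)
                        if n.category == "CUT"]
            assert set(stricter) <= set(base_ids)
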