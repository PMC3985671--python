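"""Convergent-gene filtering, binned DE features, feature matrix, half-lives."""

import numpy as np
import pandas as pd
import pytest

from asrna.features import (BinnedDE, Contrast, DEFAULT_CONTRASTS,
                            bin_differential_expression, build_feature_matrix,
                            exclude_convergent_overlapping, half_life,
                            window_bin_offsets, DecaySeries)
from asrna.model import ANTISENSE, SENSE, GeneRecord, GenomicWindow, SignalTrack


# ---------------------------------------------------------------------------
# convergent filter
# ---------------------------------------------------------------------------

def convergent_pairs_oracle(genes):
    """O(n^2) per-base oracle: overlapping opposite-strand staggered pairs."""
    excluded = set()
    for p in genes:
        for m in genes:
            if p.strand != "+" or m.strand != "-" or p.chrom != m.chrom:
                continue
            overlap = set(range(p.start, p.end)) & set(range(m.start, m.end))
            if overlap and p.start <= m.start and p.end <= m.end:
                excluded |= {p.gene_id, m.gene_id}
    return excluded


class TestConvergentFilter:
    def test_tail_to_tail_overlap_excluded(self):
        genes = [GeneRecord("p", "c", 100, 500, "+"),
                 GeneRecord("m", "c", 400, 900, "-")]
        kept, excl = exclude_convergent_overlapping(genes)
        assert kept == [] and {g.gene_id for g in excl} == {"p", "m"}

    def test_non_overlapping_kept(self):
        genes = [GeneRecord("p", "c", 100, 500, "+"),
                 GeneRecord("m", "c", 600, 900, "-")]
        kept, excl = exclude_convergent_overlapping(genes)
        assert excl == [] and len(kept) == 2

    def test_same_strand_overlap_is_tandem_not_convergent(self):
        genes = [GeneRecord("a", "c", 100, 500, "+"),
                 GeneRecord("b", "c", 400, 900, "+")]
        kept, excl = exclude_convergent_overlapping(genes)
        assert excl == []

    def test_divergent_overlap_kept(self):
        # 5' ends overlap: genes transcribe away from each other
        genes = [GeneRecord("p", "c", 400, 900, "+"),
                 GeneRecord("m", "c", 100, 500, "-")]
        kept, excl = exclude_convergent_overlapping(genes)
        assert excl == []

    def test_matches_pairwise_oracle_on_random_annotations(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            genes = []
            for i in range(30):
                s = int(rng.integers(0, 2000))
                genes.append(GeneRecord(
                    f"g{i}", "c", s, s + int(rng.integers(50, 600)),
                    "+" if rng.random() < 0.5 else "-"))
            _kept, excl = exclude_convergent_overlapping(genes)
            assert {g.gene_id for g in excl} == convergent_pairs_oracle(genes)


# ---------------------------------------------------------------------------
# binned DE
# ---------------------------------------------------------------------------

def grid_track(sample, condition, rep, length, level_fn, strands="+-"):
    """Per-base probe track with values level_fn(pos, strand)."""
    t = SignalTrack(sample, condition, rep)
    pos = np.arange(length)
    for strand in strands:
        t.set_block("c", strand, pos, level_fn(pos, strand))
    return t


@pytest.fixture
def simple_setup():
    gene = GeneRecord("g1", "c", 1000, 2500, "+")
    window = GenomicWindow("TSS", -100, 750, SENSE)
    return gene, window


class TestBinnedDE:
    def test_identity_contrast_is_zero(self, simple_setup):
        gene, window = simple_setup
        mk = lambda cond, r: grid_track(f"{cond}{r}", cond, r, 3000,
                                        lambda p, s: np.full(p.size, 7.0))
        tracks = [mk("wt", 1), mk("rrp6", 1)]
        de = bin_differential_expression(tracks, [gene],
                                         Contrast("rrp6", "wt"), window, 20)
        np.testing.assert_allclose(de.values.loc["g1"], 0.0)

    def test_uniform_shift_gives_uniform_ratio(self, simple_setup):
        gene, window = simple_setup
        wt = grid_track("w", "wt", 1, 3000, lambda p, s: np.full(p.size, 7.0))
        up = grid_track("r", "rrp6", 1, 3000, lambda p, s: np.full(p.size, 8.0))
        de = bin_differential_expression([wt, up], [gene],
                                         Contrast("rrp6", "wt"), window, 20)
        np.testing.assert_allclose(de.values.loc["g1"], 1.0)

    def test_window_850_at_20_gives_43_bins_with_truncated_last(self):
        offs = window_bin_offsets(GenomicWindow("TSS", -100, 750, SENSE), 20)
        assert len(offs) == 43
        assert offs[-1] == (740, 750)

    def test_swapped_contrast_negates(self, simple_setup):
        gene, window = simple_setup
        rng = np.random.default_rng(5)
        wt = grid_track("w", "wt", 1, 3000,
                        lambda p, s: rng.normal(7, 1, p.size))
        up = grid_track("r", "rrp6", 1, 3000,
                        lambda p, s: rng.normal(8, 1, p.size))
        c = Contrast("rrp6", "wt")
        fwd = bin_differential_expression([wt, up], [gene], c, window, 20)
        rev = bin_differential_expression([wt, up], [gene], c.swapped(), window, 20)
        np.testing.assert_allclose(fwd.values.to_numpy(),
                                   -rev.values.to_numpy(), atol=1e-12)

    def test_replicate_permutation_invariance(self, simple_setup):
        gene, window = simple_setup
        rng = np.random.default_rng(6)
        reps = [grid_track(f"w{r}", "wt", r, 3000,
                           lambda p, s: rng.normal(7, 1, p.size))
                for r in range(3)]
        other = [grid_track("r", "rrp6", 1, 3000,
                            lambda p, s: np.full(p.size, 8.0))]
        c = Contrast("rrp6", "wt")
        a = bin_differential_expression(other + reps, [gene], c, window, 20)
        b = bin_differential_expression(other + reps[::-1], [gene], c, window, 20)
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy(),
                                   atol=1e-12)

    def test_missing_condition_errors(self, simple_setup):
        gene, window = simple_setup
        wt = grid_track("w", "wt", 1, 3000, lambda p, s: np.full(p.size, 7.0))
        with pytest.raises(ValueError, match="rrp6"):
            bin_differential_expression([wt], [gene],
                                        Contrast("rrp6", "wt"), window, 20)

    def test_mirror_image_annotation_gives_identical_features(self):
        """A gene and its strand-flipped mirror read the same transcript-space
        signal, so sense and antisense blocks must agree bin for bin."""
        L = 4000
        rng = np.random.default_rng(7)
        plus_vals = rng.normal(7, 1, L)
        minus_vals = rng.normal(7, 1, L)
        fwd_wt = grid_track("w", "wt", 1, L,
                            lambda p, s: plus_vals if s == "+" else minus_vals)
        up = {"+": plus_vals + rng.normal(0, 1, L),
              "-": minus_vals + rng.normal(0, 1, L)}
        fwd_up = grid_track("r", "rrp6", 1, L, lambda p, s: up[s])
        # mirrored genome: position p -> L-1-p, strands flip
        def mirror(vals_by_strand):
            return {"+": vals_by_strand["-"][::-1].copy(),
                    "-": vals_by_strand["+"][::-1].copy()}
        mwt = mirror({"+": plus_vals, "-": minus_vals})
        mup = mirror(up)
        rev_wt = grid_track("w", "wt", 1, L, lambda p, s: mwt[s])
        rev_up = grid_track("r", "rrp6", 1, L, lambda p, s: mup[s])
        gene_f = GeneRecord("g", "c", 1000, 2500, "+")
        gene_r = GeneRecord("g", "c", L - 2500, L - 1000, "-")
        c = Contrast("rrp6", "wt")
        for window in (GenomicWindow("TSS", -100, 750, SENSE),
                       GenomicWindow("TTS", -750, 100, ANTISENSE)):
            a = bin_differential_expression([fwd_wt, fwd_up], [gene_f], c,
                                            window, 20)
            b = bin_differential_expression([rev_wt, rev_up], [gene_r], c,
                                            window, 20)
            np.testing.assert_allclose(a.values.to_numpy(),
                                       b.values.to_numpy(), atol=1e-9)


# ---------------------------------------------------------------------------
# feature matrix assembly
# ---------------------------------------------------------------------------

def fake_block(contrast, orientation, genes, n_bins, fill=0.5):
    cols = [f"{contrast.label}|{orientation}|bin{i:02d}" for i in range(n_bins)]
    vals = pd.DataFrame(fill, index=genes, columns=cols)
    offs = [(i, i + 1) for i in range(n_bins)]
    return BinnedDE(contrast, orientation, offs, vals)


class TestFeatureMatrix:
    def blocks(self, genes, n_bins=43):
        out = []
        for c in DEFAULT_CONTRASTS:
            for ori in (SENSE, ANTISENSE):
                out.append(fake_block(c, ori, genes, n_bins))
        return out

    def test_four_contrasts_two_orientations_43_bins_gives_344_columns(self):
        fm = build_feature_matrix(self.blocks(["g1", "g2"]))
        assert fm.values.shape == (2, 344)
        # fixed block order: contrasts in study order, sense before antisense
        labels = [(lab, ori) for lab, ori, _ in fm.blocks]
        assert labels == [(c.label, o) for c in DEFAULT_CONTRASTS
                          for o in (SENSE, ANTISENSE)]

    def test_gene_above_missing_threshold_dropped(self):
        blocks = self.blocks(["g1", "g2"])
        blocks[0].values.loc["g2", :] = np.nan  # 43/344 = 12.5% missing
        blocks[1].values.loc["g2", :] = np.nan  # 86/344 = 25% missing
        fm = build_feature_matrix(blocks, max_missing_fraction=0.2)
        assert fm.gene_ids == ["g1"]

    def test_single_missing_bin_imputed_with_zero(self):
        blocks = self.blocks(["g1"])
        col = blocks[0].values.columns[5]
        blocks[0].values.loc["g1", col] = np.nan
        fm = build_feature_matrix(blocks)
        assert fm.values.loc["g1", col] == 0.0
        assert fm.imputed.loc["g1", col]
        assert fm.imputed.to_numpy().sum() == 1

    def test_disjoint_gene_sets_error(self):
        a = self.blocks(["g1"])[:4]
        b = self.blocks(["g2"])[4:]
        with pytest.raises(ValueError, match="intersection"):
            build_feature_matrix(a + b)


# ---------------------------------------------------------------------------
# half-lives
# ---------------------------------------------------------------------------

class TestHalfLife:
    def test_unit_rate_constant_gives_0693_minutes(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        fit = half_life(DecaySeries("g", t, np.exp(-1.0 * t)))
        assert fit.k == pytest.approx(1.0, rel=1e-9)
        assert fit.t_half == pytest.approx(0.693, rel=1e-9)

    def test_halving_every_ten_minutes(self):
        t = np.array([0.0, 10.0, 20.0, 30.0])
        fit = half_life(DecaySeries("g", t, 0.5 ** (t / 10.0)))
        k_true = np.log(2) / 10.0
        assert fit.k == pytest.approx(k_true, rel=1e-9)
        assert fit.t_half == pytest.approx(0.693 / k_true, rel=1e-9)

    def test_noiseless_exponential_recovers_k_vs_regression_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            k = float(rng.uniform(0.01, 2.0))
            t = np.sort(np.concatenate(([0.0], rng.uniform(1, 40, 5))))
            y = np.exp(-k * t) * 3.7
            fit = half_life(DecaySeries("g", t, y))
            assert fit.k == pytest.approx(k, rel=1e-9)
            # independent oracle: closed-form OLS slope
            x = t - t.mean()
            slope = (x * np.log(y)).sum() / (x * x).sum()
            assert fit.k == pytest.approx(-slope, rel=1e-9)

    def test_constant_levels_yield_infinite_half_life(self):
        fit = half_life(DecaySeries("g", np.array([0.0, 5.0, 10.0]),
                                    np.array([1.0, 1.0, 1.0])))
        assert fit.k == 0.0 and np.isinf(fit.t_half)

    def test_nonpositive_level_errors(self):
        with pytest.raises(ValueError, match="nonpositive"):
            half_life(DecaySeries("g", np.array([0.0, 5.0, 10.0]),
                                  np.array([1.0, 0.0, 1.0])))

    def test_too_few_timepoints_error(self):
        with pytest.raises(ValueError, match="3 timepoints"):
            half_life(DecaySeries("g", np.array([0.0, 5.0]),
                                  np.array([1.0, 0.5])))
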