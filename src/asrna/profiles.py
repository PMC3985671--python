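"""Antisense metagene profiles, Nrd1/Nab3 motif scanning, PAR-CLiP binding
aggregation and the nonparametric group comparisons used throughout.

Metagene profiles are class-wise medians of the exosome-mutant antisense
signal in 10-bp bins anchored at the TSS or TTS of the sense ORF, smoothed
with a 150-bp moving average stepping every 10 bp.  Motifs use the Nab3 and
Nrd1 consensus tetramers TCTT and GTA[AG], counted with overlaps allowed on
the antisense strand of the last 400 bp of each gene (the 5' region of the
antisense transcript).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .model import (ANTISENSE, GeneRecord, GenomicWindow, SignalTrack,
                    resolve_window)

NAB3_MOTIF = "TCTT"
NRD1_MOTIFS = ("GTAA", "GTAG")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    class_label: str
    anchor: str  # TSS | TTS
    positions: np.ndarray  # bin start offsets, sense orientation, step = bin size
    raw_median: np.ndarray  # per-bin median across genes (NaN = no coverage)
    smoothed: np.ndarray  # moving-average values, same length
    n_genes: int


def moving_average(values: np.ndarray, window_bins: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    Missing bins (NaN) are skipped and the average renormalised over the
    bins actually present; a window with no data stays NaN.
    """
    n = values.size
    half = window_bins // 2
    out = np.full(n, np.nan)
    finite = np.isfinite(values)
    vals = np.where(finite, values, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0], np.cumsum(finite.astype(np.int64))))
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        cnt = ccnt[hi] - ccnt[lo]
        if cnt:
            out[i] = (csum[hi] - csum[lo]) / cnt
    return out


def antisense_metagene(
    tracks: Sequence[SignalTrack],
    genes: Sequence[GeneRecord],
    anchor: str,
    span: Tuple[int, int] = (-500, 1500),
    bin_bp: int = 10,
    smooth_bp: int = 150,
    class_label: str = "",
) -> MetageneProfile:
    """Class metagene of antisense signal around one anchor.

    Per 10-bp bin (offsets in sense-transcript orientation) each gene
    contributes the mean over replicate tracks of its antisense-strand
    signal; the profile is the median across genes, then smoothed.
    """
    if not genes:
        raise ValueError("metagene requires a non-empty gene class")
    offsets = np.arange(span[0], span[1], bin_bp)
    n_bins = offsets.size
    per_gene = np.full((len(genes), n_bins), np.nan)
    for gi, g in enumerate(genes):
        a = g.anchor(anchor)
        if g.strand == "+":
            starts = a + offsets
            ends = starts + bin_bp
            strand = "-"
        else:
            ends = a - offsets
            starts = ends - bin_bp
            strand = "+"
        edges = np.stack([starts, ends], axis=1)
        edges = np.clip(edges, 0, None)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=np.int64)
        for t in tracks:
            s, c = t.binned_stats(g.chrom, strand, edges)
            valid = c > 0
            sums[valid] += s[valid] / c[valid]
            counts[valid] += 1
        with np.errstate(invalid="ignore"):
            per_gene[gi] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    with np.errstate(all="ignore"):
        raw = np.nanmedian(per_gene, axis=0)
    smoothed = moving_average(raw, max(smooth_bp // bin_bp, 1))
    return MetageneProfile(class_label, anchor, offsets, raw, smoothed, len(genes))


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def count_overlapping(seq: str, motifs: Sequence[str]) -> int:
    """Occurrences of any motif, overlaps allowed; ambiguous bases never match."""
    seq = seq.upper()
    total = 0
    for motif in motifs:
        start = 0
        while True:
            hit = seq.find(motif, start)
            if hit < 0:
                break
            total += 1
            start = hit + 1
    return total


@dataclass
class MotifCounts:
    gene_id: str
    nab3_count: int
    nrd1_count: int
    region: Tuple[str, int, int, str]  # resolved chrom, start, end, strand
    coverage: float  # fraction of requested window on the chromosome


def count_motifs(
    sequences,
    genes: Sequence[GeneRecord],
    window: GenomicWindow = GenomicWindow("TTS", -400, 0, ANTISENSE),
) -> List[MotifCounts]:
    """Count Nab3 (TCTT) and Nrd1 (GTA[AG]) motifs per gene.

    The window is resolved through the gene's orientation; the extracted
    sequence is reverse-complemented when the resolved strand is ``-`` so the
    scan always reads the (antisense) transcript 5'->3'.
    """
    sizes = {name: len(sequences[name]) for name in sequences.keys()}
    out = []
    for g in genes:
        chrom, start, end, strand = resolve_window(g, window, sizes)
        requested = window.width
        if end <= start:
            out.append(MotifCounts(g.gene_id, 0, 0, (chrom, start, end, strand), 0.0))
            continue
        seq = str(sequences[chrom][start:end])
        if strand == "-":
            seq = reverse_complement(seq)
        out.append(MotifCounts(
            g.gene_id,
            count_overlapping(seq, [NAB3_MOTIF]),
            count_overlapping(seq, NRD1_MOTIFS),
            (chrom, start, end, strand),
            (end - start) / requested,
        ))
    return out


# ---------------------------------------------------------------------------
# binding
# ---------------------------------------------------------------------------

@dataclass
class BindingScore:
    gene_id: str
    raw_sum: float
    wt_expression: Optional[float]  # linear scale
    normalized: Optional[float]


def aggregate_binding(
    binding_track: SignalTrack,
    genes: Sequence[GeneRecord],
    window: GenomicWindow,
    wt_tracks: Sequence[SignalTrack],
) -> List[BindingScore]:
    """Sum cross-link counts per gene window, normalised to WT expression.

    WT expression of the region is the mean log2 antisense signal across the
    WT replicates, linearised as 2**mean; a gene whose WT expression is
    missing or nonpositive gets a missing normalised score.
    """
    out = []
    for g in genes:
        chrom, start, end, strand = resolve_window(g, window)
        raw, _n = binding_track.region_stats(chrom, start, end, strand)
        if raw < 0:
            raise ValueError(f"{g.gene_id}: negative binding signal")
        means = [t.region_mean(chrom, start, end, strand) for t in wt_tracks]
        means = [m for m in means if m is not None]
        if not means:
            out.append(BindingScore(g.gene_id, raw, None, None))
            continue
        wt_lin = float(2.0 ** np.mean(means))
        norm = raw / wt_lin if wt_lin > 0 else None
        out.append(BindingScore(g.gene_id, float(raw), wt_lin, norm))
    return out


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null enumeration when the smaller group has <= 8 values and there
    are no ties across groups; otherwise the normal approximation with tie
    and continuity corrections.  Returns ``(U statistic of group A, p)``.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return float(a.size * b.size / 2.0), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)
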