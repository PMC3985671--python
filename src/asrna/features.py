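"""Per-gene binned differential expression, the clustering feature matrix,
convergent-gene filtering and RNA half-lives.

Differential expression (DE) of a gene in a contrast is the difference of
mean log2 signals (numerator condition minus denominator condition, i.e. a
log2 fold change), computed per 20-bp bin over a transcript-anchored window,
with replicates averaged before differencing.  The sense window covers
-100..+750 bp around the TSS; the antisense window covers the first 750 bp
of the antisense transcript (anchored at the ORF TTS, extending into the
gene) plus 100 bp upstream of its start.  Bins within each block are ordered
5'->3' along the transcript they describe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import ANTISENSE, SENSE, GeneRecord, GenomicWindow, SignalTrack

# fixed condition / contrast vocabulary of the study design
CONDITIONS = ("wt", "rrp6", "set1rrp6", "hda2rrp6", "rpd3rrp6")


@dataclass(frozen=True)
class Contrast:
    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("contrast numerator must differ from denominator")

    @property
    def label(self) -> str:
        return f"{self.numerator}_vs_{self.denominator}"

    def swapped(self) -> "Contrast":
        return Contrast(self.denominator, self.numerator)


#: the four contrasts of the classification, in fixed feature order
DEFAULT_CONTRASTS: Tuple[Contrast, ...] = (
    Contrast("rrp6", "wt"),
    Contrast("set1rrp6", "rrp6"),
    Contrast("hda2rrp6", "rrp6"),
    Contrast("rpd3rrp6", "rrp6"),
)


@dataclass
class BinnedDE:
    """Per-gene per-bin log2 ratios for one contrast and orientation."""

    contrast: Contrast
    orientation: str  # sense | antisense
    bin_offsets: List[Tuple[int, int]]  # transcript-orientation offsets, column order
    values: pd.DataFrame  # genes x bins, NaN = missing

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.bin_offsets):
            raise ValueError("values width must equal number of bins")


@dataclass
class FeatureMatrix:
    """Genes x concatenated binned-DE features, imputation mask attached."""

    values: pd.DataFrame  # no missing entries
    imputed: pd.DataFrame  # bool, True where 0.0 was imputed
    blocks: List[Tuple[str, str, int]]  # (contrast label, orientation, n_bins)

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()

    def block_slice(self, contrast_label: str, orientation: str) -> slice:
        start = 0
        for lab, ori, n in self.blocks:
            if lab == contrast_label and ori == orientation:
                return slice(start, start + n)
            start += n
        raise KeyError((contrast_label, orientation))

    def block_values(self, contrast_label: str, orientation: str) -> pd.DataFrame:
        sl = self.block_slice(contrast_label, orientation)
        return self.values.iloc[:, sl]

    def block_imputed(self, contrast_label: str, orientation: str) -> pd.DataFrame:
        sl = self.block_slice(contrast_label, orientation)
        return self.imputed.iloc[:, sl]


# ---------------------------------------------------------------------------
# convergent-gene filter
# ---------------------------------------------------------------------------

def exclude_convergent_overlapping(
    genes: Sequence[GeneRecord],
) -> Tuple[List[GeneRecord], List[GeneRecord]]:
    """Drop convergent overlapping gene pairs.

    A pair is convergent-overlapping when the genes sit on opposite strands,
    their intervals intersect by at least 1 bp, and the pair is staggered
    tail-to-tail: the ``+`` gene starts left of the ``-`` gene and ends
    inside it, so the two 3' ends face each other across the shared region.
    Both members of such a pair are excluded.
    """
    excluded_ids = set()
    by_chrom: Dict[str, Tuple[list, list]] = {}
    for g in genes:
        bucket = by_chrom.setdefault(g.chrom, ([], []))
        (bucket[0] if g.strand == "+" else bucket[1]).append(g)
    for plus, minus in by_chrom.values():
        minus.sort(key=lambda g: g.start)
        m_starts = np.array([g.start for g in minus])
        for p in plus:
            # staggered tail-to-tail: p.start <= m.start < p.end <= m.end
            lo = np.searchsorted(m_starts, p.start, side="left")
            hi = np.searchsorted(m_starts, p.end, side="left")
            for m in minus[lo:hi]:
                if m.end >= p.end:
                    excluded_ids.add(p.gene_id)
                    excluded_ids.add(m.gene_id)
    kept = [g for g in genes if g.gene_id not in excluded_ids]
    excl = [g for g in genes if g.gene_id in excluded_ids]
    return kept, excl


# ---------------------------------------------------------------------------
# binned differential expression
# ---------------------------------------------------------------------------

def window_bin_offsets(window: GenomicWindow, bin_bp: int) -> List[Tuple[int, int]]:
    """Half-open bins tiling the window left-to-right in sense offsets.

    The window width need not be divisible by the bin size; the final bin is
    truncated so the stated window is preserved exactly (e.g. 850 bp at 20 bp
    gives 43 bins, the last 10 bp wide).
    """
    offs = []
    a = window.offset_start
    while a < window.offset_end:
        b = min(a + bin_bp, window.offset_end)
        offs.append((a, b))
        a = b
    return offs


def _bin_edges_for_gene(
    gene: GeneRecord, window: GenomicWindow, offsets: Sequence[Tuple[int, int]]
) -> Tuple[np.ndarray, str]:
    """Genomic ``(m, 2)`` edge array (column order) plus target strand."""
    a = gene.anchor(window.anchor)
    offs = np.asarray(offsets)
    if gene.strand == "+":
        edges = a + offs
        strand = "+"
    else:
        edges = np.stack([a - offs[:, 1], a - offs[:, 0]], axis=1)
        strand = "-"
    if window.target_strand == ANTISENSE:
        strand = "-" if strand == "+" else "+"
    edges = np.clip(edges, 0, None)
    return edges.astype(np.int64), strand


def _condition_bin_means(
    tracks: Sequence[SignalTrack],
    genes: Sequence[GeneRecord],
    window: GenomicWindow,
    offsets: Sequence[Tuple[int, int]],
) -> np.ndarray:
    """Genes x bins mean log2 signal for one condition (NaN where no probes).

    Per replicate the bin mean is sum/count over its probes; replicate means
    are then averaged, ignoring replicates with no coverage of the bin.
    """
    n_genes, n_bins = len(genes), len(offsets)
    edges = np.empty((n_genes, n_bins, 2), dtype=np.int64)
    strands = []
    for i, g in enumerate(genes):
        e, s = _bin_edges_for_gene(g, window, offsets)
        edges[i] = e
        strands.append(s)
    strands = np.array(strands)
    chroms = np.array([g.chrom for g in genes])

    acc = np.zeros((n_genes, n_bins))
    nrep = np.zeros((n_genes, n_bins), dtype=np.int64)
    for track in tracks:
        means = np.full((n_genes, n_bins), np.nan)
        for chrom in np.unique(chroms):
            for strand in ("+", "-"):
                sel = np.flatnonzero((chroms == chrom) & (strands == strand))
                if sel.size == 0:
                    continue
                flat = edges[sel].reshape(-1, 2)
                sums, counts = track.binned_stats(chrom, strand, flat)
                with np.errstate(invalid="ignore"):
                    m = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
                means[sel] = m.reshape(sel.size, n_bins)
        ok = ~np.isnan(means)
        acc[ok] += means[ok]
        nrep += ok
    with np.errstate(invalid="ignore"):
        return np.where(nrep > 0, acc / np.maximum(nrep, 1), np.nan)


def bin_differential_expression(
    tracks: Sequence[SignalTrack],
    genes: Sequence[GeneRecord],
    contrast: Contrast,
    window: GenomicWindow,
    bin_bp: int = 20,
) -> BinnedDE:
    """Per-gene binned log2 ratio between two conditions over one window.

    A bin is missing (NaN) when either condition has no probe in it.
    """
    num = [t for t in tracks if t.condition == contrast.numerator]
    den = [t for t in tracks if t.condition == contrast.denominator]
    for label, grp in ((contrast.numerator, num), (contrast.denominator, den)):
        if not grp:
            raise ValueError(f"no tracks for condition {label!r}")
    offsets = window_bin_offsets(window, bin_bp)
    de = _condition_bin_means(num, genes, window, offsets) - _condition_bin_means(
        den, genes, window, offsets
    )
    orientation = window.target_strand
    ids = [g.gene_id for g in genes]
    if orientation == ANTISENSE:
        # 5'->3' along the antisense transcript = decreasing sense offsets
        offsets = offsets[::-1]
        de = de[:, ::-1]
    cols = [f"{contrast.label}|{orientation}|bin{i:02d}" for i in range(len(offsets))]
    return BinnedDE(contrast, orientation, list(offsets),
                    pd.DataFrame(de, index=ids, columns=cols))


def build_feature_matrix(
    blocks: Sequence[BinnedDE], max_missing_fraction: float = 0.2
) -> FeatureMatrix:
    """Concatenate binned-DE blocks into the clustering feature matrix.

    Genes missing more than ``max_missing_fraction`` of their entries are
    dropped; the remaining missing entries are imputed with 0.0 (no change)
    and flagged in the imputation mask.
    """
    if not blocks:
        raise ValueError("no blocks given")
    common = blocks[0].values.index
    for b in blocks[1:]:
        common = common.intersection(b.values.index)
    if len(common) == 0:
        raise ValueError("empty intersection of gene sets across blocks")
    common = blocks[0].values.index[blocks[0].values.index.isin(common)]
    values = pd.concat([b.values.loc[common] for b in blocks], axis=1)
    missing = values.isna()
    frac = missing.to_numpy().mean(axis=1)
    keep = frac <= max_missing_fraction
    values = values.loc[keep]
    missing = missing.loc[keep]
    values = values.fillna(0.0)
    meta = [(b.contrast.label, b.orientation, b.values.shape[1]) for b in blocks]
    return FeatureMatrix(values, missing, meta)


# ---------------------------------------------------------------------------
# half-lives
# ---------------------------------------------------------------------------

@dataclass
class DecaySeries:
    """A control-normalised RNA decay time course and its first-order fit."""

    gene_id: str
    timepoints: np.ndarray  # minutes, strictly increasing from 0
    levels: np.ndarray  # unitless, level / level of stable control
    k: Optional[float] = None  # decay rate constant, 1/min
    t_half: Optional[float] = None  # minutes


def half_life(series: DecaySeries, coefficient: float = 0.693) -> DecaySeries:
    """First-order decay fit: t1/2 = coefficient / k.

    ``k`` is minus the slope of the ordinary-least-squares fit of
    ``ln(level)`` against time.  A non-decaying series (slope >= 0) gets
    ``k = 0`` and an infinite half-life.
    """
    t = np.asarray(series.timepoints, dtype=float)
    y = np.asarray(series.levels, dtype=float)
    if t.size < 3:
        raise ValueError(f"{series.gene_id}: need at least 3 timepoints")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError(f"{series.gene_id}: timepoints must increase strictly from 0")
    if np.any(y <= 0):
        raise ValueError(f"{series.gene_id}: nonpositive level, log undefined")
    slope = np.polyfit(t, np.log(y), 1)[0]
    k = max(-slope, 0.0)
    t_half = coefficient / k if k > 0 else np.inf
    return DecaySeries(series.gene_id, t, y, k=float(k), t_half=float(t_half))


def read_decay_table(df: pd.DataFrame) -> List[DecaySeries]:
    """Build decay series from a 3-column table (gene, minutes, level)."""
    out = []
    for gid, grp in df.groupby(df.columns[0], sort=True):
        grp = grp.sort_values(grp.columns[1])
        out.append(DecaySeries(str(gid),
                               grp.iloc[:, 1].to_numpy(float),
                               grp.iloc[:, 2].to_numpy(float)))
    return out
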