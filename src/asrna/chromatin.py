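"""Chromatin-mark window scoring, promoter-feature enrichment, expression
quartile splits, expressed-segment detection and ncRNA (CUT/SUT) annotation.

Chromatin marks (e.g. H3K4me3 over H3) are strandless: windows are still
resolved through the gene's orientation so "0..-300 bp of the TTS" lands
inside the gene's 3' end, but the signal is read strand-agnostically.
ncRNAs are expressed segments of the exosome-mutant transcriptome that do
not overlap any catalogued transcript on the same strand and are at least
200 bp long; those at least 2-fold up in the exosome mutant versus wild
type are CUTs, those detectable in wild type are SUTs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassAssignment
from .model import GeneRecord, GenomicWindow, SignalTrack, resolve_window


# ---------------------------------------------------------------------------
# window scoring
# ---------------------------------------------------------------------------

def window_score(
    track: SignalTrack, genes: Sequence[GeneRecord], window: GenomicWindow
) -> Dict[str, Optional[float]]:
    """Per-gene mean track value in the resolved window, strand-agnostic."""
    out: Dict[str, Optional[float]] = {}
    for g in genes:
        chrom, start, end, _strand = resolve_window(g, window)
        out[g.gene_id] = track.region_mean(chrom, start, end, strand=None) \
            if end > start else None
    return out


# ---------------------------------------------------------------------------
# promoter-feature enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    class_label: str
    feature: str
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: Optional[float]
    p_two_sided: float

    @property
    def starred(self) -> bool:
        return self.p_two_sided < 0.05


def promoter_enrichment(
    assignment: ClassAssignment,
    promoters: pd.DataFrame,
    feature: str,
) -> List[EnrichmentResult]:
    """Fisher's exact enrichment of a boolean promoter feature per class.

    ``promoters`` is indexed by gene id and must carry a 0/1 column named
    ``feature`` (for the open/closed configuration pass e.g. a precomputed
    ``closed`` indicator).  Each class is tested against all other genes
    with promoter annotation.  The two-sided p sums the probabilities of all
    tables (at fixed margins) whose point probability does not exceed the
    observed one; the odds ratio is the sample one, ``ad/bc``.
    """
    results = []
    annotated = [g for g in assignment.gene_class if g in promoters.index]
    feat = promoters[feature].astype(bool)
    for cls in ("I", "II", "III", "IV", "unclassified"):
        in_cls = [g for g in annotated if assignment.gene_class[g] == cls]
        out_cls = [g for g in annotated if assignment.gene_class[g] != cls]
        if not in_cls:
            continue
        a = int(feat.loc[in_cls].sum())
        b = len(in_cls) - a
        c = int(feat.loc[out_cls].sum())
        d = len(out_cls) - c
        if min(a + b, c + d, a + c, b + d) == 0:
            results.append(EnrichmentResult(cls, feature, ((a, b), (c, d)), None, 1.0))
            continue
        _or, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        odds = (a * d) / (b * c) if b * c > 0 else None
        results.append(EnrichmentResult(cls, feature, ((a, b), (c, d)), odds, float(p)))
    return results


# ---------------------------------------------------------------------------
# quartile x Set1-effect split
# ---------------------------------------------------------------------------

def set1_effect_split(
    expr_rrp6: Mapping[str, float],
    de_set1: Mapping[str, float],
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Quartiles of exosome-mutant expression crossed with the Set1 effect.

    Transcripts are ranked by expression (ties broken by id) and split into
    four equal-rank quartiles; within each, counts of transcripts silenced
    (log2 change <= -log2(threshold)), overexpressed (>= +log2) or not
    affected in the Set1 double mutant are tabulated.
    """
    ids = sorted(set(expr_rrp6) & set(de_set1))
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 transcripts for quartiles")
    order = sorted(ids, key=lambda g: (expr_rrp6[g], g))
    log_thr = np.log2(fold_threshold)
    rows = []
    for rank, gid in enumerate(order):
        q = min(3, (4 * rank) // n) + 1
        de = de_set1[gid]
        if de <= -log_thr:
            grp = "silenced"
        elif de >= log_thr:
            grp = "overexpressed"
        else:
            grp = "not_affected"
        rows.append({"transcript": gid, "quartile": q, "group": grp})
    df = pd.DataFrame(rows)
    return df


def set1_split_counts(split: pd.DataFrame) -> pd.DataFrame:
    counts = split.pivot_table(index="quartile", columns="group",
                               values="transcript", aggfunc="count", fill_value=0)
    for col in ("silenced", "overexpressed", "not_affected"):
        if col not in counts:
            counts[col] = 0
    return counts[["silenced", "not_affected", "overexpressed"]]


# ---------------------------------------------------------------------------
# segmentation & ncRNA annotation
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


def segment_track(
    track: SignalTrack, min_level: float, max_gap: int, min_len: int
) -> List[Segment]:
    """Threshold segmentation of a strand-specific track.

    Maximal runs of probes at or above ``min_level`` on one strand; runs
    whose bounding probes are closer than ``max_gap`` bp are merged, and
    segments shorter than ``min_len`` bp are dropped.  A segment spans from
    its first probe to one probe-step past its last.
    """
    segments: List[Segment] = []
    for chrom, strand in track.keys():
        pos, val = track.block(chrom, strand)
        step = max(int(round(track.probe_step(chrom, strand))), 1)
        high = val >= min_level
        if not high.any():
            continue
        idx = np.flatnonzero(high)
        breaks = np.flatnonzero(np.diff(pos[idx]) >= max_gap)
        run_bounds = np.split(idx, breaks + 1)
        for run in run_bounds:
            start = int(pos[run[0]])
            end = int(pos[run[-1]]) + step
            if end - start >= min_len:
                segments.append(Segment(chrom, start, end, strand))
    segments.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return segments


@dataclass
class NcRNASegment:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    mean_rrp6_level: float
    mean_wt_level: float
    log2_ratio: float
    category: str  # CUT | SUT | ncRNA-other


def annotate_ncrnas(
    segments: Sequence[Segment],
    known_catalog: Sequence[GeneRecord],
    wt_tracks: Sequence[SignalTrack],
    rrp6_tracks: Sequence[SignalTrack],
    min_len: int = 200,
    fold_threshold: float = 2.0,
    min_level: float = 6.0,
) -> List[NcRNASegment]:
    """Annotate expressed segments as ncRNAs and split them into CUT/SUT.

    Segments overlapping (same strand, >= 1 bp) any catalogued transcript
    are dropped, as are survivors shorter than ``min_len``.  The remainder
    are scored with mean WT and exosome-mutant log2 levels over the segment;
    a log2 ratio of at least ``log2(fold_threshold)`` makes a CUT, otherwise
    a WT level at or above ``min_level`` makes a SUT, else ncRNA-other.
    """
    catalog: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for g in known_catalog:
        catalog.setdefault((g.chrom, g.strand), []).append((g.start, g.end))
    cat_arrays = {}
    for key, ivals in catalog.items():
        ivals.sort()
        cat_arrays[key] = (np.array([s for s, _ in ivals]),
                          np.array([e for _, e in ivals]))

    def overlaps_catalog(seg: Segment) -> bool:
        key = (seg.chrom, seg.strand)
        if key not in cat_arrays:
            return False
        starts, ends = cat_arrays[key]
        i = np.searchsorted(starts, seg.end, side="left")
        return bool(np.any(ends[:i] > seg.start))

    def mean_level(tracks: Sequence[SignalTrack], seg: Segment) -> float:
        means = [t.region_mean(seg.chrom, seg.start, seg.end, seg.strand)
                 for t in tracks]
        means = [m for m in means if m is not None]
        return float(np.mean(means)) if means else np.nan

    out: List[NcRNASegment] = []
    counter = 0
    for seg in segments:
        if overlaps_catalog(seg) or seg.length < min_len:
            continue
        wt = mean_level(wt_tracks, seg)
        rp = mean_level(rrp6_tracks, seg)
        ratio = rp - wt  # tracks are log2, so the level difference is the log2 ratio
        if ratio >= np.log2(fold_threshold):
            cat = "CUT"
        elif wt >= min_level:
            cat = "SUT"
        else:
            cat = "ncRNA-other"
        counter += 1
        out.append(NcRNASegment(f"ncRNA{counter:05d}", seg.chrom, seg.start,
                                seg.end, seg.strand, rp, wt, float(ratio), cat))
    return out


def ncrna_table(ncrnas: Sequence[NcRNASegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": n.id, "chrom": n.chrom, "start": n.start, "end": n.end,
        "strand": n.strand, "mean_rrp6_level": n.mean_rrp6_level,
        "mean_wt_level": n.mean_wt_level, "log2_ratio": n.log2_ratio,
        "category": n.category,
    } for n in ncrnas])
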