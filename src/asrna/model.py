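"""Genomic primitives for strand-specific tiling expression analysis.

Coordinates are 0-based half-open on every interface.  A gene's TSS and TTS
are the boundary coordinates of its interval in transcript orientation: for
a ``+`` gene the TSS is ``start`` and the TTS is ``end``; for a ``-`` gene
the anchors swap.  Windows are expressed as signed offsets from one of
these anchors and are applied along the direction of *sense* transcription
(downstream = increasing genomic coordinate for ``+`` genes, decreasing for
``-`` genes), regardless of which strand the signal is read from.

Probe signals are assumed to be already-normalised log2 intensities; an
empty interval yields an explicit missing value (``None``/NaN), never 0.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple

import numpy as np

log = logging.getLogger(__name__)

SENSE = "sense"
ANTISENSE = "antisense"

_OPPOSITE = {"+": "-", "-": "+"}


@dataclass(frozen=True)
class GeneRecord:
    """One annotated ORF with strand and TSS/TTS anchors.

    ``start < end`` always; ``tss``/``tts`` are derived from the strand under
    the 0-based half-open convention (boundary coordinates).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}: start must be < end (got {self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def anchor(self, name: str) -> int:
        if name == "TSS":
            return self.tss
        if name == "TTS":
            return self.tts
        raise ValueError(f"unknown anchor {name!r}")


@dataclass(frozen=True)
class GenomicWindow:
    """A window anchored at the TSS or TTS of a gene.

    Offsets are signed base-pair distances measured in sense-transcript
    orientation; ``target_strand`` selects whether signal/sequence is taken
    from the gene's own strand (``sense``) or the opposite one (``antisense``).
    """

    anchor: str
    offset_start: int
    offset_end: int
    target_strand: str = SENSE

    def __post_init__(self) -> None:
        if self.anchor not in ("TSS", "TTS"):
            raise ValueError(f"anchor must be 'TSS' or 'TTS', got {self.anchor!r}")
        if self.offset_start >= self.offset_end:
            raise ValueError("offset_start must be < offset_end")
        if self.target_strand not in (SENSE, ANTISENSE):
            raise ValueError(f"target_strand must be 'sense' or 'antisense'")

    @property
    def width(self) -> int:
        return self.offset_end - self.offset_start


def resolve_window(
    gene: GeneRecord,
    window: GenomicWindow,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> Tuple[str, int, int, str]:
    """Map a transcript-relative window onto genomic coordinates.

    Returns ``(chrom, start, end, strand)`` with a 0-based half-open interval
    clipped to ``[0, chrom_size)``.  A window entirely off the chromosome
    comes back as an empty interval (``start == end``).
    """
    a = gene.anchor(window.anchor)
    if gene.strand == "+":
        start, end = a + window.offset_start, a + window.offset_end
        strand = "+"
    else:
        # downstream for a - gene is decreasing coordinate
        start, end = a - window.offset_end, a - window.offset_start
        strand = "-"
    if window.target_strand == ANTISENSE:
        strand = _OPPOSITE[strand]
    lo, hi = 0, chrom_sizes.get(gene.chrom, np.inf) if chrom_sizes else np.inf
    start = int(max(start, lo))
    end = int(min(end, hi))
    if start >= end:
        start = end = max(start, 0)
    return gene.chrom, start, end, strand


class SignalTrack:
    """Strand-resolved per-position log2 intensity for one sample.

    Positions are kept strictly increasing per ``(chrom, strand)``; a prefix
    cumulative sum is cached lazily so that interval means over arbitrary
    windows cost two binary searches.
    """

    def __init__(self, sample_id: str, condition: str = "", replicate: int = 0):
        self.sample_id = sample_id
        self.condition = condition
        self.replicate = replicate
        self._pos: Dict[Tuple[str, str], np.ndarray] = {}
        self._val: Dict[Tuple[str, str], np.ndarray] = {}
        self._cum: Dict[Tuple[str, str], np.ndarray] = {}
        self._warned: set = set()

    # -- construction ------------------------------------------------------
    def set_block(self, chrom: str, strand: str, positions, values) -> None:
        pos = np.asarray(positions, dtype=np.int64)
        val = np.asarray(values, dtype=np.float64)
        if pos.shape != val.shape:
            raise ValueError("positions and values must have equal length")
        if not np.all(np.isfinite(val)):
            raise ValueError(f"non-finite intensity on {chrom}{strand}")
        if pos.size and np.any(np.diff(pos) <= 0):
            order = np.argsort(pos, kind="stable")
            pos, val = pos[order], val[order]
            if np.any(np.diff(pos) == 0):
                raise ValueError(f"duplicate probe position on {chrom}{strand}")
            log.warning("%s: unsorted positions on %s%s, sorted", self.sample_id, chrom, strand)
        self._pos[(chrom, strand)] = pos
        self._val[(chrom, strand)] = val
        self._cum.pop((chrom, strand), None)

    def keys(self) -> Iterator[Tuple[str, str]]:
        return iter(sorted(self._pos))

    def chroms(self) -> list:
        return sorted({c for c, _ in self._pos})

    def block(self, chrom: str, strand: str) -> Tuple[np.ndarray, np.ndarray]:
        return self._pos[(chrom, strand)], self._val[(chrom, strand)]

    def probe_step(self, chrom: str, strand: str) -> float:
        pos = self._pos.get((chrom, strand))
        if pos is None or pos.size < 2:
            return 1.0
        return float(np.median(np.diff(pos)))

    # -- queries -----------------------------------------------------------
    def _cumsum(self, key) -> np.ndarray:
        cum = self._cum.get(key)
        if cum is None:
            v = self._val[key]
            cum = np.concatenate(([0.0], np.cumsum(v)))
            self._cum[key] = cum
        return cum

    def _keys_for(self, chrom: str, strand: Optional[str]):
        if strand is None:
            return [k for k in self._pos if k[0] == chrom]
        key = (chrom, strand)
        return [key] if key in self._pos else []

    def region_stats(
        self, chrom: str, start: int, end: int, strand: Optional[str]
    ) -> Tuple[float, int]:
        """Sum and probe count over ``[start, end)``; ``strand=None`` pools strands."""
        total, n = 0.0, 0
        for key in self._keys_for(chrom, strand):
            pos = self._pos[key]
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            if hi > lo:
                cum = self._cumsum(key)
                total += cum[hi] - cum[lo]
                n += hi - lo
        return total, n

    def region_mean(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> Optional[float]:
        total, n = self.region_stats(chrom, start, end, strand)
        return total / n if n else None

    def binned_stats(
        self, chrom: str, strand: Optional[str], edges: np.ndarray
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Vectorised per-bin sums and counts for a flat array of bin edges.

        ``edges`` has shape ``(m, 2)``; returns ``(sums, counts)`` of length m.
        """
        edges = np.asarray(edges)
        sums = np.zeros(len(edges))
        counts = np.zeros(len(edges), dtype=np.int64)
        for key in self._keys_for(chrom, strand):
            pos = self._pos[key]
            cum = self._cumsum(key)
            lo = np.searchsorted(pos, edges[:, 0], side="left")
            hi = np.searchsorted(pos, edges[:, 1], side="left")
            sums += cum[hi] - cum[lo]
            counts += hi - lo
        return sums, counts


def region_signal(
    track: SignalTrack, chrom: str, start: int, end: int, strand: Optional[str]
) -> Optional[float]:
    """Mean probe intensity in ``[start, end)`` on one strand, or ``None``.

    An unknown chromosome/strand is treated as missing data (logged once per
    track), not as an error: chromatin and binding tracks legitimately cover
    only part of the genome.
    """
    if start >= end:
        return None
    if not track._keys_for(chrom, strand):
        key = (chrom, strand)
        if key not in track._warned:
            track._warned.add(key)
            log.warning("%s: no data for %s strand %r", track.sample_id, chrom, strand)
        return None
    return track.region_mean(chrom, start, end, strand)


@dataclass
class AnalysisConfig:
    """All fixed parameters of the classification pipeline.

    Defaults are the published study's values: 20-bp differential-expression
    bins over the -100..+750 window around the sense TSS and the mirror-image
    window along the antisense transcript (anchored at the ORF TTS), PAM with
    15 clusters, 120 subsampled robustness clusterings (k = 10..15, 20 each,
    80 % of genes), a 60 % core cut-off, 2-fold thresholds, 200-bp minimum
    ncRNA length and t1/2 = 0.693/k half-lives.
    """

    sense_window: GenomicWindow = field(
        default_factory=lambda: GenomicWindow("TSS", -100, 750, SENSE)
    )
    # the asRNA starts at the ORF TTS and runs toward the TSS: -100..+750 along
    # the antisense transcript == -750..+100 in sense-orientation offsets
    antisense_window: GenomicWindow = field(
        default_factory=lambda: GenomicWindow("TTS", -750, 100, ANTISENSE)
    )
    de_bin: int = 20
    profile_bin: int = 10
    smooth_window: int = 150
    smooth_step: int = 10
    k_main: int = 15
    k_range: Tuple[int, int] = (10, 15)
    runs_per_k: int = 20
    subsample_fraction: float = 0.8
    core_cutoff: float = 0.60
    fold_threshold: float = 2.0
    min_ncrna_len: int = 200
    motif_window: GenomicWindow = field(
        default_factory=lambda: GenomicWindow("TTS", -400, 0, ANTISENSE)
    )
    halflife_coefficient: float = 0.693
    class_epsilon: float = 0.2
    max_missing_fraction: float = 0.2
    metagene_span: Tuple[int, int] = (-500, 1500)
    h3k4_tts_window: GenomicWindow = field(
        default_factory=lambda: GenomicWindow("TTS", -300, 0, SENSE)
    )
    promoter_window: GenomicWindow = field(
        default_factory=lambda: GenomicWindow("TSS", -100, 300, SENSE)
    )
    min_level: float = 6.0
    max_gap: int = 50
    min_seg_len: int = 64
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.subsample_fraction < 1.0):
            raise ValueError("subsample_fraction must be in (0, 1)")
        if not (0.0 < self.core_cutoff <= 1.0):
            raise ValueError("core_cutoff must be in (0, 1]")
        if self.fold_threshold <= 1.0:
            raise ValueError("fold_threshold must be > 1")
        for name in ("de_bin", "profile_bin", "smooth_window", "smooth_step",
                     "k_main", "runs_per_k", "min_ncrna_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.class_epsilon < 0:
            raise ValueError("class_epsilon must be >= 0")

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, GenomicWindow):
                v = [v.anchor, v.offset_start, v.offset_end, v.target_strand]
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        kw = {}
        win_fields = {"sense_window", "antisense_window", "motif_window",
                      "h3k4_tts_window", "promoter_window"}
        tup_fields = {"k_range", "metagene_span"}
        for f in fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if f.name in win_fields:
                v = GenomicWindow(v[0], int(v[1]), int(v[2]), v[3])
            elif f.name in tup_fields:
                v = tuple(int(x) for x in v)
            kw[f.name] = v
        return cls(**kw)
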