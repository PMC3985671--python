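"""Readers and writers for the external formats the pipeline touches.

Annotation comes in as BED6/BED12 (taken as 0-based half-open) or GFF3
(1-based inclusive, shifted on read).  Signal tracks are bedGraph or wiggle
(fixedStep/variableStep) text; strand-specific tracks use the file-pair
convention ``<prefix>.plus.bedgraph`` / ``<prefix>.minus.bedgraph``.
Tabular data are TSV with a header row.  Genome sequence is FASTA via
pyfaidx.

Parsers are deliberately strict: a malformed line raises a ``ParseError``
naming the file and line number rather than silently skipping.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .model import GeneRecord, SignalTrack

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


def _err(path, lineno, msg) -> ParseError:
    return ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str, format: Optional[str] = None) -> List[GeneRecord]:
    """Read gene records from BED6/BED12 or GFF3.

    Returns genes sorted by ``(chrom, start, gene_id)``.  Duplicate gene ids
    are an error.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "GFF3" if ext in (".gff", ".gff3") else "BED"
    format = format.upper()
    if format not in ("BED", "GFF3"):
        raise ValueError(f"unknown annotation format {format!r}")
    genes: List[GeneRecord] = []
    seen: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if format == "BED":
                    if len(parts) < 6:
                        raise ValueError("expected >= 6 BED columns")
                    chrom, start, end, name, _score, strand = parts[:6]
                    rec = GeneRecord(name, chrom, int(start), int(end), strand)
                else:
                    if len(parts) != 9:
                        raise ValueError("expected 9 GFF3 columns")
                    chrom, _src, ftype, start, end, _sc, strand, _fr, attrs = parts
                    if ftype != "gene":
                        continue
                    attr = dict(
                        kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                    )
                    name = attr.get("ID") or attr.get("Name")
                    if not name:
                        raise ValueError("gene feature without ID attribute")
                    rec = GeneRecord(name, chrom, int(start) - 1, int(end), strand)
            except ParseError:
                raise
            except Exception as exc:
                raise _err(path, lineno, str(exc)) from exc
            if rec.gene_id in seen:
                raise _err(path, lineno,
                           f"duplicate gene_id {rec.gene_id!r} (first at line {seen[rec.gene_id]})")
            seen[rec.gene_id] = lineno
            genes.append(rec)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_annotation(genes: Sequence[GeneRecord], path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

def _parse_bedgraph(path: str):
    """Yield ``(chrom, pos, value)`` probes; one probe per interval, at its start."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise _err(path, lineno, "expected 4 bedGraph columns")
            chrom, start, end, value = parts[:4]
            try:
                s, e, v = int(start), int(end), float(value)
            except ValueError as exc:
                raise _err(path, lineno, f"non-numeric field: {exc}") from exc
            if not np.isfinite(v):
                raise _err(path, lineno, "non-finite value")
            if e <= s:
                raise _err(path, lineno, "empty interval")
            yield chrom, s, v


def _parse_wiggle(path: str):
    """Yield ``(chrom, pos, value)`` from fixedStep/variableStep wiggle.

    A declared ``span`` expands each record to one probe per covered base.
    """
    mode = None
    chrom = step = span = start = None
    idx = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                fieldsd = dict(kv.split("=", 1) for kv in line.split()[1:])
                mode = line.split()[0]
                chrom = fieldsd.get("chrom")
                if chrom is None:
                    raise _err(path, lineno, "declaration without chrom")
                span = int(fieldsd.get("span", 1))
                if mode == "fixedStep":
                    if "start" not in fieldsd:
                        raise _err(path, lineno, "fixedStep without start")
                    start = int(fieldsd["start"]) - 1  # wiggle is 1-based
                    step = int(fieldsd.get("step", 1))
                    idx = 0
                continue
            if mode is None:
                raise _err(path, lineno, "data before any step declaration")
            parts = line.split()
            try:
                if mode == "fixedStep":
                    if len(parts) != 1:
                        raise ValueError("fixedStep line must hold one value")
                    v = float(parts[0])
                    pos = start + idx * step
                    idx += 1
                else:
                    if len(parts) != 2:
                        raise ValueError("variableStep line must hold position and value")
                    pos = int(parts[0]) - 1
                    v = float(parts[1])
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from exc
            for off in range(span):
                yield chrom, pos + off, v


def read_track(
    path: str,
    strand: str = ".",
    sample_id: Optional[str] = None,
    condition: str = "",
    replicate: int = 0,
    format: Optional[str] = None,
) -> SignalTrack:
    """Read a single-strand track from bedGraph or wiggle text."""
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "wiggle" if ext in (".wig", ".wiggle") else "bedGraph"
    parse = _parse_wiggle if format == "wiggle" else _parse_bedgraph
    per_chrom: Dict[str, Tuple[list, list]] = {}
    for chrom, pos, v in parse(path):
        bucket = per_chrom.setdefault(chrom, ([], []))
        bucket[0].append(pos)
        bucket[1].append(v)
    track = SignalTrack(sample_id or os.path.basename(path), condition, replicate)
    for chrom, (pos, val) in per_chrom.items():
        track.set_block(chrom, strand, pos, val)
    return track


def read_stranded_track(
    prefix: str, sample_id: Optional[str] = None, condition: str = "", replicate: int = 0
) -> SignalTrack:
    """Read a ``<prefix>.plus.bedgraph`` / ``<prefix>.minus.bedgraph`` pair."""
    track = SignalTrack(sample_id or os.path.basename(prefix), condition, replicate)
    for strand, suffix in (("+", ".plus.bedgraph"), ("-", ".minus.bedgraph")):
        path = prefix + suffix
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        per_chrom: Dict[str, Tuple[list, list]] = {}
        for chrom, pos, v in _parse_bedgraph(path):
            bucket = per_chrom.setdefault(chrom, ([], []))
            bucket[0].append(pos)
            bucket[1].append(v)
        for chrom, (pos, val) in per_chrom.items():
            track.set_block(chrom, strand, pos, val)
    return track


def write_track(track: SignalTrack, prefix: str) -> List[str]:
    """Write a track back to bedGraph, one file per strand.

    Stranded tracks use the plus/minus pair convention; a strandless track
    (single ``.`` strand) becomes ``<prefix>.bedgraph``.  Values are written
    with 6 decimals so a write/read round trip is stable at that precision.
    """
    written = []
    strands = sorted({s for _, s in track.keys()})
    for strand in strands:
        if strand == "+":
            path = prefix + ".plus.bedgraph"
        elif strand == "-":
            path = prefix + ".minus.bedgraph"
        else:
            path = prefix + ".bedgraph"
        chunks = []
        for chrom, s in track.keys():
            if s != strand:
                continue
            pos, val = track.block(chrom, s)
            step = max(int(round(track.probe_step(chrom, s))), 1)
            ends = np.minimum(pos + step, np.append(pos[1:], pos[-1] + step)) if pos.size else pos
            chunks.append(pd.DataFrame({
                "chrom": chrom, "start": pos, "end": ends,
                "value": np.round(val, 6),
            }))
        df = pd.concat(chunks) if chunks else pd.DataFrame(columns=["chrom", "start", "end", "value"])
        df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# tables & sequence
# ---------------------------------------------------------------------------

def read_table(path: str, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_fasta(path: str) -> Fasta:
    return Fasta(path, as_raw=True, sequence_always_upper=True)


def write_fasta(seqs: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")
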