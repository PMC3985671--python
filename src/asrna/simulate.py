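"""Self-contained synthetic study generator.

Emulates the tiling-array study design end to end: a multi-chromosome
genome with non-overlapping genes (plus planted convergent decoy pairs and
intergenic ncRNAs), strand-specific per-probe log2 expression tracks for
wild type, the exosome mutant and the three chromatin double mutants in
triplicate, a genome FASTA with class-dependent Nrd1/Nab3 motif densities
in the antisense 5' windows, a PAR-CLiP-like binding track proportional to
motif content, an H3K4me3/H3 ratio track with 3' elevation at
antisense-producing genes, promoter-structure and decay-course tables, and
a ground-truth table for every planted feature.

All effects are additive on the log2 scale.  Class geometry follows the
published profiles qualitatively: class I antisense spans the whole gene
and runs past the TSS, class II nearly so, class III stays in the 3' third,
class IV carries only a weak Rrp6-sensitive antisense near the TTS.  A
fixed seed yields a byte-identical bundle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .classify import CLASSES, ClassAssignment
from .model import GeneRecord, GenomicWindow, resolve_window

_BASES = np.array(list("ACGT"))
_MOTIFS_ALL = ("TCTT", "GTAA", "GTAG")

CONDITIONS = ("wt", "rrp6", "set1rrp6", "hda2rrp6", "rpd3rrp6")


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_per_class: Dict[str, int] = field(default_factory=lambda: {
        "I": 30, "II": 70, "III": 400, "IV": 70, "none": 1400})
    n_convergent_pairs: int = 50
    gene_len_range: Tuple[int, int] = (800, 3000)
    probe_step: int = 8
    replicates: int = 3
    noise_sd: float = 0.3  # per-probe Gaussian noise, log2 units
    rep_offset_sd: float = 0.05  # per-replicate whole-track shift
    background_level: float = 4.0
    antisense_base: float = 4.5  # WT level over a planted asRNA region
    baseline_mean: Dict[str, float] = field(default_factory=lambda: {
        "I": 7.2, "II": 7.2, "III": 8.3, "IV": 6.5, "none": 8.3})
    baseline_sd: float = 1.0
    # planted log2 effects per class: antisense in rrp6-vs-wt, sense in
    # rrp6-vs-wt, sense in each double-vs-rrp6, antisense in set1-vs-rrp6
    effects: Dict[str, Dict[str, float]] = field(default_factory=lambda: {
        "I": {"as_rrp6": 2.0, "s_rrp6": -1.5, "s_doubles": 1.0, "as_set1": 0.0},
        "II": {"as_rrp6": 2.0, "s_rrp6": -1.5, "s_doubles": 0.0, "as_set1": -1.2},
        "III": {"as_rrp6": 2.0, "s_rrp6": 0.0, "s_doubles": 0.0, "as_set1": -1.2},
        "IV": {"as_rrp6": 0.3, "s_rrp6": 0.0, "s_doubles": 1.0, "as_set1": 0.0},
        "none": {"as_rrp6": 0.0, "s_rrp6": 0.0, "s_doubles": 0.0, "as_set1": 0.0},
    })
    # asRNA extent as a fraction of gene length, measured from the TTS
    # toward (and for class I beyond) the TSS
    as_extent: Dict[str, float] = field(default_factory=lambda: {
        "I": 1.1, "II": 0.9, "III": 0.35, "IV": 0.2, "none": 0.0})
    # expected (nab3, nrd1) motifs per 400 bp of antisense 5' window
    motif_rates: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "I": (2.0, 2.0), "II": (2.0, 2.0), "III": (6.0, 5.0),
        "IV": (2.0, 2.0), "none": (2.0, 2.0)})
    binding_background: float = 0.005
    binding_per_motif: float = 0.03
    h3k4_baseline: float = 1.0
    h3k4_tss_peak: float = 0.8
    h3k4_tts_peak: float = 0.9  # only at antisense-producing classes I-III
    h3k4_noise_sd: float = 0.05
    closed_tata_prob_class1: float = 0.7
    closed_tata_prob_other: float = 0.25
    n_cuts: int = 40
    n_suts: int = 30
    n_short_decoys: int = 15
    ncrna_len_range: Tuple[int, int] = (250, 800)
    short_len_range: Tuple[int, int] = (80, 150)
    cut_up_log2: float = 2.3
    sut_level: float = 6.8
    intergenic_range: Tuple[int, int] = (400, 1200)
    n_chroms: int = 8
    chrom_margin: int = 1000
    decay_t_halves: Tuple[float, ...] = (2.0, 5.0, 10.0, 20.0, 40.0)
    decay_timepoints: Tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0)
    seed: int = 1

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.n_per_class.values()):
            raise ValueError("class counts must be positive")
        for v in self.as_extent.values():
            if not (0.0 <= v <= 1.5):
                raise ValueError("antisense extent must be in [0, 1.5]")
        if self.probe_step <= 0 or self.replicates <= 0:
            raise ValueError("probe_step and replicates must be positive")

    @classmethod
    def small(cls, seed: int = 1) -> "SyntheticConfig":
        """A down-scaled bundle for unit tests and smoke runs."""
        return cls(
            n_per_class={"I": 6, "II": 10, "III": 40, "IV": 10, "none": 120},
            n_convergent_pairs=8, gene_len_range=(800, 1600),
            n_cuts=8, n_suts=6, n_short_decoys=4, n_chroms=3, seed=seed)

    @classmethod
    def null(cls, seed: int = 1) -> "SyntheticConfig":
        """Zero effects, zero noise: nothing should classify."""
        zero = {"as_rrp6": 0.0, "s_rrp6": 0.0, "s_doubles": 0.0, "as_set1": 0.0}
        base = cls.small(seed)
        return replace(
            base,
            effects={c: dict(zero) for c in base.effects},
            noise_sd=0.0, rep_offset_sd=0.0,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class TruthTable:
    """Planted ground truth for every generated artifact."""

    gene_class: pd.DataFrame  # index gene_id; class, convergent flag, motif counts
    ncrnas: pd.DataFrame  # planted intergenic transcripts with category
    decay: pd.DataFrame  # gene, true half-life (minutes)

    def classes(self) -> Dict[str, str]:
        return self.gene_class["class"].to_dict()


@dataclass
class _Locus:
    kind: str  # gene | ncrna
    gene: Optional[GeneRecord] = None
    cls: str = "none"
    convergent: bool = False
    as_region: Optional[Tuple[int, int]] = None  # genomic interval of asRNA
    ncrna: Optional[Tuple[str, int, int, str, str]] = None  # chrom,s,e,strand,cat


def _layout(config: SyntheticConfig, rng: np.random.Generator):
    """Place all loci on chromosomes; returns loci, chrom sizes."""
    units: List[Tuple[str, str]] = []
    for cls, n in config.n_per_class.items():
        units += [("gene", cls)] * n
    units += [("pair", "none")] * config.n_convergent_pairs
    units += [("ncrna", "CUT")] * config.n_cuts
    units += [("ncrna", "SUT")] * config.n_suts
    units += [("ncrna", "short")] * config.n_short_decoys
    order = rng.permutation(len(units))
    units = [units[i] for i in order]
    per_chrom = np.array_split(np.arange(len(units)), config.n_chroms)

    loci: List[_Locus] = []
    sizes: Dict[str, int] = {}
    gid = 0
    lo, hi = config.gene_len_range
    for ci, idxs in enumerate(per_chrom):
        chrom = f"chr{ci + 1:02d}"
        cursor = config.chrom_margin
        for ui in idxs:
            kind, tag = units[ui]
            gap = int(rng.integers(*config.intergenic_range))
            if kind == "gene":
                L = int(rng.integers(lo, hi + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                ext = config.as_extent[tag]
                ext_bp = int(round(ext * L))
                over = max(0, ext_bp - L)  # asRNA run-on past the TSS
                if strand == "+":
                    start = cursor + over
                    end = start + L
                    as_region = (end - ext_bp, end) if ext_bp else None
                    footprint_end = end
                else:
                    start = cursor
                    end = start + L
                    as_region = (start, start + ext_bp) if ext_bp else None
                    footprint_end = max(end, start + ext_bp)
                gid += 1
                g = GeneRecord(f"g{gid:05d}", chrom, start, end, strand)
                loci.append(_Locus("gene", g, tag, False, as_region))
                cursor = footprint_end + gap
            elif kind == "pair":
                l1 = int(rng.integers(lo, hi + 1))
                l2 = int(rng.integers(lo, hi + 1))
                ov = int(rng.integers(60, 251))
                gid += 1
                gp = GeneRecord(f"g{gid:05d}", chrom, cursor, cursor + l1, "+")
                gid += 1
                gm = GeneRecord(f"g{gid:05d}", chrom, cursor + l1 - ov,
                                cursor + l1 - ov + l2, "-")
                loci.append(_Locus("gene", gp, "none", True))
                loci.append(_Locus("gene", gm, "none", True))
                cursor = gm.end + gap
            else:
                rng_len = (config.short_len_range if tag == "short"
                           else config.ncrna_len_range)
                L = int(rng.integers(rng_len[0], rng_len[1] + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                loci.append(_Locus("ncrna",
                                   ncrna=(chrom, cursor, cursor + L, strand, tag)))
                cursor = cursor + L + gap
        sizes[chrom] = cursor + config.chrom_margin
    return loci, sizes


def _scrub_motifs(arr: np.ndarray, rng: np.random.Generator) -> None:
    """Mutate bases until the char array holds no Nab3/Nrd1 motif."""
    s = "".join(arr)
    for _ in range(500):
        hit = min((p for p in (s.find(m) for m in _MOTIFS_ALL) if p >= 0),
                  default=-1)
        if hit < 0:
            return
        arr[hit + 1] = rng.choice(_BASES)
        s = "".join(arr)
    raise RuntimeError("motif scrub failed to converge")


def _count_simple(s: str, motifs: Sequence[str]) -> int:
    total = 0
    for m in motifs:
        for i in range(len(s) - len(m) + 1):
            if s[i:i + len(m)] == m:
                total += 1
    return total


def _plant_motifs(
    genome: Dict[str, np.ndarray],
    gene: GeneRecord,
    rates: Tuple[float, float],
    window: GenomicWindow,
    sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> None:
    chrom, start, end, strand = resolve_window(gene, window, sizes)
    w = end - start
    if w < 8:
        return
    seg = genome[chrom][start:end].copy()
    if strand == "-":
        # work in asRNA reading direction
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seg = np.array([comp[b] for b in seg[::-1]])
    _scrub_motifs(seg, rng)
    occupied = np.zeros(w, dtype=bool)
    for rate, choices in ((rates[0], ["TCTT"]), (rates[1], ["GTAA", "GTAG"])):
        k = rng.poisson(rate * w / 400.0)
        placed = 0
        for off in rng.permutation(w - 3):
            if placed >= k:
                break
            if occupied[off:off + 4].any():
                continue
            motif = choices[int(rng.integers(len(choices)))]
            seg[off:off + 4] = list(motif)
            occupied[off:off + 4] = True
            placed += 1
    if strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seg = np.array([comp[b] for b in seg[::-1]])
    genome[chrom][start:end] = seg


def _probe_index(coord: int, step: int) -> int:
    return -(-coord // step)  # ceil division


def generate_dataset(
    config: SyntheticConfig, outdir: str, overwrite: bool = False
) -> TruthTable:
    """Write the full synthetic bundle to ``outdir`` and return its truth."""
    if os.path.exists(outdir) and os.listdir(outdir) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty (use overwrite)")
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "tracks"), exist_ok=True)
    rng = np.random.default_rng(config.seed)

    loci, sizes = _layout(config, rng)
    genes = [l.gene for l in loci if l.kind == "gene"]
    aio.write_annotation(genes, os.path.join(outdir, "annotation.bed"))

    # ---- genome sequence with planted motif densities --------------------
    genome = {c: _BASES[rng.integers(0, 4, size=n)] for c, n in sorted(sizes.items())}
    motif_window = GenomicWindow("TTS", -400, 0, "antisense")
    for l in loci:
        if l.kind == "gene" and not l.convergent:
            _plant_motifs(genome, l.gene, config.motif_rates[l.cls],
                          motif_window, sizes, rng)
    # bookkeeping pass over the final sequence
    truth_nab: Dict[str, int] = {}
    truth_nrd: Dict[str, int] = {}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for l in loci:
        if l.kind != "gene":
            continue
        chrom, start, end, strand = resolve_window(l.gene, motif_window, sizes)
        s = "".join(genome[chrom][start:end])
        if strand == "-":
            s = "".join(comp[b] for b in reversed(s))
        truth_nab[l.gene.gene_id] = _count_simple(s, ["TCTT"])
        truth_nrd[l.gene.gene_id] = _count_simple(s, ["GTAA", "GTAG"])
    aio.write_fasta({c: "".join(v) for c, v in genome.items()},
                    os.path.join(outdir, "genome.fa"))

    # ---- per-strain expression base levels -------------------------------
    sense_level: Dict[str, Dict[str, float]] = {c: {} for c in CONDITIONS}
    anti_level: Dict[str, Dict[str, float]] = {c: {} for c in CONDITIONS}
    for l in loci:
        if l.kind != "gene":
            continue
        e = config.effects[l.cls]
        b = rng.normal(config.baseline_mean[l.cls], config.baseline_sd)
        gid_ = l.gene.gene_id
        sense_level["wt"][gid_] = b
        sense_level["rrp6"][gid_] = b + e["s_rrp6"]
        for cond in ("set1rrp6", "hda2rrp6", "rpd3rrp6"):
            sense_level[cond][gid_] = b + e["s_rrp6"] + e["s_doubles"]
        if l.as_region is not None:
            ab = rng.normal(config.antisense_base, 0.2)
            anti_level["wt"][gid_] = ab
            anti_level["rrp6"][gid_] = ab + e["as_rrp6"]
            anti_level["set1rrp6"][gid_] = ab + e["as_rrp6"] + e["as_set1"]
            anti_level["hda2rrp6"][gid_] = ab + e["as_rrp6"]
            anti_level["rpd3rrp6"][gid_] = ab + e["as_rrp6"]

    # ---- probe grids and per-strain base arrays --------------------------
    step = config.probe_step
    chroms = sorted(sizes)
    positions = {c: np.arange(0, sizes[c], step, dtype=np.int64) for c in chroms}
    base: Dict[Tuple[str, str, str], np.ndarray] = {}
    for cond in CONDITIONS:
        for c in chroms:
            for strand in "+-":
                base[(cond, c, strand)] = np.full(
                    positions[c].size, config.background_level)
    opposite = {"+": "-", "-": "+"}
    for l in loci:
        if l.kind == "gene":
            g = l.gene
            i0, i1 = _probe_index(g.start, step), _probe_index(g.end, step)
            for cond in CONDITIONS:
                base[(cond, g.chrom, g.strand)][i0:i1] = sense_level[cond][g.gene_id]
            if l.as_region is not None:
                a0, a1 = l.as_region
                j0, j1 = _probe_index(a0, step), _probe_index(a1, step)
                st = opposite[g.strand]
                for cond in CONDITIONS:
                    base[(cond, g.chrom, st)][j0:j1] = anti_level[cond][g.gene_id]
        else:
            chrom, s, e, strand, cat = l.ncrna
            i0, i1 = _probe_index(s, step), _probe_index(e, step)
            if cat == "SUT":
                wt_level, rrp6_level = config.sut_level, config.sut_level
            else:  # CUT or short decoy: exosome-sensitive
                wt_level = config.antisense_base
                rrp6_level = config.antisense_base + config.cut_up_log2
            for cond in CONDITIONS:
                lvl = wt_level if cond == "wt" else rrp6_level
                base[(cond, chrom, strand)][i0:i1] = lvl

    # ---- noisy replicate tracks ------------------------------------------
    for cond in CONDITIONS:
        for rep in range(1, config.replicates + 1):
            off = rng.normal(0.0, config.rep_offset_sd) if config.rep_offset_sd else 0.0
            for strand, suffix in (("+", "plus"), ("-", "minus")):
                frames = []
                for c in chroms:
                    vals = base[(cond, c, strand)] + off
                    if config.noise_sd:
                        vals = vals + rng.normal(0.0, config.noise_sd,
                                                 size=vals.size)
                    pos = positions[c]
                    frames.append(pd.DataFrame({
                        0: c, 1: pos, 2: pos + step, 3: np.round(vals, 4)}))
                path = os.path.join(
                    outdir, "tracks", f"{cond}_rep{rep}.{suffix}.bedgraph")
                pd.concat(frames).to_csv(path, sep="\t", header=False,
                                         index=False, float_format="%.4f")

    # ---- binding track (linear counts, proportional to motif content) ----
    bind = {(c, s): np.full(positions[c].size, config.binding_background)
            for c in chroms for s in "+-"}
    for l in loci:
        if l.kind != "gene" or l.convergent:
            continue
        chrom, s0, e0, strand = resolve_window(l.gene, motif_window, sizes)
        i0, i1 = _probe_index(s0, step), _probe_index(e0, step)
        total = truth_nab[l.gene.gene_id] + truth_nrd[l.gene.gene_id]
        bind[(chrom, strand)][i0:i1] = (config.binding_background
                                        + config.binding_per_motif * total)
    for strand, suffix in (("+", "plus"), ("-", "minus")):
        frames = []
        for c in chroms:
            pos = positions[c]
            frames.append(pd.DataFrame({
                0: c, 1: pos, 2: pos + step, 3: np.round(bind[(c, strand)], 6)}))
        pd.concat(frames).to_csv(
            os.path.join(outdir, f"parclip.{suffix}.bedgraph"),
            sep="\t", header=False, index=False, float_format="%.6f")

    # ---- H3K4me3/H3 ratio track (strandless) -----------------------------
    h3 = {c: config.h3k4_baseline
          + (rng.normal(0, config.h3k4_noise_sd, positions[c].size)
             if config.h3k4_noise_sd else 0.0)
          for c in chroms}
    tss_win = GenomicWindow("TSS", -100, 300, "sense")
    tts_win = GenomicWindow("TTS", -300, 0, "sense")
    for l in loci:
        if l.kind != "gene":
            continue
        chrom, s0, e0, _ = resolve_window(l.gene, tss_win, sizes)
        h3[chrom][_probe_index(s0, step):_probe_index(e0, step)] += config.h3k4_tss_peak
        if l.cls in ("I", "II", "III"):
            chrom, s0, e0, _ = resolve_window(l.gene, tts_win, sizes)
            h3[chrom][_probe_index(s0, step):_probe_index(e0, step)] += config.h3k4_tts_peak
    frames = []
    for c in chroms:
        pos = positions[c]
        frames.append(pd.DataFrame({
            0: c, 1: pos, 2: pos + step, 3: np.round(h3[c], 4)}))
    pd.concat(frames).to_csv(os.path.join(outdir, "h3k4me3.bedgraph"),
                             sep="\t", header=False, index=False,
                             float_format="%.4f")

    # ---- promoter structure table ----------------------------------------
    prom_rows = []
    for l in loci:
        if l.kind != "gene":
            continue
        p = (config.closed_tata_prob_class1 if l.cls == "I"
             else config.closed_tata_prob_other)
        closed_tata = rng.random() < p
        if closed_tata:
            tata, occ = 1, "closed"
        else:
            tata = int(rng.random() < 0.2)
            occ = "open" if rng.random() < 0.6 else "other"
        prom_rows.append({"gene_id": l.gene.gene_id, "tata": tata, "occ": occ,
                          "tf_sites": ""})
    prom = pd.DataFrame(prom_rows).set_index("gene_id").sort_index()
    aio.write_table(prom, os.path.join(outdir, "promoters.tsv"))

    # ---- decay series -----------------------------------------------------
    decay_rows, decay_truth = [], []
    t = np.asarray(config.decay_timepoints)
    for i, th in enumerate(config.decay_t_halves, 1):
        gid_ = f"decay{i:02d}"
        levels = 2.0 ** (-t / th)
        for tp, lv in zip(t, levels):
            decay_rows.append({"gene_id": gid_, "minutes": tp, "level": lv})
        decay_truth.append({"gene_id": gid_, "t_half_true": th})
    aio.write_table(pd.DataFrame(decay_rows), os.path.join(outdir, "decay.tsv"),
                    index=False)
    decay_truth_df = pd.DataFrame(decay_truth).set_index("gene_id")
    aio.write_table(decay_truth_df, os.path.join(outdir, "truth_decay.tsv"))

    # ---- truth tables & manifest -----------------------------------------
    gene_rows = []
    for l in loci:
        if l.kind != "gene":
            continue
        gene_rows.append({
            "gene_id": l.gene.gene_id,
            "class": "convergent" if l.convergent else l.cls,
            "convergent": int(l.convergent),
            "nab3_count": truth_nab[l.gene.gene_id],
            "nrd1_count": truth_nrd[l.gene.gene_id],
        })
    gene_truth = pd.DataFrame(gene_rows).set_index("gene_id").sort_index()
    aio.write_table(gene_truth, os.path.join(outdir, "truth_genes.tsv"))
    nc_rows = [{"chrom": c, "start": s, "end": e, "strand": st, "category": cat}
               for l in loci if l.kind == "ncrna"
               for (c, s, e, st, cat) in [l.ncrna]]
    nc_truth = pd.DataFrame(nc_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    aio.write_table(nc_truth, os.path.join(outdir, "truth_ncrnas.tsv"), index=False)

    artifacts = sorted(
        os.path.relpath(os.path.join(root, f), outdir)
        for root, _dirs, files in os.walk(outdir) for f in files)
    manifest = {"seed": config.seed, "config": config.to_dict(),
                "artifacts": artifacts}
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return TruthTable(gene_truth, nc_truth, decay_truth_df)


def load_truth(bundle_dir: str) -> TruthTable:
    return TruthTable(
        aio.read_table(os.path.join(bundle_dir, "truth_genes.tsv"), index_col=0),
        aio.read_table(os.path.join(bundle_dir, "truth_ncrnas.tsv")),
        aio.read_table(os.path.join(bundle_dir, "truth_decay.tsv"), index_col=0),
    )


# ---------------------------------------------------------------------------
# evaluation against truth
# ---------------------------------------------------------------------------

def truth_compare(
    assignment: ClassAssignment,
    truth: Mapping[str, str],
    restrict: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion matrix (truth rows x assigned columns) with recall/precision.

    Planted classes ``none`` and ``convergent`` map to *unclassified*; genes
    the pipeline dropped (e.g. convergent pairs) count as unclassified too.
    ``restrict`` limits the tally to a subset of gene ids (e.g. core genes).
    """
    def norm(c: str) -> str:
        return c if c in ("I", "II", "III", "IV") else "unclassified"

    universe = set(truth)
    if restrict is not None:
        universe &= set(restrict)
    conf = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for gid in sorted(universe):
        t = norm(truth[gid])
        p = norm(assignment.gene_class.get(gid, "unclassified"))
        conf.loc[t, p] += 1
    stats = []
    for cls in CLASSES:
        planted = int(conf.loc[cls].sum())
        called = int(conf[cls].sum())
        correct = int(conf.loc[cls, cls])
        stats.append({
            "class": cls, "planted": planted, "called": called,
            "recall": correct / planted if planted else np.nan,
            "precision": correct / called if called else np.nan,
        })
    return conf, pd.DataFrame(stats).set_index("class")
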