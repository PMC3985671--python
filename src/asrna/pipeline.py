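"""End-to-end orchestration of the classification pipeline over a bundle.

A *bundle* is the on-disk input layout the synthetic generator emits (and
that real data can be massaged into): ``annotation.bed``, ``genome.fa``,
``tracks/<condition>_rep<i>.{plus,minus}.bedgraph`` for the five strains in
triplicate, ``parclip.{plus,minus}.bedgraph``, ``h3k4me3.bedgraph``,
``promoters.tsv``, ``decay.tsv`` and optional ``truth_*.tsv`` tables.

The stage functions here hold the pipeline logic; :mod:`asrna.cli` is a
thin command wrapper that adds file round-trips and the run manifest.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as aio
from .chromatin import (annotate_ncrnas, ncrna_table, promoter_enrichment,
                        segment_track, set1_effect_split, set1_split_counts,
                        window_score)
from .classify import (ClassAssignment, assign_classes, assignment_table,
                       cluster_profiles, label_genes)
from .cluster import (ClusteringResult, ConsensusResult, consensus_robustness,
                      core_scores, pam_cluster, select_core_genes)
from .features import (DEFAULT_CONTRASTS, FeatureMatrix,
                       bin_differential_expression, build_feature_matrix,
                       exclude_convergent_overlapping, half_life,
                       read_decay_table)
from .model import AnalysisConfig, GeneRecord, SignalTrack
from .profiles import (aggregate_binding, antisense_metagene, compare_groups,
                       count_motifs)
from .simulate import CONDITIONS

log = logging.getLogger(__name__)


@dataclass
class Bundle:
    bundle_dir: str
    genes: List[GeneRecord]
    tracks: List[SignalTrack]
    genome_path: str
    binding: Optional[SignalTrack]
    h3k4: Optional[SignalTrack]
    promoters: Optional[pd.DataFrame]
    decay: Optional[pd.DataFrame]

    def condition_tracks(self, condition: str) -> List[SignalTrack]:
        return [t for t in self.tracks if t.condition == condition]


def load_bundle(bundle_dir: str) -> Bundle:
    genes = aio.read_annotation(os.path.join(bundle_dir, "annotation.bed"))
    tracks = []
    for cond in CONDITIONS:
        rep = 1
        while True:
            prefix = os.path.join(bundle_dir, "tracks", f"{cond}_rep{rep}")
            if not os.path.exists(prefix + ".plus.bedgraph"):
                break
            tracks.append(aio.read_stranded_track(
                prefix, sample_id=f"{cond}_rep{rep}", condition=cond,
                replicate=rep))
            rep += 1
        if rep == 1:
            raise FileNotFoundError(
                f"no tracks for condition {cond!r} under {bundle_dir}/tracks")
    def _opt(loader, *paths):
        return loader(*paths) if os.path.exists(paths[0]) else None
    binding = None
    if os.path.exists(os.path.join(bundle_dir, "parclip.plus.bedgraph")):
        binding = aio.read_stranded_track(os.path.join(bundle_dir, "parclip"),
                                          sample_id="parclip")
    h3k4 = None
    if os.path.exists(os.path.join(bundle_dir, "h3k4me3.bedgraph")):
        h3k4 = aio.read_track(os.path.join(bundle_dir, "h3k4me3.bedgraph"),
                              strand=".", sample_id="h3k4me3")
    promoters = _opt(lambda p: aio.read_table(p, index_col=0),
                     os.path.join(bundle_dir, "promoters.tsv"))
    decay = _opt(aio.read_table, os.path.join(bundle_dir, "decay.tsv"))
    return Bundle(bundle_dir, genes, tracks,
                  os.path.join(bundle_dir, "genome.fa"),
                  binding, h3k4, promoters, decay)


def mean_track(tracks: Sequence[SignalTrack], sample_id: str) -> SignalTrack:
    """Average replicate tracks probe-wise (requires identical probe grids)."""
    out = SignalTrack(sample_id, tracks[0].condition)
    for key in tracks[0].keys():
        chrom, strand = key
        pos0, val = tracks[0].block(chrom, strand)
        acc = val.copy()
        for t in tracks[1:]:
            pos, val = t.block(chrom, strand)
            if pos.shape != pos0.shape or np.any(pos != pos0):
                raise ValueError("replicate tracks have different probe grids")
            acc += val
        out.set_block(chrom, strand, pos0, acc / len(tracks))
    return out


# ---------------------------------------------------------------------------
# stage: features
# ---------------------------------------------------------------------------

def build_features(bundle: Bundle, config: AnalysisConfig
                   ) -> Tuple[FeatureMatrix, List[GeneRecord], List[GeneRecord]]:
    kept, excluded = exclude_convergent_overlapping(bundle.genes)
    log.info("convergent filter: kept %d, excluded %d genes",
             len(kept), len(excluded))
    blocks = []
    for contrast in DEFAULT_CONTRASTS:
        for window in (config.sense_window, config.antisense_window):
            blocks.append(bin_differential_expression(
                bundle.tracks, kept, contrast, window, config.de_bin))
    fm = build_feature_matrix(blocks, config.max_missing_fraction)
    return fm, kept, excluded


def write_features(fm: FeatureMatrix, outdir: str) -> None:
    aio.write_table(fm.values, os.path.join(outdir, "features.tsv"))
    aio.write_table(fm.imputed.astype(int),
                    os.path.join(outdir, "features_imputed.tsv"))
    with open(os.path.join(outdir, "features_meta.json"), "w") as fh:
        json.dump({"blocks": fm.blocks}, fh, indent=1)


def read_features(outdir: str) -> FeatureMatrix:
    values = aio.read_table(os.path.join(outdir, "features.tsv"), index_col=0)
    imputed = aio.read_table(os.path.join(outdir, "features_imputed.tsv"),
                             index_col=0).astype(bool)
    with open(os.path.join(outdir, "features_meta.json")) as fh:
        meta = json.load(fh)
    blocks = [tuple(b) for b in meta["blocks"]]
    return FeatureMatrix(values, imputed, blocks)


# ---------------------------------------------------------------------------
# stage: clustering + consensus + core
# ---------------------------------------------------------------------------

def run_clustering(fm: FeatureMatrix, config: AnalysisConfig
                   ) -> Tuple[ClusteringResult, ConsensusResult, Dict[str, bool]]:
    base = pam_cluster(fm, config.k_main, config.seed)
    consensus = consensus_robustness(
        fm, config.k_range, config.runs_per_k, config.subsample_fraction,
        config.seed)
    core = select_core_genes(consensus, base, config.core_cutoff)
    return base, consensus, core


# ---------------------------------------------------------------------------
# stage: classification
# ---------------------------------------------------------------------------

def run_classification(fm: FeatureMatrix, base: ClusteringResult,
                       core: Mapping[str, bool], config: AnalysisConfig
                       ) -> ClassAssignment:
    profiles = cluster_profiles(fm, base)
    mapping, trace = assign_classes(profiles, config.class_epsilon)
    return label_genes(mapping, base, dict(core), trace)


# ---------------------------------------------------------------------------
# stage: downstream characterisation
# ---------------------------------------------------------------------------

def gene_body_means(tracks: Sequence[SignalTrack], genes: Sequence[GeneRecord]
                    ) -> Dict[str, float]:
    """Mean sense-strand log2 level over each gene body, replicate-averaged."""
    out = {}
    for g in genes:
        vals = [t.region_mean(g.chrom, g.start, g.end, g.strand) for t in tracks]
        vals = [v for v in vals if v is not None]
        out[g.gene_id] = float(np.mean(vals)) if vals else np.nan
    return out


def class_metagenes(bundle: Bundle, assignment: ClassAssignment,
                    config: AnalysisConfig) -> Dict[Tuple[str, str], object]:
    rrp6 = bundle.condition_tracks("rrp6")
    by_class: Dict[str, List[GeneRecord]] = {}
    for g in bundle.genes:
        cls = assignment.gene_class.get(g.gene_id)
        if cls:
            by_class.setdefault(cls, []).append(g)
    out = {}
    for cls, genes in sorted(by_class.items()):
        for anchor in ("TSS", "TTS"):
            out[(cls, anchor)] = antisense_metagene(
                rrp6, genes, anchor, config.metagene_span, config.profile_bin,
                config.smooth_window, class_label=cls)
    return out


def motif_binding_analysis(bundle: Bundle, assignment: ClassAssignment,
                           config: AnalysisConfig
                           ) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, float]]:
    """Motif counts, binding scores and the functional/non-functional tests.

    Functional antisense = classes I and II; non-functional = class III.
    Returns the per-gene tables and Wilcoxon p-values for motif counts and
    normalised Nrd1 binding (class III expected higher in both).
    """
    empty_m = pd.DataFrame(columns=["nab3", "nrd1", "class"]).rename_axis("gene_id")
    classified = [g for g in bundle.genes
                  if assignment.gene_class.get(g.gene_id, "unclassified")
                  != "unclassified"]
    if not classified:
        return empty_m, pd.DataFrame(), {}
    genome = aio.read_fasta(bundle.genome_path)
    counts = count_motifs(genome, classified, config.motif_window)
    mdf = pd.DataFrame([{
        "gene_id": m.gene_id, "nab3": m.nab3_count, "nrd1": m.nrd1_count,
        "class": assignment.gene_class[m.gene_id],
    } for m in counts]).set_index("gene_id")
    stats: Dict[str, float] = {}
    func = mdf[mdf["class"].isin(["I", "II"])]
    nonf = mdf[mdf["class"] == "III"]
    if len(func) and len(nonf):
        for col in ("nab3", "nrd1"):
            _u, p = compare_groups(nonf[col], func[col])
            stats[f"{col}_p"] = p
    bdf = pd.DataFrame()
    if bundle.binding is not None:
        wt = bundle.condition_tracks("wt")
        scores = aggregate_binding(bundle.binding, classified,
                                   config.motif_window, wt)
        bdf = pd.DataFrame([{
            "gene_id": s.gene_id, "raw_sum": s.raw_sum,
            "wt_expression": s.wt_expression, "normalized": s.normalized,
            "class": assignment.gene_class[s.gene_id],
        } for s in scores]).set_index("gene_id")
        fb = bdf[bdf["class"].isin(["I", "II"])]["normalized"].dropna()
        nb = bdf[bdf["class"] == "III"]["normalized"].dropna()
        if len(fb) and len(nb):
            _u, p = compare_groups(nb, fb)
            stats["binding_p"] = p
    return mdf, bdf, stats


def chromatin_analysis(bundle: Bundle, assignment: ClassAssignment,
                       config: AnalysisConfig):
    """H3K4me3 windows, promoter enrichments and the Set1-effect split."""
    out: Dict[str, object] = {}
    classified_ids = set(assignment.gene_class)
    genes = [g for g in bundle.genes if g.gene_id in classified_ids]
    if bundle.h3k4 is not None:
        scores = window_score(bundle.h3k4, genes, config.h3k4_tts_window)
        sdf = pd.DataFrame({
            "h3k4me3_tts": pd.Series(scores),
            "class": pd.Series({g: assignment.gene_class[g] for g in scores}),
        })
        sdf.index.name = "gene_id"
        out["h3k4_scores"] = sdf
        with_as = sdf[sdf["class"].isin(["I", "II", "III"])]["h3k4me3_tts"].dropna()
        without = sdf[sdf["class"].isin(["IV", "unclassified"])]["h3k4me3_tts"].dropna()
        if len(with_as) and len(without):
            _u, p = compare_groups(with_as, without)
            out["h3k4_p"] = float(p)
    if bundle.promoters is not None:
        prom = bundle.promoters.copy()
        prom["closed"] = (prom["occ"] == "closed").astype(int)
        enr = (promoter_enrichment(assignment, prom, "tata")
               + promoter_enrichment(assignment, prom, "closed"))
        out["enrichment"] = pd.DataFrame([{
            "class": e.class_label, "feature": e.feature,
            "a": e.table[0][0], "b": e.table[0][1],
            "c": e.table[1][0], "d": e.table[1][1],
            "odds_ratio": e.odds_ratio, "p": e.p_two_sided,
            "starred": e.starred,
        } for e in enr])
    # Set1 quartile split on ORF transcripts
    rrp6_expr = gene_body_means(bundle.condition_tracks("rrp6"), genes)
    set1_expr = gene_body_means(bundle.condition_tracks("set1rrp6"), genes)
    de = {g: set1_expr[g] - rrp6_expr[g] for g in rrp6_expr
          if np.isfinite(rrp6_expr[g]) and np.isfinite(set1_expr[g])}
    expr = {g: rrp6_expr[g] for g in de}
    if len(de) >= 4:
        split = set1_effect_split(expr, de, config.fold_threshold)
        out["set1_split"] = split
        out["set1_split_counts"] = set1_split_counts(split)
    return out


def ncrna_analysis(bundle: Bundle, config: AnalysisConfig) -> pd.DataFrame:
    rrp6_mean = mean_track(bundle.condition_tracks("rrp6"), "rrp6_mean")
    segments = segment_track(rrp6_mean, config.min_level, config.max_gap,
                             config.min_seg_len)
    ncrnas = annotate_ncrnas(
        segments, bundle.genes, bundle.condition_tracks("wt"),
        bundle.condition_tracks("rrp6"), config.min_ncrna_len,
        config.fold_threshold, config.min_level)
    return ncrna_table(ncrnas)


def halflife_analysis(bundle: Bundle, config: AnalysisConfig) -> pd.DataFrame:
    if bundle.decay is None:
        raise FileNotFoundError("bundle has no decay.tsv")
    rows = []
    for series in read_decay_table(bundle.decay):
        fit = half_life(series, config.halflife_coefficient)
        rows.append({"gene_id": fit.gene_id, "k": fit.k, "t_half": fit.t_half})
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# one-call driver (used by `asrna all`, tests and the acceptance script)
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    bundle: Bundle
    features: FeatureMatrix
    kept: List[GeneRecord]
    excluded: List[GeneRecord]
    base: ClusteringResult
    consensus: ConsensusResult
    core_flags: Dict[str, bool]
    assignment: ClassAssignment
    motifs: pd.DataFrame
    binding: pd.DataFrame
    analysis_stats: Dict[str, object]
    ncrnas: pd.DataFrame
    halflives: Optional[pd.DataFrame]


def run_pipeline(bundle_dir: str, config: AnalysisConfig) -> PipelineResult:
    bundle = load_bundle(bundle_dir)
    fm, kept, excluded = build_features(bundle, config)
    base, consensus, core = run_clustering(fm, config)
    assignment = run_classification(fm, base, core, config)
    mdf, bdf, mstats = motif_binding_analysis(bundle, assignment, config)
    chrom = chromatin_analysis(bundle, assignment, config)
    stats: Dict[str, object] = dict(mstats)
    for key in ("h3k4_p",):
        if key in chrom:
            stats[key] = chrom[key]
    if "enrichment" in chrom:
        stats["enrichment"] = chrom["enrichment"]
    ncrnas = ncrna_analysis(bundle, config)
    hl = halflife_analysis(bundle, config) if bundle.decay is not None else None
    return PipelineResult(bundle, fm, kept, excluded, base, consensus,
                          dict(core), assignment, mdf, bdf, stats, ncrnas, hl)
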