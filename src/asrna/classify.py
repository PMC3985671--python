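"""Grouping of PAM clusters into antisense-behaviour classes I-IV.

Each cluster is summarised per (contrast, orientation) by the median over
its genes of the gene's mean non-imputed binned differential expression.
The summaries drive an explicit rule engine with a dead-zone ``epsilon``
(default 0.2 log2) around zero:

* **Class IV** - sense de-repression in all three double mutants without
  appreciable Rrp6-sensitive antisense (AS_rrp6 <= eps): genes repressed by
  the HDACs/HMT already in wild type.
* **Class I**  - antisense accumulates in the exosome mutant, the gene is
  repressed there, and the repression is relieved by loss of Set1, Hda2 and
  Rpd3 (HDAC/HMT-dependent antisense silencing).
* **Class II** - antisense accumulates and the gene is repressed, but the
  chromatin mutants barely move the sense transcript (silencing independent
  of these enzymes).
* **Class III** - antisense accumulates with no effect on the ORF.
* anything else is *unclassified*; clusters whose antisense rises only in a
  double mutant but not in the exosome-only contrast land here by
  construction.

Gene-level labels are restricted to robustness-core genes; non-core genes
are unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .cluster import ClusteringResult
from .features import FeatureMatrix

CLASSES = ("I", "II", "III", "IV", "unclassified")


@dataclass
class ClusterProfile:
    cluster: int
    n_genes: int
    summary: Dict[Tuple[str, str], float]  # (contrast label, orientation) -> log2
    median_curve: Dict[Tuple[str, str], np.ndarray]


@dataclass
class ClassAssignment:
    gene_class: Dict[str, str]  # gene_id -> class
    cluster_to_class: Dict[int, str]
    rule_trace: List[dict]
    core_flags: Dict[str, bool]

    def class_counts(self) -> Dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for cls in self.gene_class.values():
            counts[cls] += 1
        return counts

    def genes_in(self, cls: str) -> List[str]:
        return [g for g, c in self.gene_class.items() if c == cls]


def cluster_profiles(
    features: FeatureMatrix, clustering: ClusteringResult
) -> List[ClusterProfile]:
    """Median per-bin curves and scalar summaries for every cluster.

    The scalar summary for a block is the median across member genes of each
    gene's mean over its non-imputed bins (imputed zeros carry no evidence
    and are left out of the gene mean).
    """
    if list(features.gene_ids) != list(clustering.gene_ids):
        raise ValueError("feature matrix and clustering cover different genes")
    profiles = []
    vals = features.values.to_numpy()
    imp = features.imputed.to_numpy()
    for c in range(1, clustering.k + 1):
        members = clustering.members(c)
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        summary: Dict[Tuple[str, str], float] = {}
        curves: Dict[Tuple[str, str], np.ndarray] = {}
        for lab, ori, _n in features.blocks:
            sl = features.block_slice(lab, ori)
            block = vals[members, sl]
            mask = imp[members, sl]
            curves[(lab, ori)] = np.median(block, axis=0)
            observed = np.where(mask, np.nan, block)
            with np.errstate(invalid="ignore"):
                gene_means = np.nanmean(observed, axis=1)
            gene_means = np.where(np.isnan(gene_means), 0.0, gene_means)
            summary[(lab, ori)] = float(np.median(gene_means))
        profiles.append(ClusterProfile(c, int(members.size), summary, curves))
    return profiles


_RRP6 = "rrp6_vs_wt"
_SET1 = "set1rrp6_vs_rrp6"
_HDA2 = "hda2rrp6_vs_rrp6"
_RPD3 = "rpd3rrp6_vs_rrp6"


def assign_classes(
    profiles: List[ClusterProfile], epsilon: float = 0.2
) -> Tuple[Dict[int, str], List[dict]]:
    """Apply the class rules to cluster summaries; returns mapping and trace."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    mapping: Dict[int, str] = {}
    trace: List[dict] = []
    for p in profiles:
        try:
            as_rrp6 = p.summary[(_RRP6, "antisense")]
            s_rrp6 = p.summary[(_RRP6, "sense")]
            s_set1 = p.summary[(_SET1, "sense")]
            s_hda2 = p.summary[(_HDA2, "sense")]
            s_rpd3 = p.summary[(_RPD3, "sense")]
        except KeyError as exc:
            raise KeyError(f"cluster {p.cluster}: missing summary {exc}") from exc
        doubles_up = s_set1 > epsilon and s_hda2 > epsilon and s_rpd3 > epsilon
        doubles_flat = max(abs(s_set1), abs(s_hda2), abs(s_rpd3)) <= epsilon
        if doubles_up and as_rrp6 <= epsilon:
            cls, rule = "IV", "derepressed in all doubles, no Rrp6-sensitive asRNA"
        elif as_rrp6 > epsilon and s_rrp6 < -epsilon and doubles_up:
            cls, rule = "I", "asRNA up, sense repressed, relieved in all doubles"
        elif as_rrp6 > epsilon and s_rrp6 < -epsilon and doubles_flat:
            cls, rule = "II", "asRNA up, sense repressed, doubles flat"
        elif as_rrp6 > epsilon and abs(s_rrp6) <= epsilon:
            cls, rule = "III", "asRNA up, sense unaffected"
        else:
            cls, rule = "unclassified", "no rule fired"
        mapping[p.cluster] = cls
        trace.append({
            "cluster": p.cluster, "class": cls, "rule": rule,
            "AS_rrp6": as_rrp6, "S_rrp6": s_rrp6,
            "S_set1": s_set1, "S_hda2": s_hda2, "S_rpd3": s_rpd3,
            "epsilon": epsilon, "n_genes": p.n_genes,
        })
    return mapping, trace


def label_genes(
    cluster_to_class: Mapping[int, str],
    clustering: ClusteringResult,
    core_flags: Mapping[str, bool],
    rule_trace: List[dict] | None = None,
) -> ClassAssignment:
    """Propagate cluster classes to core genes; non-core genes are unclassified."""
    gene_class: Dict[str, str] = {}
    for gid, lab in zip(clustering.gene_ids, clustering.labels):
        if core_flags.get(gid, False):
            gene_class[gid] = cluster_to_class[int(lab)]
        else:
            gene_class[gid] = "unclassified"
    return ClassAssignment(gene_class, dict(cluster_to_class),
                           rule_trace or [], dict(core_flags))


def assignment_table(assignment: ClassAssignment, clustering: ClusteringResult) -> pd.DataFrame:
    rows = []
    lab = clustering.labels_dict()
    for gid, cls in assignment.gene_class.items():
        rows.append({
            "gene_id": gid,
            "cluster": lab.get(gid),
            "core": bool(assignment.core_flags.get(gid, False)),
            "class": cls,
        })
    return pd.DataFrame(rows).set_index("gene_id").sort_index()
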