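"""Partitioning-around-medoids (PAM) clustering with subsampled consensus.

The base clustering uses classic PAM on Euclidean distances between feature
rows: a deterministic greedy BUILD phase followed by steepest-descent SWAP
(accept the best strictly cost-decreasing medoid/non-medoid exchange until
none exists), with first-index tie-breaking throughout.  Robustness is
assessed by re-clustering random 80 % subsamples across a range of cluster
counts and recording, for every gene pair, how often the two genes were
sampled together and how often they landed in the same cluster.  A gene is
a *core* member of its base cluster when its mean co-clustering frequency
with the other members is at least the cut-off (60 % by default).

The SWAP phase is vectorised: each iteration evaluates all k*(n-k) swaps in
O(n^2) using nearest / second-nearest medoid distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import FeatureMatrix

log = logging.getLogger(__name__)

_SWAP_TOL = 1e-9  # a swap must beat this margin to count as strictly decreasing


@dataclass
class ClusteringResult:
    k: int
    gene_ids: List[str]
    labels: np.ndarray  # cluster index 1..k per gene
    medoid_indices: np.ndarray  # positions into gene_ids, cluster order 1..k
    total_cost: float
    cost_trace: List[float]  # total cost after BUILD and after each accepted swap

    @property
    def medoid_ids(self) -> List[str]:
        return [self.gene_ids[i] for i in self.medoid_indices]

    def labels_dict(self) -> Dict[str, int]:
        return dict(zip(self.gene_ids, (int(x) for x in self.labels)))

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


@dataclass
class ConsensusResult:
    """Pairwise co-sampling / co-clustering counters over all robustness runs."""

    runs: int
    gene_ids: List[str]
    co_sampled: np.ndarray  # symmetric int32, diagonal = times sampled
    co_clustered: np.ndarray  # symmetric int32
    run_records: Optional[List[Tuple[np.ndarray, np.ndarray]]] = None

    def pair_frequency(self, i: int, j: int) -> Optional[float]:
        ns = int(self.co_sampled[i, j])
        return int(self.co_clustered[i, j]) / ns if ns else None

    def frequency_matrix(self) -> np.ndarray:
        """Pair frequencies with NaN where a pair was never co-sampled."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.co_clustered / self.co_sampled
        f[self.co_sampled == 0] = np.nan
        return f


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

def euclidean_distances(x: np.ndarray) -> np.ndarray:
    """Dense symmetric Euclidean distance matrix with an exact zero diagonal."""
    sq = np.einsum("ij,ij->i", x, x)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return d


def _pam_build(d: np.ndarray, k: int) -> List[int]:
    n = d.shape[0]
    first = int(np.argmin(d.sum(axis=1)))
    medoids = [first]
    nearest = d[first].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        nxt = int(np.argmax(gains))
        medoids.append(nxt)
        np.minimum(nearest, d[nxt], out=nearest)
    return medoids


def _nearest_two(d: np.ndarray, medoids: np.ndarray):
    dm = d[:, medoids]  # (n, k)
    a1 = np.argmin(dm, axis=1)
    rows = np.arange(d.shape[0])
    d1 = dm[rows, a1]
    if len(medoids) > 1:
        dm2 = dm.copy()
        dm2[rows, a1] = np.inf
        d2 = dm2.min(axis=1)
    else:
        d2 = np.full(d.shape[0], np.inf)
    return a1, d1, d2


def _pam_swap(d: np.ndarray, medoids: List[int]) -> Tuple[np.ndarray, List[float]]:
    n = d.shape[0]
    k = len(medoids)
    med = np.asarray(medoids, dtype=np.int64)
    b1 = np.empty_like(d)
    b2 = np.empty_like(d)
    trace: List[float] = []
    while True:
        a1, d1, d2 = _nearest_two(d, med)
        trace.append(float(d1.sum()))
        if k == n:
            break
        col1 = d1[:, None]
        # b1[j, h] = min(d(j,h) - d1(j), 0): gain for points re-attracted by h
        np.subtract(d, col1, out=b1)
        np.minimum(b1, 0.0, out=b1)
        shared = b1.sum(axis=0)  # per candidate h
        # b2[j, h] = loss/gain for j when its own medoid is removed
        np.minimum(d, d2[:, None], out=b2)
        b2 -= col1
        b2 -= b1
        order = np.argsort(a1, kind="stable")
        counts = np.bincount(a1, minlength=k)
        bounds = np.minimum(np.concatenate(([0], np.cumsum(counts)))[:-1], n - 1)
        grouped = np.add.reduceat(b2[order], bounds, axis=0)
        grouped[counts == 0] = 0.0  # empty groups get reduceat garbage; zero them
        delta = grouped + shared[None, :]  # (k, n)
        delta[:, med] = np.inf
        flat = int(np.argmin(delta))
        i, h = divmod(flat, n)
        if delta[i, h] >= -_SWAP_TOL:
            break
        med[i] = h
    return med, trace


def pam_cluster(
    features, k: int, seed: int = 0
) -> ClusteringResult:
    """Classic deterministic PAM (BUILD + steepest-descent SWAP).

    ``features`` is a :class:`FeatureMatrix` or a plain array; distances are
    Euclidean on rows.  The algorithm is deterministic, so ``seed`` only
    participates in the call signature for interface symmetry with the
    consensus procedure.
    """
    if isinstance(features, FeatureMatrix):
        x = features.matrix
        ids = features.gene_ids
    else:
        x = np.asarray(features, dtype=float)
        ids = [str(i) for i in range(x.shape[0])]
    d = euclidean_distances(x)
    return pam_from_distances(d, k, ids)


def pam_from_distances(
    d: np.ndarray, k: int, gene_ids: Optional[Sequence[str]] = None
) -> ClusteringResult:
    n = d.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = list(gene_ids) if gene_ids is not None else [str(i) for i in range(n)]
    medoids = _pam_build(d, k)
    med, trace = _pam_swap(d, medoids)
    a1, d1, _ = _nearest_two(d, med)
    labels = a1 + 1
    labels[med] = np.arange(1, k + 1)  # a medoid owns its cluster even on ties
    return ClusteringResult(k, ids, labels, med, float(d1.sum()), trace)


# ---------------------------------------------------------------------------
# consensus robustness
# ---------------------------------------------------------------------------

def consensus_robustness(
    features,
    k_range: Tuple[int, int] = (10, 15),
    runs_per_k: int = 20,
    subsample_fraction: float = 0.8,
    seed: int = 1,
    keep_runs: bool = False,
) -> ConsensusResult:
    """Subsampled re-clustering: count co-sampling and co-assignment per pair.

    For run ``r`` (enumerated over k values in increasing order, ``runs_per_k``
    each) a random subsample of ``floor(fraction * n)`` genes is drawn without
    replacement from the stream ``default_rng([seed, r])`` and PAM is run with
    that k on the induced distance submatrix.
    """
    if isinstance(features, FeatureMatrix):
        x = features.matrix
        ids = features.gene_ids
    else:
        x = np.asarray(features, dtype=float)
        ids = [str(i) for i in range(x.shape[0])]
    n = x.shape[0]
    m = int(np.floor(subsample_fraction * n))
    ks = [k for k in range(k_range[0], k_range[1] + 1) for _ in range(runs_per_k)]
    if m < max(ks):
        raise ValueError(f"subsample size {m} below largest k {max(ks)}")
    d_full = euclidean_distances(x)
    co_sampled = np.zeros((n, n), dtype=np.int32)
    co_clustered = np.zeros((n, n), dtype=np.int32)
    records: List[Tuple[np.ndarray, np.ndarray]] = []
    for r, k in enumerate(ks):
        rng = np.random.default_rng([seed, r])
        idx = np.sort(rng.choice(n, size=m, replace=False))
        d_sub = d_full[np.ix_(idx, idx)]
        res = pam_from_distances(d_sub, k)
        co_sampled[np.ix_(idx, idx)] += 1
        for c in range(1, k + 1):
            mem = idx[res.labels == c]
            if mem.size:
                co_clustered[np.ix_(mem, mem)] += 1
        if keep_runs:
            records.append((idx, res.labels.copy()))
        if (r + 1) % 20 == 0:
            log.info("consensus: %d/%d runs done", r + 1, len(ks))
    return ConsensusResult(len(ks), ids, co_sampled, co_clustered,
                           records if keep_runs else None)


def select_core_genes(
    consensus: ConsensusResult, base: ClusteringResult, cutoff: float = 0.60
) -> Dict[str, bool]:
    """Flag genes whose mean pair frequency with base-cluster mates >= cutoff.

    The mean runs over the other members of the gene's base cluster that were
    co-sampled with it at least once.  Singleton clusters are core by
    convention; a gene with no co-sampled cluster-mates is non-core.
    """
    if list(consensus.gene_ids) != list(base.gene_ids):
        raise ValueError("consensus and base clustering cover different genes")
    freq = consensus.frequency_matrix()
    flags: Dict[str, bool] = {}
    for c in range(1, base.k + 1):
        members = base.members(c)
        if members.size == 1:
            gid = base.gene_ids[members[0]]
            flags[gid] = True
            log.info("cluster %d is a singleton; %s core by convention", c, gid)
            continue
        sub = freq[np.ix_(members, members)].copy()
        np.fill_diagonal(sub, np.nan)
        score = _row_nanmean(sub)
        for gi, s in zip(members, score):
            gid = base.gene_ids[gi]
            if np.isnan(s):
                flags[gid] = False
                log.warning("%s: no co-sampled cluster-mates; non-core", gid)
            else:
                flags[gid] = bool(s >= cutoff)
    return flags


def core_scores(consensus: ConsensusResult, base: ClusteringResult) -> Dict[str, float]:
    """Per-gene mean co-clustering frequency with base-cluster mates (NaN if none)."""
    freq = consensus.frequency_matrix()
    out: Dict[str, float] = {}
    for c in range(1, base.k + 1):
        members = base.members(c)
        sub = freq[np.ix_(members, members)].copy()
        np.fill_diagonal(sub, np.nan)
        score = _row_nanmean(sub)
        for gi, s in zip(members, score):
            out[base.gene_ids[gi]] = float(s)
    return out


def _row_nanmean(a: np.ndarray) -> np.ndarray:
    """Row means ignoring NaN; all-NaN rows give NaN without warnings."""
    ok = ~np.isnan(a)
    counts = ok.sum(axis=1)
    sums = np.where(ok, a, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
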