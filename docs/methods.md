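# Methods

This note documents the models, conventions and design choices behind the
`asrna` pipeline, and what the synthetic study does and does not emulate.

## Coordinates and windows

All coordinates are 0-based half-open. A gene's TSS/TTS are the boundary
coordinates of its annotated interval in transcript orientation (for a `-`
gene, TSS = interval end, TTS = interval start). GFF3 input is shifted on
read; BED is taken as-is.

Windows are signed offset pairs from the TSS or TTS, applied along the
direction of **sense** transcription, with `target_strand` deciding which
strand the signal or sequence is read from. The sense differential-
expression window is TSS −100..+750. The antisense transcript starts at the
ORF TTS and runs toward the TSS, so "the first 750 bp of the asRNA plus
100 bp upstream of its start" is TTS −750..+100 in sense-orientation
offsets; this is the default antisense window and it is consistent with the
motif window (TTS −400..0, the asRNA's 5′ region, inside the gene 3′ end).
Windows are clipped at chromosome boundaries and the covered fraction is
reported; an entirely off-chromosome window is an explicit empty interval.

Missing signal is an explicit value (None/NaN), never 0.0: an empty bin
must not masquerade as "no change".

## Differential-expression features

Per gene, contrast and orientation, DE is the difference of mean log2
signals (a log2 fold change): replicate bin means are averaged per
condition first, then differenced. Bins are half-open 20-bp tiles covering
the window left-to-right; 850 bp is not divisible by 20, so the final bin
is truncated to 10 bp (43 bins), preserving the stated window exactly.
Within a block, bins are ordered 5′→3′ along the transcript the block
describes (for the antisense block, decreasing sense offsets). Whether
probes are averaged before or after forming ratios commutes only
approximately; mean-then-difference is fixed here.

Blocks are concatenated in a fixed order (the four contrasts in study
order, sense before antisense). Genes missing more than 20 % of entries are
dropped; remaining missing entries are imputed with 0.0 (a neutral value
that cannot create spurious class signal) and tracked in an imputation mask
so that cluster summaries can ignore them.

Convergent overlapping pairs are excluded before feature building. The
operational definition: two genes on opposite strands whose intervals
intersect by ≥ 1 bp in a staggered tail-to-tail arrangement (the `+` gene
starts left of the `-` gene and ends inside it), so the 3′ ends face each
other across the shared region. Full-containment and 5′-overlapping
(divergent) arrangements are not excluded. Both members of a qualifying
pair are removed.

## PAM and consensus clustering

Distances are Euclidean on the untransformed log2 feature rows (the
features share a scale, and Euclidean is the classic default for
k-medoids). The PAM implementation is the deterministic textbook variant:

* **BUILD** starts from the point minimising total distance and greedily
  adds the medoid with the largest cost reduction, first index winning ties;
* **SWAP** repeatedly applies the best strictly cost-decreasing
  medoid/non-medoid exchange (steepest descent, first-index tie-break)
  until none exists. Each iteration evaluates all k·(n−k) swaps in O(n²)
  via nearest/second-nearest medoid distances; the cost trace is recorded
  and is non-increasing by construction.

Determinism means the `seed` argument does not influence the base
clustering; it seeds only the subsampling of the robustness procedure,
where run *r* draws its subsample from the stream `default_rng([seed, r])`
so runs are reproducible and independently replayable.

A caveat verified during development: steepest-descent PAM is not
guaranteed to reach the global optimum even on tiny instances — degenerate
geometry can make the best swap a cost tie, which the "strictly
decreasing" rule correctly refuses. The tests therefore assert global
optimality (against exhaustive medoid enumeration) on instances with
unambiguous structure, and "global optimum or verified single-swap local
optimum" on arbitrary random instances.

Consensus bookkeeping stores, per gene pair, how often both were sampled
and how often they were co-assigned. A gene's core score is the mean pair
frequency with the other members of its base (k = 15) cluster, conditional
on co-sampling (pairs never drawn together carry no evidence); core
membership is score ≥ 0.60, boundary inclusive. Singleton clusters are
core by convention, and a gene with no co-sampled mates is non-core; both
events are logged.

## Class rules

Each cluster is summarised per (contrast, orientation) by the median over
member genes of the gene's mean over non-imputed bins. The rules use a
dead zone ε (default 0.2 log2) instead of a strict sign test — with noisy
medians a strict "above/below 0" classifies everything — and are applied
in order (the trace records the decision):

1. **IV** if all three double-mutant sense summaries exceed ε and the
   *Δrrp6* antisense summary does not (de-repression without Rrp6-sensitive
   asRNA takes precedence);
2. **I** if antisense is up, sense is down in *Δrrp6*, and all three double
   mutants relieve the repression;
3. **II** if antisense is up, sense is down, and all three double-mutant
   sense summaries stay within ±ε ("marginal" is operationalised as the
   dead zone);
4. **III** if antisense is up and the sense summary is within ±ε;
5. otherwise unclassified. Clusters whose antisense rises only in a double
   mutant but not in *Δrrp6* versus WT fail every antisense condition and
   stay unclassified by construction.

Gene labels are restricted to core genes; non-core genes are unclassified.

## Metagenes, motifs, binding, statistics

Metagene profiles take, per 10-bp bin in sense-orientation offsets around
the TSS or TTS (default span −500..+1500), the median across class genes of
the replicate-averaged antisense signal, then a centred 150-bp moving
average stepping 10 bp. Edges use shrinking windows and missing bins are
skipped with renormalisation, so the smoothed profile keeps the length and
alignment of the raw one.

Motif counting uses the Nab3/Nrd1 consensus tetramers TCTT and GTA[AG],
scanned 5′→3′ on the antisense transcript (the extracted window sequence is
reverse-complemented when the resolved strand is `-`). Overlapping
occurrences count; ambiguous bases never match. Binding scores sum the
(linear, nonnegative) cross-link track over the same window and divide by
the WT expression of the region linearised as 2^(mean log2) — a ratio of a
count to a log value would be dimensionally incoherent.

Group comparisons are two-sided Wilcoxon rank-sum tests: exact enumeration
when the smaller group has ≤ 8 values and there are no cross-group ties,
otherwise the normal approximation with tie and continuity corrections
(scipy's implementation behind the package's `compare_groups` surface).
Promoter-feature enrichment uses Fisher's exact test with the standard
two-sided definition (sum of the probabilities of all tables at fixed
margins whose point probability does not exceed the observed one); the
reported odds ratio is the sample one, a·d/(b·c). Both are cross-checked
in the tests against independent permutation / hypergeometric enumerations.

Chromatin tracks are strandless: windows still resolve through gene
orientation (so "TTS −300..0" lies inside the 3′ end for either strand)
but the signal is read strand-agnostically. The quartile × Set1-effect
split ranks transcripts by *Δrrp6* expression with ties broken by id,
cuts at equal-rank quartiles, and calls silenced/overexpressed at
∓log2(fold threshold) = ∓1.

## Segmentation and ncRNA annotation

The structural segmentation of the original tiling analysis is out of
scope; a threshold segmenter stands in as plumbing: maximal runs of probes
at or above `min_level` (default 6.0 log2) per strand, runs closer than
`max_gap` (50 bp) merged, segments shorter than `min_seg_len` (64 bp)
dropped, each segment spanning first probe to one probe-step past the last.
Segments overlapping a catalogued transcript on the same strand (≥ 1 bp)
are discarded — strandedness is essential for antisense work — and
survivors ≥ 200 bp are ncRNAs. A segment ≥ 2-fold up in *Δrrp6* versus WT
(log2 track-mean difference ≥ 1) is a CUT; otherwise detectability in WT
(≥ `min_level`, the same threshold the segmenter uses) makes it a SUT, and
the rest are ncRNA-other. Exact genome-wide ncRNA counts depend on the
segmentation threshold and on RNA preparation and are not a target; only
the rule logic is.

## Half-lives

k is minus the slope of an ordinary-least-squares fit of ln(level) against
time on control-normalised levels (≥ 3 time points, strictly increasing
from 0, all positive); t½ = 0.693/k with the printed coefficient 0.693 kept
as-is (configurable; using ln 2 instead changes half-lives by 0.02 %).
Non-decaying series get k = 0 and an infinite half-life.

## The synthetic study

The generator emulates the study design: ~1970 genes in five planted
classes (30/70/400/70/1400) plus 50 convergent decoy pairs on 8
chromosomes; gene lengths uniform 800–3000 bp; per-probe log2 signals at
8-bp spacing for the five strains in triplicate, with per-gene baselines
N(class mean, 1), additive class effects on the log2 scale, N(0, 0.3)
probe noise and N(0, 0.05) whole-track replicate offsets. Default effects:
antisense +2.0 in *Δrrp6* for classes I–III (+0.3 for IV), sense −1.5 in
*Δrrp6* for I/II, sense +1.0 in every double mutant for I/IV, antisense
−1.2 in *Δset1Δrrp6* for II/III. Antisense extents follow the published
profile shapes qualitatively: class I covers the gene and runs 10 % past
the TSS, class II 90 %, class III 35 % from the TTS; class IV is set to
20 % so that its weak effect stays inside the classification dead zone, as
its description requires. Motif densities are Poisson-planted in the
antisense 5′ window after scrubbing background occurrences (class III 6
Nab3 + 5 Nrd1 per 400 bp, all others 2 + 2), with the truth table recording
exact re-counts of the final sequence; binding is proportional to motif
content; H3K4me3 gains a 3′ peak only at antisense-producing classes;
class I promoters are closed+TATA with probability 0.7 (0.25 elsewhere).
Intergenic CUTs/SUTs, sub-200-bp decoy segments and exact exponential decay
courses complete the bundle. A fixed seed yields a byte-identical bundle.

What the generator does **not** emulate: probe-level hybridisation
chemistry, cross-hybridisation and spatial artifacts, sequence-dependent
probe affinity, correlated biological replicate variation, overlapping
tandem transcription, condition-dependent expression programs. Passing the
recovery tests therefore shows the pipeline recovers the class structure it
formalises under realistic noise — not that the published class sizes would
be reproduced on the deposited arrays, which also depend on normalisation
and manually grouped clusters.

## Problem sizes and numerical choices

The default study (~2070 genes, 344 features, 121 PAM runs on ~1580-gene
subsamples) runs in a few minutes on one CPU; unit tests use a down-scaled
preset (~200 genes) and the zero-effect/zero-noise null preset. Swap
acceptance uses a 1e-9 strict-decrease margin to avoid floating-point
cycling; consensus counters are int32; distance matrices are dense float64
(n ≈ 2000 → 32 MB). Degenerate inputs are handled explicitly: identical
points give zero-cost clusters with medoids owning their clusters on ties;
all-tied group comparisons return p = 1; zero-margin contingency tables
report a missing odds ratio and p = 1; empty bins and unknown
chromosomes/strands propagate as missing, logged once per track.
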