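# asrna

Genome-wide classification of budding-yeast genes by the behaviour of their
Rrp6-sensitive antisense RNAs across histone-modifier mutants, as a tested,
reusable pipeline.

## The problem

The *Saccharomyces cerevisiae* genome is pervasively transcribed. Many
antisense RNAs (asRNAs) are cryptic unstable transcripts (CUTs) that are
terminated early by the Nrd1/Nab3/Sen1 (NNS) complex and degraded by the
nuclear exosome; deleting the 3′–5′ exonuclease Rrp6 stabilises them. For
some genes the accumulating asRNA silences sense transcription, in a process
that can depend on the H3K4 methyl transferase Set1 and the histone
deacetylases Hda1 and Rpd3. Given strand-specific tiling expression data for
WT, *Δrrp6*, *Δset1Δrrp6*, *Δhda2Δrrp6* and *Δrpd3Δrrp6* (triplicates), the
pipeline groups genes into functional classes:

* **Class I** — asRNA accumulates in *Δrrp6*, the ORF is repressed, and the
  repression is relieved on loss of Set1, Hda2 or Rpd3 (HDAC/HMT-dependent
  antisense silencing);
* **Class II** — asRNA accumulates and the ORF is repressed, but the
  chromatin mutants barely affect sense expression;
* **Class III** — asRNA accumulates with no effect on the ORF
  ("non-functional" asRNA);
* **Class IV** — ORF de-repressed in all three double mutants with little
  Rrp6-sensitive asRNA (repressed by the HDACs/HMT already in WT);
* everything else is an **unclassified** control set.

## The method

1. **Features.** For each gene, log2 differential expression is computed in
   20-bp bins for four contrasts (*Δrrp6*/WT and each double mutant/*Δrrp6*),
   for the sense transcript over TSS −100..+750 and for the antisense
   transcript over the first 750 bp of the asRNA (anchored at the ORF TTS,
   extending into the gene) plus 100 bp upstream; the 8 blocks of 43 bins are
   concatenated into a 344-dimensional feature vector. Convergent
   overlapping gene pairs (facing 3′ ends) are excluded first.
2. **Clustering.** PAM (partitioning around medoids, deterministic
   BUILD + SWAP, Euclidean distance) with k = 15, followed by a robustness
   analysis: 120 further clusterings (k = 10..15, 20 each) on random 80 %
   subsamples. For every gene pair the co-clustering frequency
   f(i,j) = #co-clustered / #co-sampled is recorded; a gene is a **core**
   member of its cluster when its mean frequency with cluster-mates is
   ≥ 60 %.
3. **Classes.** Each cluster is summarised by the median (over genes) mean
   binned differential expression per contrast/orientation, and an explicit
   rule engine with a ±0.2 log2 dead zone maps clusters to classes I–IV.
   Core genes inherit their cluster's class.
4. **Characterisation.** Class-wise antisense metagene profiles (10-bp bins,
   150-bp moving average, TSS- and TTS-aligned); Nab3 (TCTT) and Nrd1
   (GTA[AG]) motif counts and PAR-CLiP binding in the antisense 5′ window
   (last 400 bp of the gene), compared across classes by Wilcoxon rank-sum;
   H3K4me3/H3 in TTS −300..0 and promoter windows; TATA/open-closed promoter
   enrichment by Fisher's exact test; threshold segmentation of the *Δrrp6*
   transcriptome into ncRNAs with CUT (≥ 2-fold up in *Δrrp6*) / SUT
   (detectable in WT) annotation; RNA half-lives as t½ = 0.693/k from
   log-linear decay fits.

A synthetic-data generator plants this entire structure — class effects and
antisense extents, motif densities, binding, H3K4me3 geometry, convergent
decoy pairs, intergenic CUTs/SUTs, decay courses — with known ground truth,
so every stage is testable end-to-end without external downloads.

## Worked example

```sh
cat > demo.yaml <<EOF
seed: 1
run_dir: demo_run
synthetic:
  preset: small        # ~200-gene bundle; drop this line for full scale
EOF
asrna -c demo.yaml all
```

prints

```
simulate: 202 genes, 18 planted ncRNAs -> demo_run/bundle
features: 186 genes x 344 features; 16 convergent genes excluded
cluster: k=15, cost=671.2, 177 core genes of 186
classify: I=6, II=10, III=37, IV=10, unclassified=123
profile: wrote 10 metagene tables
motifs: {"nab3_p": 5.79e-08, "nrd1_p": 2.30e-05, "binding_p": 3.55e-08}
chromatin: {"h3k4_p": 2.72e-25}
ncrna: 70 ncRNAs ({'CUT': 64, 'SUT': 6})
halflife: fitted 5 series
evaluate: core recovery 1.000 over 63 planted core genes
```

Reading this: the generator planted 6/10/40/10 genes of classes I–IV plus
120 background genes and 8 convergent decoy pairs. The convergent filter
removed exactly the 16 decoys; PAM + consensus kept 177 core genes; the rule
engine recovered every planted core gene's class (`core recovery 1.000`).
Class III windows carry more NNS motifs and more Nrd1 binding than classes
I/II (small Wilcoxon p), antisense-producing classes show elevated 3′-end
H3K4me3, and the 64 CUTs comprise the planted intergenic CUTs plus the
planted antisense transcripts themselves, which are Rrp6-sensitive by
construction. Artifacts (feature matrix, cluster/core tables, per-class gene
lists, metagene profiles, enrichment tables, run manifest with SHA-256
digests) land under `demo_run/`.

The same stages are available individually (`asrna -c cfg.yaml features`,
`cluster`, `classify`, ...) and as library functions (`asrna.run_pipeline`,
`asrna.pam_cluster`, `asrna.count_motifs`, ...).

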