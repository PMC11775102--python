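# Methods

`chromenv` integrates stage-resolved chromatin data for male germ cell
differentiation (germline stem cells GSC, primary spermatocytes SCI, round
spermatids RS): chromatin-state segmentation from binarized histone marks,
ChIP-seq peak annotation and cross-stage dynamics, enhancer classification and
gene linking, promoter chromatin-environment assignment, spike-in-anchored
differential expression, heterologous spike-in scaling for CUT&Tag signal, and
region-overlap permutation tests. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Coordinate conventions

All coordinates are 0-based half-open `[start, end)` (BED). GTF input
(1-based inclusive) is converted on read; the TSS of a minus-strand gene is
`end - 1`. Peaks are unstranded. Windows that run past a chromosome end are
clipped, not rejected, so TSS ±3 kb windows near telomeres stay usable.

## Chromatin-state model

Hidden Markov model over fixed 200 bp bins with independent Bernoulli
emissions per histone mark given the state — the emission model of the
standard chromatin-state tools. Six marks are used by default (H3K4me1,
H3K4me3, H3K27ac, H3K27me3, H3K36me3, H3K9me3).

- **Binarization**: a bin is called present when the upper-tail Poisson
  probability of its read count under the genome-wide background rate is
  ≤ 1e-4.
- **Fitting**: Baum–Welch EM with scaled forward–backward recursions
  (numba-compiled). Emissions are initialized from k-means centroids of the
  binary mark patterns, randomly perturbed per restart (5 restarts by default,
  best likelihood kept); transitions start sticky (0.95 self-transition).
  Convergence at relative log-likelihood change ≤ 1e-4 or 200 iterations.
  The log-likelihood trace is stored on the model and is monotone
  non-decreasing (EM guarantee; tests tolerate 1e-6 relative float noise).
  Chromosomes are independent sequences sharing one initial distribution.
- **Decoding**: per-bin posterior argmax (forward–backward), not Viterbi,
  matching the cited tools' segmentation behaviour; runs are run-length
  encoded into a segmentation that tiles each chromosome.
- **State naming**: learned states are numbers; mnemonic labels (TSSA, TxWk,
  EnhA, …) are assigned by the user (or, in the synthetic pipeline, by
  Hungarian matching of fitted emissions to the generating patterns). An
  18-state vocabulary pools to 13 states (TSSFlnkD→TSSFlnk, EnhG1/2→EnhG,
  ReprPCWk→ReprPC, Quies1-3→Quies), and the 13 states map onto six
  categories: active (TSSA, Tx, EnhG, EnhA), weak (TSSFlnk, TxWk, EnhW),
  heterochromatin (ZNF/Rpts, Het), bivalent (TssBiv, EnhBiv), polycomb
  (ReprPC), quiescent (Quies).

Emission probabilities inside likelihood computations are clipped to
[1e-10, 1-1e-10]; stored parameters are not clipped, so the one-state model
returns empirical mark frequencies exactly.

## Peak annotation and dynamics

Peaks are annotated into four categories with an explicit priority —
promoter > intragenic > downstream > distal intergenic — where promoter means
overlap with TSS ± 3 kb (strand-aware anchor, boundary-inclusive), intragenic
means overlap with a gene body, and downstream means within 3 kb past the 3′
end (the window mirrors the TSS window; the choice is configurable). The
priority rule makes multi-feature overlaps deterministic.

Cross-stage dynamics: peaks from all stages are union-merged into maximal
regions (strictly overlapping, ≥1 bp; book-ended peaks stay separate); a
region is present at a stage when it overlaps any peak of that stage by ≥1 bp.
The presence pattern names the class (`common`, `GSC-spe`, `GSC-SCI`,
`GSC-RS`, …) and classes with ≤100 regions are flagged `minor` rather than
dropped, so every pattern stays recoverable.

Per-chromosome density is peaks per Mb; stage ratios report ∞ when the
denominator stage has zero peaks and the numerator does not, and missing when
both are zero.

TSS metagene profiles split genes into expression percentile groups (deciles
by default), flip minus-strand genes so positions run 5′→3′, sample flanks at
native 50 bp resolution, and rescale gene bodies to 100 meta-bins. Genes
shorter than two signal bins are excluded and counted.

## Chromatin environment, enhancers, gene links

The predominant state of a region is the label covering the most bp; exact
ties break by category priority (active > bivalent > polycomb > weak >
heterochromatin > quiescent), then lexicographically — ambiguity is rare but
the rule makes it deterministic. Promoter environments use TSS ± 3 kb and also
record the runner-up state and fraction as an ambiguity check.

"H3K79me2+" means ≥1 bp overlap with a mark peak (configurable minimum).
Enhancer records are maximal runs of EnhA/EnhG/EnhW/EnhBiv. Gene linking
measures boundary-to-boundary gaps (0 for overlap) and keeps genes within
100 kb; `nearest` mode returns the closest gene (ties kept and flagged),
`all` mode every gene in range. Per-gene H3K79me2 localisation is GB (body
overlap), ENH (any linked enhancer is mark-positive), GB-ENH, or none — a
partition. Linked-gene expression contrasts use the two-sided Wilcoxon
rank-sum between mark-positive and mark-negative enhancers per class, BH
corrected across the four classes; groups with fewer than two enhancers get a
missing p.

## Spike-in differential expression

Library sizes are computed over non-control genes only, so sequencing depth is
carried by the endogenous transcriptome while the spike-ins (ERCC) inform the
unwanted-variation factors. cpm filtering keeps genes with ≥1 cpm in ≥2
samples; control rows are always kept.

**Control-gene normalization** follows the RUVg construction: row-centred
log(count + 0.5) of the control genes, SVD, first k right singular vectors as
the per-sample unwanted factors W (orthonormal), which are regressed out of
every gene's log expression and returned for use as covariates (k = 1 by
default; the source analyses do not state k).

**Threshold test**: per-gene negative binomial model. Dispersion is a
method-of-moments estimate on depth-normalized counts per group, shrunk 75%
toward the common (median) dispersion and floored at 1e-4. The log fold
change and its standard error come from a closed-form group-total estimator
(delta method on the NB mean–variance relation) or, when covariates are
supplied, from a per-gene NB GLM with a log-library-size offset. The test is
a shifted Wald against H0: |log2FC| ≤ log2(1.5) — both tail shifts contribute
to p, the TREAT idea — with BH correction; status is up/down only when
fdr < 0.05 *and* the estimated |FC| > 1.5. This is an original implementation:
numerical agreement with edgeR's glmTreat is not claimed; agreement is at the
level of operating characteristics, which the acceptance suite measures
(null false-call fraction, sensitivity on planted four-fold effects).

Feature enrichment contrasts up (and down) genes against non-deregulated genes
on length deciles, the six-group biotype scheme (IG-TR, protein_coding,
pseudogene, lncRNA, mtRNA, snoRNA; unmapped biotypes are reported as "other"),
and chromosome, by chi-square; when expected cell counts fall below 5 the test
switches to a seeded Monte-Carlo permutation chi-square (flagged in the
output), since no exact r×c test is available in the stack.

## CUT&Tag spike-in scaling

Heterologous spike-in nuclei are added at a fixed ratio to target cells, so
spike-genome reads measure per-cell recovery. Scale factor_i = reference /
spike_reads_i with the reference defaulting to the minimum spike count across
samples — factors stay ≤1 and noise is never amplified. Profiles are linear in
the factors. Class-stratified TSS profiles scale each sample's track by its
factor, average within genotype, anchor at the TSS ± 3 kb and flip
minus-strand genes.

## Region-overlap permutation tests

Statistic: number of query (A) regions overlapping ≥1 subject (B) region.
Null: `circular` (one random rotation per chromosome, preserving region count,
lengths and spacing — the default, as it preserves clustering) or
`random_regions` (uniform re-placement preserving lengths, optionally avoiding
a mask). p uses the +1 permutation correction, so min p = 1/(n_perm+1);
z = (obs − mean)/sd of the permuted statistics; the normalized z divides by
√|A| so multi-set matrices are comparable. The matrix mode runs all ordered
pairs from one seed stream and flags significance by BH at 0.05. The overlap
statistic is discrete: with sparse region sets the attainable p-values are few
and the +1 correction makes them conservative; null-uniformity checks
therefore use dense sets where the statistic is quasi-continuous.

## Synthetic data: the stated world

The default scenario is a toy-scale analogue of a stage-resolved germ-cell
study: two 5 Mb autosomes, a 3 Mb chrX and a 1 Mb chrY; 2,000 non-overlapping
genes on both strands with log-normal lengths (median 2 kb — scaled to the toy
genome, not to mm10 where median gene length is an order of magnitude larger);
six marks emitted by a 13-state model with field-typical emission patterns and
0.95 self-transition; three stages of peaks with planted presence patterns
(35% common, 20% RS-specific, the rest split across the other five patterns),
geometric lengths around 800 bp at 30 regions/Mb, placed non-overlapping with
exact Poisson counts so planted densities are recovered to counting error; a
planted 10× RS-stage rate on chrX (the sex-chromosome acquisition pattern);
and a 3 KO vs 3 CTL negative binomial count matrix (dispersion 0.1, mean 100,
92 ERCC rows) with ±2 log2FC planted on 100 up and 100 down genes.

Two generator choices are deliberate and load-bearing:

- The planted unwanted sample factor is standardized to its stated magnitude
  (sd 0.3 in the pipeline, 0.6 in the acceptance check) and planted orthogonal
  to the genotype contrast. With six samples a random factor can be too weak
  to dominate the leading expression direction and can partially align with
  genotype — a confounding no k=1 factor method can resolve, and one the RUVg
  model itself assumes away. The generator therefore states the world the
  method is defined for.
- Planted up-genes sit at repressed/bivalent promoters and receive H3K79me2
  only at a linked, non-overlapping enhancer; planted down-genes sit at active
  promoters with mark-positive bodies. This is the environment-dependent
  regulation structure the integration layer is meant to recover.

What the generator does **not** emulate: read-level noise, GC and mappability
structure, replicate-level peak calling, realistic gene length and density
(at 2,000 genes on 14 Mb, promoter windows tile most of the genome, so the
annotation fractions are promoter-heavy — unlike a real genome), transcript
isoforms, and any dependence between chromatin state and peak placement. A
green test therefore establishes algorithmic correctness and recovery of
planted structure at stated effect sizes — not biological validity on real
data.

## Determinism

Every generator and every stochastic analysis step takes an explicit seed;
the pipeline derives per-stage seeds from one master seed via a seed sequence.
Two runs with the same seed produce hash-identical output tables (the resolved
config copy differs only in its recorded output path).
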