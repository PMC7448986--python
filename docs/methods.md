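# Methods

This note describes the models and procedures implemented in
`chemoscan`, the choices made where the design was genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## Overview

The package re-implements, as a tested pipeline, a homology-based
annotation protocol for insect chemosensory receptor families (odorant
receptors, OR; gustatory receptors, GR; ionotropic receptors, IR)
followed by comparative analyses between two closely related species:

1. translated search of reference proteins against the genome,
2. chaining of hits into candidate loci with 2-kb flanks,
3. spliced gene-model construction per locus (best model retained),
4. retention/pseudogene/family-consistency curation, run in two rounds
   (round 2 adds the round-1 proteins as queries),
5. transcript-based completeness accounting,
6. family phylogenies with bootstrap supports and sister-leaf
   orthologue pairing, and
7. a pairwise M7-vs-M8 codon site-model test for positive selection
   with NEB/BEB site identification.

A synthetic-genome forge generates all inputs with known truth, so
every stage is measurable at desk scale.

## Translated search

Each scaffold is translated in six frames; query proteins are aligned
locally (Smith–Waterman, affine gaps, BLOSUM62 with `*` columns floored
at −4 so that stop codons do not terminate alignments through
pseudogene exons; gap open −11, gap extend −1). Genome-scale frames are
pre-screened with exact amino-acid 5-mer seeds clustered by diagonal
(two seeds per cluster by default); every candidate window is then
re-aligned by full local DP, so reported scores are exact DP scores on
the reported regions. E-values use fixed ungapped Karlin–Altschul
parameters for BLOSUM62 (λ = 0.3176, K = 0.134) with
E = K·m·n·e^(−λS), n being the total translated search space. Absolute
e-values therefore differ from NCBI BLAST, which estimates gapped
parameters per search, but the 1e-5 cutoff keeps its meaning of "score
far beyond what the search space produces by chance", and the whole
stage is deterministic.

## Locus chaining

Two HSPs chain iff they share scaffold and strand, the genomic gap is
at most `max_intron` (default 15 kb), the query intervals advance
colinearly along the coding strand (≤10 aa overlap tolerated), and the
chain span stays within `max_locus_span` (50 kb). A repeat of
already-covered query region forces a split, which separates tandem
duplicates. Chains from different queries with overlapping genomic
ranges merge into one locus. The defaults exceed observed beetle
receptor intron sizes while still splitting clusters, and are
config-exposed; the source protocol did not state its chaining
constants, so these are declared reconstructions.

## Spliced gene models

Inside each flanked locus the best-supported references (top 5 by
summed HSP bit score) are aligned to the locus DNA by a local dynamic
program with states for codon match (BLOSUM62 on the translated
codon), codon insertion/deletion (3-bp steps, affine), single-base
frameshifts (−20 each, counted), internal stops (scored −15, counted,
written as X), and introns: a zero-length-cost jump from a GT donor to
an AG acceptor at least 30 bp downstream, charged a flat −10, allowed
only between codons. Only canonical GT–AG introns are modelled. The
penalties are set so one frameshift outweighs any single mismatch but
does not reject a model outright. The DP kernel is JIT-compiled
(numba) and runs rolling score rows with full pointer matrices, so a
400-aa protein against a 10-kb locus takes tens of milliseconds.
Model scores are alignment-score units private to this implementation;
only their ranking is meaningful, and ties break toward fewer
frameshifts, fewer stops, longer proteins, then lexicographic
reference id. The model protein is the translation of the predicted
CDS (not the reference), so downstream curation sees what the genome
encodes.

## Curation and the two rounds

A model with ≥1 internal stop or frameshift is a pseudogene and is kept
regardless of length. Clean models are full length at ≥0.9 of the
reference length (the protocol counts full-length genes without
defining the cutoff; 0.9 is declared and config-exposed), retained as
partial at ≥ max(0.5 × reference length, 191 aa) — i.e. strictly more
than 190 aa — and rejected otherwise. Family consistency: the model
protein is scored against a labelled database (all family references
plus decoy proteins); the candidate is removed if the best hit is a
decoy or the winning family leads the runner-up family by under 5 bits.
Where two loci reconstruct the same gene (an exon chain split by a weak
internal exon), only the best-scoring model is kept.

Round 2 repeats search→chain→model with the round-1 retained proteins
added as queries and as modelling references, merging loci across
rounds. One consequence of using round-1 proteins as references is that
a truncated gene modelled from its own round-1 protein can classify as
"full" relative to that shorter reference; gene-level recovery is
unaffected, but round-2 partial counts are a lower bound. The forge's
round-2 rescue scenario plants a paralog pair in which the hidden
gene's short exons fall below search significance against the only
(heavily diverged) external reference while remaining clearly
detectable through its annotated paralog; the margins on both sides of
the significance threshold are ≥2.5 standard deviations of the
per-exon score, so the property is stable across seeds.

## Completeness accounting

A transcript is a family candidate if its best translated alignment to
a family reference covers at least 120 aa (OR/GR) or 190 aa (IR),
counted as aligned residue pairs. A candidate counts as found in the
annotation if it aligns to an annotated protein of the family at ≥90%
identity over at least the same length (the identity rule is declared
here; the source protocol did not state one). The report counts total,
found, and missing candidates per family.

## Trees and orthologue pairs

Proteins under 230 aa (OR) or 250 aa (GR) are excluded from trees; IRs
have no extra filter. Alignment is MAFFT (single thread, deterministic).
Distances are maximum-likelihood JTT distances — with gamma rate
heterogeneity (4 categories, shape picked per family by maximizing the
mean pairwise likelihood over a grid) and empirical amino-acid
frequencies for ORs and GRs, plain JTT for IRs — estimated on a dense
log-spaced branch-length grid with quadratic refinement (grid-limited
accuracy ~1%, ample for tree building). The tree is neighbor joining
over that matrix; node support is the percentage of column-resampled
bootstrap replicates (distances and NJ recomputed) containing each
bipartition; rooting is on the edge above the designated outgroup clade
(Orco for ORs, sugar receptors for GRs, IR8a/25a for IRs), with an
optional midpoint fallback. NJ over ML distances replaces a full ML
topology search deliberately: it is exact on additive matrices,
deterministic, orders of magnitude faster, and the downstream contract
(bootstraps, rooting, pair extraction) is unchanged. An orthologue pair
is the strictest reading of 1:1 orthology: two leaves from the two
focal species whose MRCA has exactly those two descendants; each gene
appears in at most one pair.

## Site-model selection test

Orthologue-pair proteins are MAFFT-aligned and the alignment guides the
codon alignment (stop-containing columns removed with a warning). The
substitution process is a GY94-style model on the 61 sense codons:
single-nucleotide changes at rate proportional to the target codon
frequency, ×κ for transitions, ×ω for nonsynonymous changes. Codon
frequencies are uniform by default, which keeps the matrix symmetric
(one eigendecomposition serves all branch lengths) and makes the
simulator and the fitter exactly self-consistent; this is a documented
divergence from codeml's F3x4 default. Site variation in ω: M7 is
beta(p, q) discretized into K = 10 equal-probability categories
(category means); M8 adds a class at ω_s ≥ 1 with weight 1 − p0. Branch
length t is expected substitutions per codon averaged over the mixture.
Likelihoods are maximized by bounded L-BFGS-B with multi-start
(t ∈ [1e-4, 20], κ ∈ [0.1, 20], p, q ∈ [0.05, 50], p0 ∈ [0, 1],
ω_s ∈ [1, 20]); the M8 fit always includes a start at the M7 optimum
with p0 = 1, so lnL(M8) ≥ lnL(M7) up to optimizer tolerance by
construction.

The LRT is Δ = max(0, 2(lnL_M8 − lnL_M7)) referred to χ² with df = 1 —
the convention of the protocol this package follows — with df = 2
available as an option (the usual codeml recommendation for M7-vs-M8).
NEB site posteriors are computed at the MLEs; BEB averages NEB-style
posteriors over a 6-points-per-dimension grid on (p0, p, q, ω_s)
spanning the fitting bounds (log-spaced where the bounds are wide),
weighting each grid point by its data likelihood under a uniform prior;
t and κ stay at their MLEs. A degenerate one-point grid reproduces NEB
exactly, which the tests exploit. A pair is called positively selected
iff P < 0.01 and at least one site reaches posterior ≥ 0.95 under both
NEB and BEB.

Power at these settings deserves a caveat: with only two sequences, the
per-site information is small. Under the benchmark alternative
(n = 300 codons, t = 0.5, p0 = 0.5, ω_s = 2) the LRT alone rejects at
P < 0.01 in roughly a quarter of replicates and the full decision rule
(which also needs a 0.95-posterior site) fires in about one in ten,
even though the parameter estimates themselves are close to truth
(median ω̂_s ≈ 2.4 and p̂0 ≈ 0.65 at n = 500). This mirrors the known
behaviour of site-model LRTs on minimal trees: the test is valid (the
measured null false-positive rate at P < 0.01 is ≈ 0, consistent with
the boundary mixture making df = 1 conservative) but weak for pairs at
moderate ω_s, and detections on real pairs should be read accordingly.

## Synthetic data

The forge plants multi-exon genes (default 2–6 introns of 60–400 bp,
proteins of 380–460 aa, receptor-like sizes) on uniform-random
scaffolds (GC 50%, so no accidental homology), with two 4-gene tandem
clusters at 5% nucleotide divergence inside 50-kb windows, stop
pseudogenes (one sense codon → TAA), frameshift pseudogenes (1-bp
deletion), and 5'-truncated partials, each derived from an intact
parent at 8% nucleotide divergence so that parent references detect
them. References are outgroup-style copies of the intact proteins at
15% amino-acid divergence. Transcripts are concatenated exons with
small end truncations; genome-absent genes can be injected to exercise
the completeness check. The codon simulator shares the GY94 matrix code
with the fitter verbatim. All randomness flows from a single seed per
artifact; identical spec + seed reproduces outputs byte for byte.

What the forge does **not** emulate: repeats and transposable elements,
GC heterogeneity and codon-usage bias, non-canonical (GC–AG) splice
sites, sequencing/assembly error, alternative isoforms, and real
family-wide homology structure (solo genes are unrelated random
proteins). Passing benchmarks therefore demonstrates the pipeline's
algorithmic correctness and its behaviour under the stated divergence
structure, not performance on real assemblies, where repeat-induced
spurious loci and assembly fragmentation dominate the error budget.

## Benchmark problem sizes

The standard recovery benchmark uses the 2-Mb, 60-gene forge at five
seeds; spliced-alignment exactness uses 50 constructed loci; the search
oracle check uses 200 random small instances; tree benchmarks use 100
additive matrices and 20 planted families (25-replicate bootstraps for
recovery, 200 for the determinism check); the null LRT study uses 60
replicates of 300 codons, the power study 12 replicates at 300 codons,
and the recovery study 20 replicates at 500 codons with the full
five-restart optimizer. These sizes give stable pass/fail margins for
every property while keeping a full run on one CPU within minutes.
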