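# Methods

This note documents the statistical models, the synthetic-data generator
that stands in for real cohorts, the numerical choices, and the known
limitations of the package.

## Peak calling and differential methylation

Windows of 50 nt at 25 nt steps tile each gene's exonic (transcript) span;
a trailing partial window is kept when the uncovered tail is at least half
a window.  Within a condition, counts are **pooled across replicate IP and
input libraries** and each window is tested with the one-sided exact
hypergeometric tail of the 2×2 table contrasting the window's IP/input
split with the rest of the transcriptome.  Pooling trades replicate-level
dispersion modeling for a fully specified exact test whose p-values can be
verified against a rational-arithmetic enumeration oracle; a per-replicate
GLM (as in exomePeak2) is out of scope and equivalence with exomePeak2
output is not claimed.  BH correction runs across all windows; significant
windows with a genomic gap ≤ one step merge into peaks, whose p is the
minimum member-window p and whose enrichment is
log2((IP CPM + 1)/(input CPM + 1)) over the merged span.

Differential methylation operates on the union peak set of the two
conditions.  The four counts (tumour IP/input, normal IP/input summed over
the peak span) are scaled to the mean library depth and rounded, then
tested two-sided (Fisher).  The significance rule is **raw p < .05** — the
rule the analysis chain defines — with BH q always reported next to it.
diff log2FC uses a pseudocount of 1 on each cell, so identical tables give
exactly 0.

The per-gene relative m6A level uses peak spans when a gene has significant
peaks and the whole gene otherwise; genes are ranked by level and cut into
tertiles of near-equal size (the "tristile").

## Why the paired-aliquot noise model

The generator draws, for every replicate and window, a latent Gamma rate
(shape 1/φ) shared by the IP library and its **matched** input; both counts
are Poisson around that rate and the methylation enrichment fold
multiplies the IP rate only.  Marginally both libraries are NB(μ, φ) with
variance μ + φμ².  The sharing is what makes the matched input a valid
control: biological abundance fluctuations cancel in the IP-vs-input
contrast, and the conditional window split is binomial — exactly the
sampling model the pooled exact test assumes.  With independent NB noise
in the two libraries instead, the exact test is strongly anticonservative
(measured: ~10% of windows called under a fold-1 null) and no windowed
count test of this form could be calibrated; the paired construction is
therefore part of the generator's design, not a tuning choice.

## Synthetic cohort: what it emulates and what it does not

Defaults (SimConfig): 200 genes, half pseudogenes with subtype proportions
processed 0.72 / unprocessed 0.20 / unitary 0.05 / polymorphic 0.03;
6 tumour and 7 normal IP/input MeRIP pairs (the tissue design of the
MeRIP cohort being emulated); 50 tumour / 30 normal expression samples (a
scaled-down tumour-vs-normal cohort); 30 reads/window mean input depth;
NB dispersion φ = 0.1 (typical bulk RNA-seq); enrichment fold 4 at planted
sites; 30% of genes methylated, of which 15% are tumour-specific (hyper)
and 15% normal-specific (hypo); DE fraction 10% at |log2FC| = 2;
pseudogene–parent latent coupling ρ = 0.6 with attenuation of the coupling
by m6A level for processed pseudogenes (slope 0.8 of the normalized
level); expression–m6A coupling mean ∝ exp(−γ·level) with γ = 0.3;
survival log-HR ln 2 per SD of the risk genes' expression with 20%
censoring; mutation rate 0.005 and CNV rate 0.03 per gene×sample.

Planted motif GGACU (within RRACH) is written strand-aware into the genome
at the centre of each designated methylation window.  Each pseudogene gets
a unique parent (sampled without replacement when enough coding genes
exist) so every pair's latent coupling is independent; real parent
mappings are many-to-one, which only dilutes per-pair correlations.  The
ceRNA coupling acts on the log-mean scale through a shared per-sample
Gaussian latent (σ = 0.8); NB sampling noise attenuates the realized
Spearman ρ below the latent ρ, so ρ is a coupling strength, not a target
correlation.  One "candidate" pseudogene is planted with the full
oncogenic profile (hypo-m6A, up-regulated, risk-prognostic, genetically
clean, sharing a miRNA seed site with its positively correlated parent);
other differential-m6A genes are decoupled from the concurrent-DE
direction so the planted profile is unique by construction.

Censoring is an independent exponential with rate λ0·c/(1−c), which gives
the configured censoring fraction c exactly at β = 0 and within a few
points for the default β.

Not emulated: batch effects between cohorts, GC/mappability bias,
read-level structure (counts are generated at window/gene level), isoform
diversity, many-to-one parent families, wobble or 3′-compensatory miRNA
pairing, and tumour purity.  Passing tests therefore demonstrate method
correctness under the stated generative assumptions, not performance on
real sequencing data.

Randomness: a single master seed feeds named substreams (CRC32 of the
component name mixed into a SeedSequence), so adding a generator component
never perturbs the draws of another, and identical configs give
byte-identical pipeline outputs.

## Differential expression

Per gene, CPM-normalized counts give group means m_t, m_n and
log2FC = log2((m_t+1)/(m_n+1)).  The gene-wise NB dispersion comes from a
method-of-moments estimate on the CPM scale — the Poisson term subtracted
is μ times the mean CPM scale factor (1e6/depth), not μ itself — with
negative raw values retained through a 20-bin mean trend and a 50/50
shrink toward it (flooring only the final value), because truncating at
zero first biases the dispersion upward and makes the test conservative.
The Wald statistic uses a delta-method standard error and a normal
reference; with the trend-stabilized dispersion the statistic is close to
pivotal, and the null type-I rate on 2000-gene NB simulations sits within
the binomial 95% band of the nominal 0.05.  CPM normalization carries the
usual compositional caveat: strong asymmetric DE shifts library sizes and
can bias null genes; the package keeps CPM for transparency rather than
adopting median-of-ratios.

## Survival screen

The univariate Cox fit maximizes the Efron-corrected partial likelihood by
damped Newton iteration (halving steps that would decrease the
log-likelihood), converging at |Δβ| < 1e-8 or 50 iterations; the Wald p
uses the observed information.  Covariates are z-scored by default so β is
per SD; two-group contrasts should pass `standardize=False` to keep β on
the group-indicator scale.  A constant covariate raises a
non-identifiability error; a monotone likelihood (perfect separation) is
flagged and β capped at ±10.  KM curves are product-limit estimates and
the two-group log-rank test is delegated to lifelines, cross-checked in
the tests against a hand-computed expected-events statistic; the default
dichotomization for KM is the median split.

## Motif discovery

Presence/absence (ZOOPS-like) counting; one-sided Fisher exact test via
the hypergeometric tail; the best exact word seeds a greedy IUPAC
generalization that accepts a degenerate code only on strict p
improvement; matches of a reported motif are masked with N before the next
round, so presence counts strictly decrease and the procedure terminates
within `max_motifs` rounds.  The stop rule is Bonferroni: best p ≥
α / (number of candidate words tested).  Mononucleotide shuffling (not
dinucleotide) generates the controls, preserving each sequence's base
multiset.  RRACH matching asks whether the motif's IUPAC match set is a
subset of RRACH's at some alignment offset.

## Candidate cascade and ranking

The ordered filters and their defaults: (1) differential m6A at raw
p < .05; (2) "expressed" operationalized as per-sample CPM ≥ 1 in at least
half the samples of one cohort (an explicit detectability rule standing in
for an undefined "stabilized RNA" notion); (3) concurrent DE opposite in
sign to the m6A change — directional by default (hypo→up, hyper→down),
with a non-directional switch; (4) prognosis at p < .05 consistent with
the expression direction (up+risk or down+protective); (5) genetic
confound exclusion at mutation frequency < 1% and CNV frequency < 5%;
(6) optional ceRNA support (≥1 shared miRNA and a Positive parent
correlation).  Survivors always form a subset chain, and a missing input
layer skips its filter with a flag rather than failing.

The rank score sums z-scores of the **magnitudes** of the three effects
(diff-m6A log2FC, expression log2FC, Cox β) over survivors.  Taking |z| of
the signed effects instead would make any two-survivor comparison a tie
(their z-scores are ±1), violating the intended monotonicity — larger
effects must rank first — so the magnitudes are standardized before
summing.  Ties break by smaller diff-m6A p, then id.

## Assay utilities

2^-ΔΔCt, V = 0.5·A·B², wound-closure %, and a one-phase decay fit
y = plateau + (y0 − plateau)·e^(−kt) with the plateau fixed at 0 by
default (abundances are fractions of the t = 0 level; a free plateau is
exposed as a parameter).  A fitted k ≤ 1e-8 — numerically zero decay, the
least-squares optimum on constant data — reports an undefined half-life
with a flag.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; GTF converts at the I/O
  boundary, BED output stays 0-based.  One transcript model per gene.
* Region labels are strand-aware; peak annotation uses the peak midpoint
  and the precedence 3′UTR > 5′UTR > exon > TSS > TTS > intron >
  intergenic (configurable); TSS/TTS flanks default to 1000 nt.
* Alphabets: motifs and seed matching normalize RNA to DNA (U→T)
  internally and render motifs back as RNA.
* The Spearman sign classification uses ρ > 0 for Positive — the
  convention the invariant requires, fixing an inconsistency in some
  published figure legends where both classes are printed with "< 0".
* Tertile boundaries round to the nearest third, so sizes differ by at
  most two for any gene count.
* Library functions stand behind standard steps: gffutils (GTF), Biopython
  (FASTA), scipy/statsmodels (exact tests, rank statistics, BH),
  lifelines (KM/log-rank, plus an independent cross-check of the Cox
  solver).  The Cox solver, the NB Wald DE test, the windowed peak caller,
  the motif search and the seed-site scanner are implemented here, each
  with an independent oracle in the tests.

## Problem sizes used in the test and acceptance runs

Peak-caller recovery uses 200-gene cohorts at enrichment fold 4 and
30 reads/window (three seeds) plus fold-1 null runs; DE calibration uses
2000 null genes at n = 10/group; Cox recovery uses 100 replicates of
two-group cohorts with 500 subjects per group; motif recovery uses 40 runs
of 50 planted sequences; the end-to-end check runs 20 master seeds of the
200-gene pipeline.  These sizes make every stochastic criterion stable
under reasonable seed changes while keeping a full run in the
single-digit-minutes range on one CPU.

## Limitations

No BAM/FASTQ ingestion, no multi-isoform collapsing, no liftover, no
replicate-aware dispersion in peak calling, no multivariate or
time-dependent Cox, no thermodynamic or conservation scoring of miRNA
sites, and no figure rendering (all outputs are plain TSV/BED/JSON).  The
external worked example for the RPS15AP12 transcript ORF requires the user
to supply the transcript sequence; it is not bundled.
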