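# Methods

## Problem setting

A tumor biopsy is a mixture of cell populations: diploid stromal cells and
one or more tumor subclones, each subclone genetically homogeneous but
carrying its own copy-number aberrations (CNAs). A SNP array or a counting
assay applied to such a sample measures, per locus, the *average* number of
A- and B-allele copies across all cells — a coefficient-weighted linear
combination of the component genotypes. Recovering the exact per-component
copy numbers from this aggregate is an underdetermined linear problem as
soon as three or more components are present (see "De-mixing" below), so
`mixcna` instead reduces CNA analysis to a three-state question per locus:
is the dominant aberrant component a **gain**, a **loss**, or is the locus
**normal**?

## Coordinates

Aggregate allele channels (a, b) are transformed per locus to

- B-allele frequency `beta = b / (a + b)` — 0.5 at a balanced
  heterozygote, 0 or 1 at homozygotes;
- total-DNA enrichment `rho = (a + b) / 2` — 1 at a diploid locus — and
  `log_r = log2(rho)`.

Zero-coverage loci get `beta = 0.5` by convention, so a homozygous deletion
does not register as allelic imbalance; its `rho = 0` carries the deletion
evidence (`log_r` is undefined there and the classifier clamps `rho` at a
floor of 1/64 before taking logs).

## The M-measure

Aberrations in a fraction of cells push heterozygous-SNP `beta` values away
from 0.5 while homozygous SNPs stay pinned near 0/1. The per-SNP imbalance
function

    f(beta) = |sin(2*pi*beta)|

vanishes at the three normal-state values {0, 1/2, 1} and rises steeply
between them (it is a product of trigonometric functions,
`sin 2x = 2 sin x cos x`). The M-measure of a SNP is the mean of `f` over
the *informative* SNPs of a symmetric window of `window` SNPs (default 20,
i.e. 10 on each side; windows shrink at chromosome ends). Informative means
`min(beta, 1 - beta) > hom_beta_margin` (default 0.1): homozygous SNPs
carry no imbalance information, and averaging over them would bound the
score by the heterozygosity rate (~9.5%), below any usable cutoff. A window
with no informative SNP scores 0 — no evidence, not evidence of normality.
The imbalance function is injectable (`ClassifierConfig.imbalance_fn`) so
other members of this measure family can be swapped in.

## Three-state classification

A SNP is flagged aberrant when its M-measure exceeds `m_cutoff`
(default 0.1) **or** when a one-sided z-test finds its windowed mean
`log_r` significantly below 0 at level `logr_alpha` (default 0.01). The
second clause covers the M-measure's one blind spot: a hemizygous deletion
carried by nearly all cells drives heterozygous `beta` onto 0/1, where `f`
vanishes, but halves the total DNA. The z-test uses the global median
absolute deviation of `log_r` (scaled by 1.4826) as its robust noise scale,
so aberrant segments inflate it little.

Flagged SNPs are labeled by the sign of their windowed mean `log_r`: loss
below `-logr_tolerance`, gain above `+logr_tolerance` (default 0.02). A
flagged SNP inside the tolerance band stays normal — copy-neutral imbalance
is not a copy-number event and is outside the simulated truth.

### Viterbi variant (3SMM)

The same per-SNP observations (M-measure, windowed mean `log_r`) can be
decoded with a three-state HMM (normal / loss / gain), with transition
probabilities from add-one-smoothed truth bigrams and per-state independent
Gaussian emissions fit on truth-labeled loci (`fit_hmm_from_truth`; in the
CLI, where no truth exists, the threshold classifier's own calls serve as
pseudo-truth). Ties in the Viterbi recursion break toward normal. In our
experiments decoding does not improve on plain thresholding — the loss of
performance at high stromal fractions comes from the fading aberrant
signal, not from call-level noise a smoother could remove — which is why
the threshold classifier is the default.

## De-mixing

**Binary case.** With one tumor component plus diploid stroma at
coefficient `x`, a deletion locus with aggregate copy number `c < 2`
satisfies `c = 2x + m(1 - x)` with tumor copy number `m ∈ {0, 1}`, so
`x = (c - m)/(2 - m)`. Both candidates are computed at every deletion locus
(by default the classifier's loss calls), candidates outside [0, 1] are
discarded, and the pooled candidates are histogrammed in 0.01-wide bins
over [0, 1]; the modal bin's center is the estimate `x̂`, since the true
`x` must solve every locus while wrong-hypothesis candidates scatter.
Histogram ties break toward the bin with the smaller within-bin variance.
Bin assignment adds a 1e-6-bin nudge before flooring so candidates sitting
a float-representation error below a bin edge land in the intended bin.
Each locus then receives the `m` whose candidate lies nearer `x̂`.

**General case.** For k ≥ 3 components the system is underdetermined even
in the binary-genotype toy setting. `enumerate_demixings` makes this
concrete: it searches all k-subsets of components whose per-allele profiles
range over the 2^s − 1 nonzero binary vectors on s loci, with coefficient
vectors on a positive grid summing to 1, and returns every exact
reconstruction (deduplicated up to component permutation; repeated
components are excluded since they collapse to a smaller k). Two
independent components reconstruct uniquely; three do not. Guard rails
(s ≤ 12, k ≤ 4) keep the search exhaustive; this is a demonstration
device, not a production solver.

## Simulator

The simulator emulates an Illumina-style SNP-array experiment on a mixture:

- **Germline**: two binary haplotypes, heterozygous per locus with
  probability 0.095 (homozygous loci split evenly AA/BB).
- **Subclones**: the germline plus 1,000-locus aberration blocks —
  homozygous deletion, hemizygous deletion, gain of one copy, gain of two —
  separated by 1,000 normal loci over 10,000 loci. The parental haplotype
  removed or duplicated is chosen by one seeded coin per block, so each
  block shows a coherent split `beta` band rather than per-locus scatter.
  With two subclones, the second grid is shifted by half a block with kinds
  rotated by one, so the aggregate contains overlapping aberration
  combinations (including deletion with duplication) while kinds never
  conflict within one subclone.
- **Mixing**: stroma at `alpha` with one subclone at `1 - alpha`, or two at
  `2(1-alpha)/3` and `(1-alpha)/3`.
- **Noise**: i.i.d. Gaussian noise added to the aggregate A and B channels
  *before* the `beta`/`rho` transform, so both coordinates inherit
  correlated noise; channels are clipped at zero. The default SNR of 30 is
  on the amplitude scale: noise SD = mean(channel)/30 (≈ 0.033 per
  channel). We chose the amplitude convention because it yields the tight,
  well-separated B-allele bands characteristic of real BeadStudio exports
  and an operating point at which the default cutoff of 0.1 separates
  aberrant from normal windows; a power-ratio convention at the same
  nominal value (SD ≈ 0.25) would drown the heterozygous bands entirely.
  `snr_scale="power"` remains available.

The per-locus **truth label** is the state of the aberrant component with
the largest mixing coefficient at that locus (ties to the earlier
subclone); loci aberrant in no component are normal.

What the simulator does *not* emulate: probe-specific bias and GC waves,
non-linear array normalization, recombination or realistic linkage,
copy-neutral LOH, and focal events shorter than a block. Passing tests
therefore certify the statistical machinery on idealized mixtures, not
robustness to array artifacts.

## Evaluation

With no threshold to sweep, the ROC of a fixed three-state caller reduces
to its operative point, where the area under the curve equals the balanced
accuracy `(TP/P + TN/N)/2`. The score is the unweighted mean of the
one-vs-rest balanced accuracies of gain, loss and normal. An absent class
(P = 0 or N = 0) contributes 1, so aberration-free data called all-normal
scores 1.0. `run_mixture_experiment` reports mean and replicate standard
deviation of this score per (alpha, caller) over seeded independent
simulations; the replicate count defaults to 200, with smaller counts (the
experiments below use 20) giving the same means within a few thousandths.

## RNA-seq within-exon imbalance

In the absence of subclonal heterogeneity and DNA-level CNA, allelic
imbalance is constant along an exon; expression confounders (allele-specific
expression, per-subclone expression level, splicing) shift whole exons, not
single sites. Subclone-private point mutations instead give different sites
of the same exon different variant-allele fractions — a germline
heterozygous site at 0.5 next to a somatic site at the carrier-fraction
sum. Sites covered by at least `min_reads` reads (default 100) are scored
with `0.5 − |0.5 − #B/(#A+#B)|` and an exact binomial (Clopper–Pearson)
95% CI on the variant fraction. Every within-exon pair of passing sites
with disjoint CIs is emitted as a heterogeneity call (all pairs are
emitted with an adjacency flag, so a consecutive-sites-only reading is
recoverable from the output); pairs closer than the read length (default
50 bp, configurable) are flagged as excluding a focal CNA shared by all
subclones, which would shift both sites together. CI disjointness is a
descriptive criterion and is reported uncorrected; the optional Fisher
exact mode tests each pair on the 2×2 read-count table with
Benjamini–Hochberg correction across all pairs of the run. Indel-adjacent
sites are expected to be masked upstream; a `masked` column in the input
table is honored.

The RNA-seq fixture generator draws binomial read counts at the configured
depth with variant-allele probability equal to the summed fraction of
carrier subclones (0.5 at germline heterozygous sites), i.e. equal
expression of both alleles and across subclones. It emulates sampling
noise only — not over-dispersion, mapping bias or RNA editing.

## Numerical and design notes

- All randomness flows through `numpy.random.Generator` seeded per run;
  experiment replicate seeds derive from one `SeedSequence`.
- Windowed statistics use truncated symmetric windows (convolution with a
  (2·⌊W/2⌋+1)-tap kernel divided by in-window counts).
- The depressed-`rho` z-test critical value is `Phi^{-1}(logr_alpha)`; with
  a noiseless profile the MAD noise scale is floored at 1e-9, so any
  negative windowed mean fires the test, which is the intended limit.
- Default problem sizes (10,000 loci, 20 replicates per alpha in the
  shipped experiments) were chosen as the smallest runs whose replicate
  means are stable to ~0.003; the scoring itself is O(n).

## Known limitations

- The classifier assumes aberrations spanning many SNPs; events shorter
  than about one window are attenuated by design.
- Copy-neutral LOH is deliberately reported as normal.
- The mixing-coefficient solver assumes exactly one tumor component and a
  CNA-free stroma; with several subclones it estimates a signal-weighted
  compromise, not any single coefficient.
- Balanced accuracy weights classes equally regardless of prevalence; with
  96% normal loci a caller can score well while missing short events.
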