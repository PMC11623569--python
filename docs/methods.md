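# Methods

## Observation model

The atomic observation is a pileup site: at reference position *i* in one
library, *d* reads span the position and *k* of them carry a single-base
deletion. Bisulfite treatment converts pseudouridine into an adduct that
reverse transcriptase skips, so in the treated library *k/d* at a uridine
estimates the fraction of transcript molecules modified there (the
stoichiometry); in the untreated library deletions are background noise
(sequencing/alignment artifacts and, in communities, strain indels).

Two conventions fix the semantics everywhere:

* **Depth denominator.** *d* counts all spanning reads, including the
  reads carrying the deletion — standard pileup semantics, where a deleted
  base still yields a spanning alignment. The simple-TSV dialect makes
  this explicit by carrying `del` and `nondel` columns with
  `depth = del + nondel`.
* **Coordinates and strands.** Internal coordinates are 1-based inclusive;
  BED exports are 0-based half-open and say so in a header. Calling is
  unstranded: reference T is a uridine candidate of the + strand
  transcript, reference A of the − strand. Strand assignment to a
  transcript happens only at annotation overlap, which is what makes
  antisense-transcript discovery possible without strand-specific
  libraries.

## Callers

**Isolate mode** applies hard thresholds to each treated/untreated pair:
depth ≥ 20 in both, treated deletions ≥ 5, treated fraction ≥ 0.05,
untreated fraction < 0.01. Stoichiometry is the treated fraction (the
untreated fraction is already forced to near zero). A position absent from
the untreated table has depth 0 there and simply fails the depth filter.

**Microbiome mode** keeps the depth/count floors, lowers the treated
fraction floor to 0.02, and replaces the untreated cutoff with a ≥ 2-fold
enrichment requirement plus a one-sided Fisher exact test (*p* < 0.01) on
[[k_t, d_t − k_t], [k_u, d_u − k_u]]. An untreated fraction of exactly 0
passes the fold filter by convention (infinite fold). Stoichiometry is the
Δ deletion fraction, floored at 0. The test is one-sided because the
hypothesis is directional (BS treatment adds deletions); no
multiple-testing correction is applied across sites — the fixed *p*
cutoff is part of the published operating point. The Fisher p-value comes
from `scipy.stats.fisher_exact`; the test suite checks it against a
brute-force hypergeometric enumeration for every 2×2 table with total
≤ 60.

**High confidence.** Sites called at the identical (reference, position,
strand) in ≥ 2 distinct treated libraries — biological replicates or
different growth conditions — are flagged high-confidence; merged records
carry the union of supporting libraries and per-library fractions, with
displayed fractions averaged. Homopolymer-run equivalence is *not* used
for matching: because calls inside uridine runs are left-aligned (below),
identical-position matching already matches runs consistently.

**Homopolymer ambiguity.** A deletion inside a run of ≥ 2 consecutive
uridines cannot be attributed to one base from left-aligned alignments.
Calls in runs are flagged and reported at the run's lowest reference
coordinate (the position aligners left-align to, on either strand). No
redistribution heuristic is attempted.

## Per-base deletion-ratio diagnostic

Quality control for the chemistry: pool deletions and depth per reference
base genome-wide, compute the per-base frequency, and report for each base
the mean of its three pairwise frequency ratios, e.g.
ratio(U) = mean(U:A, U:G, U:C). Pooling counts (rather than averaging
per-site fractions) stabilises the estimate at low coverage. On a balanced
(~50% GC) reference with base-independent noise every ratio is ~1; real
BS-treated RNA drives the uridine ratio far above 1. A base class with
zero aggregate depth is reported missing, never as ratio 0. All positions
are included (no masking of known rRNA/tRNA sites); the diagnostic is a
genome-wide property, and masking would require annotations the caller
does not otherwise need.

## Transcript-level quantities

* **Ψ-strength** of an RNA = Σ deletion fractions over its Ψ sites (0 for
  an unmodified gene). Genotype/condition contrasts are computed over the
  union of genes seen in either group, with absent genes contributing 0 —
  a site lost in a knockout is exactly the signal sought.
* **PUS assignment**: gene attributed to the knocked-out enzyme when
  WT − mutant strength ≥ 0.05 in *every* replicate pair; replicates are
  paired by index. Genes may be assigned to several enzymes by running
  several contrasts.
* **Stress differential**: same rule with stress − control. Reported genes
  whose control strength reaches min_delta/2 in any replicate are flagged
  `review_flag` — borderline cases that would otherwise need manual
  curation — rather than removed.
* **TPM** with pseudocount 1: rate_g = (count_g + 1)/length_g, scaled to
  sum to 10⁶ per sample. In community mode, genes with < 5 reads in every
  sample are removed before normalisation.
* **Structure pairing**: a dot-bracket symbol '.' at the site is
  unpaired, '(' or ')' paired; unbalanced strings warn but classify.
* **Correlation with abundance**: Spearman (tie-corrected, via
  `scipy.stats.spearmanr`) of sites-per-kb vs TPM and of the mean per-site
  Ψ level vs TPM; constant vectors yield a missing correlation.

## Motifs

Each call contributes one k-mer in transcript orientation (minus-strand
sites reverse-complemented, T written as U), Ψ at offset `k_up`; default
window 2+1+2 = 5, the window of the most frequent bacterial motif
(GGUAU). Shorter published motifs (GUUC, UCC, UUGC) emerge from the
consensus summariser, not from changing the window. Sites are filtered to
deletion fraction strictly above a threshold — by default the empirical
median of the input, a dataset statistic, with an override flag — then
motifs seen < 5 times are dropped. WT-vs-knockout contrasts use the
two-sided Wilcoxon rank-sum test (`scipy.stats.mannwhitneyu`): exact
permutation null for tie-free groups of ≤ 10, tie-corrected normal
approximation otherwise; identical groups give p = 1. p-values are
BH-adjusted across the motifs of one contrast (statsmodels), and a motif
is significant only when it *decreased* in the mutant (median WT > median
mutant). Fractions are pooled per site across samples rather than
averaged per sample — the site is the sampling unit of the assay. The
consensus reporter is a transparent position-frequency matrix with modal
bases, lowercased below 0.5 modal frequency; it replaces EM-style motif
discovery deliberately, trading power for auditability.

## Antisense discovery

A high-confidence call (≥ 2 supporting libraries) inside a gene's interval
on the *opposite* strand is an antisense candidate; positions covered by
genes on both strands are discarded as ambiguous. Distances to known TSS
are measured in the antisense transcript's direction (downstream on the −
strand = decreasing coordinate) and reported when within 0–200 bp
inclusive. External promoter/terminator predictors are ingested as score
tables, never reimplemented: the search regions are 200 bp upstream and
150 bp downstream of the Ψ site (starting one base away from it), only
windows scoring ≥ 0.9 qualify, and the highest-scoring window wins. The
predicted TSS is the promoter window's edge facing the Ψ site, and the
sRNA span runs inclusively from the TSS to the midpoint of the TTS
window. For even-length windows the midpoint is floored in the direction
of transcription on both strands, which makes the prediction exactly
strand-symmetric (a pure floor in genomic coordinates would not be).

## Synthetic benchmark

The simulator works directly in pileup space: read simulation and
alignment would add aligner dependence without exercising more of the
method, which consumes pileups. Per position, depth ~ Poisson(mean
depth); untreated deletions ~ Binomial(depth, background); treated
deletions ~ Binomial(depth, background + stoichiometry) at planted sites.
Defaults: 100 kb reference, i.i.d. bases at 50% GC (the balanced
composition under which the null diagnostic is ~1), 100 non-overlapping
600-nt genes on alternating strands, 1,000 Ψ sites planted at genic
uridines with stoichiometry uniform on [0.05, 0.8] (spanning well below
and above the calling floor), background deletion rate 0.001, mean depth
150. The depth default reflects deep isolate RNA-seq and deliberately
avoids the 100× grid point where a single background deletion in the
untreated half equals exactly the 1% cutoff (1/100), which rejects true
sites through a denominator artifact rather than a property of the
caller. Strain heterogeneity (community mode) designates a random subset
of positions with an elevated deletion rate in *both* libraries — a
strain indel is in the template, so both halves inherit it — producing
exactly the false-positive class the fold-change and Fisher filters
remove. Each stage (reference, truth, each sample) draws from an
independent seed stream, so adding samples never perturbs the reference.

What the simulator does not model: sequencing errors other than
deletions, quality scores, coverage autocorrelation along transcripts,
expression-dependent depth, alignment artifacts around indels, and
incomplete BS conversion. Passing benchmarks therefore demonstrate the
correctness and calibration of the *computation* under its stated noise
model, not the end-to-end accuracy of the wet-lab assay.

## Numerical and design choices

* Fraction thresholds are compared with ≥ / < exactly as stated in the
  calling rules; the motif fraction filter is strictly `>`.
* Ties in the rank-sum test switch the implementation to the asymptotic
  tie-corrected path; the exact path is used only when valid.
* Degenerate inputs: empty pileup files parse to empty tables with a
  warning; zero-depth sites are excluded from fractions and diagnostics;
  an all-zero 2×2 margin is rejected as an empty table; a constant vector
  yields a missing correlation, not 0.
* Problem sizes in the test suite (10–100 kb genomes, 30–1,000 planted
  sites, depth 100–150, exhaustive exact-test checks to table total 60
  and group size 6) were chosen so each property is measured with
  comfortable statistical margin at desk scale.

## Known limitations

* Sites within ~k bases of a contig edge are skipped in motif extraction.
* The ≥ 2-sample rule requires identical coordinates; sites wandering
  between samples across a long homopolymer run are matched only through
  left-alignment.
* Microbiome mode applies no FDR control across sites; with millions of
  tested positions the fixed p < 0.01 cutoff relies on the preceding
  fold/fraction filters for specificity.
* TPM ingests externally produced count tables; counting reads from
  alignments is out of scope.
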