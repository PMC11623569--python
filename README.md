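# psiscan

Quantitative mapping of pseudouridine (Ψ) in bacterial RNA from bisulfite
deletion signatures.

## The problem

Pseudouridine is the most abundant RNA modification, but bacterial mRNA Ψ
has been hard to map: classical CMC-based profiling (Pseudo-seq) is
insensitive, and the newer bisulfite (BS) chemistries were designed around
poly-A selection, which bacteria lack. In the BS approach, treating RNA
with bisulfite forms a BS-Ψ adduct that makes reverse transcriptase skip
the base, leaving a **single-nucleotide deletion** in the cDNA at every Ψ
position. Sequencing a BS-treated and an untreated half of the same RNA
sample and comparing per-base deletion counts therefore reveals Ψ sites at
base resolution — and quantitatively: the deletion fraction *k/d*
(deletions over spanning-read depth) estimates the fraction of transcript
molecules modified at that site, so a deletion fraction of 0.5 means 50%
stoichiometry.

`psiscan` implements the downstream computation of this assay for
bacteriologists and microbiome researchers: it consumes per-base pileup
count tables (bam-readcount output, or a simple 6-column TSV), calls Ψ
sites, quantifies stoichiometry and transcript-level Ψ load, assigns sites
to pseudouridine synthase (PUS) enzymes via knockout contrasts, detects
stress-responsive pseudouridylation, summarises sequence motifs, discovers
antisense RNA candidates, and provides a community (microbiome) calling
mode. A ground-truth simulator makes every stage testable without
sequencing data.

## The method

A uridine position (reference T on the + strand, A on the − strand — the
assay needs no strand-specific library prep) is called a Ψ site when, in a
paired treated/untreated sample:

* **isolate mode** — depth ≥ 20 in both samples, treated deletion count
  ≥ 5, treated deletion fraction ≥ 5%, untreated fraction < 1%. Reported
  stoichiometry = treated deletion fraction.
* **microbiome mode** — strain heterogeneity inflates untreated deletion
  rates, so the hard untreated cutoff is replaced by: treated fraction
  ≥ 2%, treated ≥ 2× untreated, and one-sided Fisher exact *p* < 0.01 on
  the 2×2 (deletions, non-deletions) table. Reported stoichiometry =
  Δ deletion fraction (treated − untreated).

Sites called in ≥ 2 treated libraries (replicates or different growth
conditions) are **high-confidence**. Per transcript, the **Ψ-strength** is
the sum of deletion fractions over its sites; a gene is attributed to a
PUS enzyme (or flagged as stress-responsive) when its Ψ-strength drops
(rises) by ≥ 0.05 in every replicate of a knockout (stress) contrast.
Abundance is TPM with a pseudocount of 1. A genome-wide diagnostic
computes the per-base deletion ratio mean(U:A, U:G, U:C): ~1 under random
noise, ≫1 in BS-treated Ψ-containing RNA.

## Worked example

Simulate a benchmark (50 kb genome, 300 planted Ψ sites, two replicates),
call both replicates, and aggregate:

```bash
printf 'genome_length: 50000\nn_genes: 50\nn_psi_sites: 300\nn_replicates: 2\n' > sim.yaml
psiscan simulate --config sim.yaml --seed 7 --out sim/
psiscan call-isolate --treated sim/37C_rep1_BS.pileup.tsv \
    --untreated sim/37C_rep1_untreated.pileup.tsv \
    --ref sim/reference.fa --out calls_rep1/
psiscan call-isolate --treated sim/37C_rep2_BS.pileup.tsv \
    --untreated sim/37C_rep2_untreated.pileup.tsv \
    --ref sim/reference.fa --out calls_rep2/
psiscan aggregate calls_rep1/calls.tsv calls_rep2/calls.tsv --min-samples 2 --out hc/
psiscan strength --calls hc/high_confidence.tsv --gff sim/genes.gff3 --out strength/
```

which prints

```
7 files written to sim/
292 sites called -> calls_rep1/calls.tsv
293 sites called -> calls_rep2/calls.tsv
283 high-confidence sites -> hc/high_confidence.tsv
50 genes -> strength/psi_strength.tsv
```

Of 300 planted sites, 292/293 pass the per-replicate filters (the rest sit
below the 5%-fraction or 5-deletion floor) and 283 replicate in both
libraries. The call table carries per-site stoichiometry and flags:

```
reference  pos  strand  treated_frac  untreated_frac  psi_proportion  ...  high_confidence  homopolymer_flag
ref_1      435  +       0.812174      0.0032258       0.812174             1                0
ref_1      493  +       0.102388      0               0.102388             1                1
```

(the second site sits in a uridine run, so its exact position is ambiguous
and it is reported left-aligned with `homopolymer_flag=1`). The
genome-wide diagnostic,

```bash
psiscan diagnostics --pileup sim/37C_rep1_BS.pileup.tsv --ref sim/reference.fa --out diag/
```

prints deletion ratios near 4 for T *and* A — uridines of plus- and minus-strand
transcripts respectively — against 0.45 for C/G, the unstranded deletion
signature of BS-treated Ψ:

```
base  aggregate_depth  deletions  frequency    ratio
   A          1875111      11102   0.005921 4.253200
   C          1848643       1872   0.001013 0.451113
   G          1891459       1919   0.001015 0.452605
   T          1883637      10355   0.005497 3.925231
```

The same operations are available as a library (`psiscan.call_sites_isolate`,
`psiscan.tpm`, `psiscan.assign_pus`, …); see the module docstrings and
`docs/methods.md`.

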