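"""Synthetic paired treated/untreated pileups with ground-truth Psi sites.

The generator works directly in pileup space: per-position depths are drawn
around a mean coverage, untreated deletion counts are binomial at a small
base-independent background rate, and treated deletion counts at planted
Psi positions are binomial at background + stoichiometry.  This emulates
the deletion signature that bisulfite treatment leaves at pseudouridines
during reverse transcription, without simulating reads or alignment — the
calling method consumes pileups, so pileups are what the benchmark plants
truth into.

Microbiome mode adds strain heterogeneity: a random subset of positions
carries an elevated deletion rate in *both* libraries (a strain indel is in
the template, so treated and untreated halves inherit it alike).  These are
the false-positive candidates the community-mode fold-change and Fisher
filters exist to remove.

Everything is driven by one integer seed; equal configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .io_formats import AnnotationSet, Gene, write_annotation, write_fasta, write_pileup
from .pileup_model import PileupSite, PileupTable, SampleMeta

__all__ = [
    "SimConfig",
    "TruthSite",
    "simulate_reference",
    "plant_truth",
    "simulate_pileups",
    "simulate_experiment",
    "write_simulation",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment.

    Defaults describe a bacterial-isolate benchmark: a 100 kb reference at
    50% GC (the balanced base composition under which random deletions give
    per-base ratios near 1), 100 non-overlapping genes tiling both strands,
    1,000 planted Psi sites with stoichiometries spanning the calling range,
    mean per-base coverage 150 (deep isolate RNA-seq, comfortably above the
    20x calling floor), and a 0.1% base-independent background deletion
    rate — an order of magnitude below the 1% untreated cutoff.
    """

    seed: int = 0
    genome_length: int = 100_000
    gc_content: float = 0.5
    n_genes: int = 100
    gene_length: int = 600
    n_psi_sites: int = 1_000
    stoichiometry: Union[float, Tuple[float, float]] = (0.05, 0.8)
    mean_depth: float = 150.0
    background_deletion_rate: float = 0.001
    heterogeneity_rate: float = 0.0
    heterogeneity_deletion_rate: float = 0.05
    n_replicates: int = 2
    conditions: Tuple[str, ...] = ("37C",)
    reference_name: str = "ref_1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content outside [0, 1]")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        lo, hi = self.stoichiometry_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("stoichiometry outside [0, 1]")
        if hi + self.background_deletion_rate > 1.0:
            raise ValueError("stoichiometry + background exceeds 1")
        if not 0.0 <= self.heterogeneity_rate < 1.0:
            raise ValueError("heterogeneity_rate outside [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    @property
    def stoichiometry_range(self) -> Tuple[float, float]:
        if isinstance(self.stoichiometry, tuple):
            return self.stoichiometry
        return (self.stoichiometry, self.stoichiometry)


@dataclass(frozen=True)
class TruthSite:
    """One planted Psi site with its true stoichiometry."""

    reference_id: str
    position: int  # 1-based
    strand: str
    gene_id: Optional[str]
    stoichiometry: float
    planted_pus: Optional[str] = None


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    # one independent stream per simulation stage so adding samples does not
    # perturb the reference or the truth set; crc32 is stable across runs
    seed_seq = np.random.SeedSequence([config.seed, zlib.crc32(stream.encode())])
    return np.random.default_rng(seed_seq)


def simulate_reference(config: SimConfig) -> Tuple[Dict[str, str], AnnotationSet]:
    """Draw a random reference at the configured GC content and tile genes.

    Bases are i.i.d. with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2.
    Genes of ``gene_length`` nt tile the contig with alternating strands and
    small gaps, never overlapping.
    """
    rng = _rng(config, "reference")
    gc = config.gc_content
    seq = rng.choice(
        np.array(list("ACGT")),
        size=config.genome_length,
        p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2],
    )
    sequence = "".join(seq)

    gap = max(
        10,
        (config.genome_length - config.n_genes * config.gene_length)
        // max(config.n_genes + 1, 1),
    )
    genes: List[Gene] = []
    start = gap + 1
    for i in range(config.n_genes):
        end = start + config.gene_length - 1
        if end > config.genome_length:
            raise ValueError(
                f"cannot place {config.n_genes} genes of {config.gene_length} nt "
                f"in {config.genome_length} nt"
            )
        genes.append(
            Gene(
                gene_id=f"gene_{i + 1:04d}",
                reference_id=config.reference_name,
                start=start,
                end=end,
                strand="+" if i % 2 == 0 else "-",
            )
        )
        start = end + gap + 1
    return {config.reference_name: sequence}, AnnotationSet(genes)


def plant_truth(
    config: SimConfig,
    reference: Dict[str, str],
    annotation: Optional[AnnotationSet] = None,
) -> List[TruthSite]:
    """Choose uridine positions and stoichiometries for the planted sites.

    Sites are drawn uniformly from genic uridine positions (T on a + gene,
    A on a - gene) when an annotation is given, otherwise from all T
    positions of the + strand.  Stoichiometries are uniform over the
    configured range.
    """
    rng = _rng(config, "truth")
    ref_name = config.reference_name
    seq = reference[ref_name]
    candidates: List[Tuple[int, str, Optional[str]]] = []
    if annotation is not None:
        for g in annotation:
            base = "T" if g.strand == "+" else "A"
            for pos in range(g.start, g.end + 1):
                if seq[pos - 1] == base:
                    candidates.append((pos, g.strand, g.gene_id))
    else:
        candidates = [
            (i + 1, "+", None) for i, b in enumerate(seq) if b == "T"
        ]
    if config.n_psi_sites > len(candidates):
        raise ValueError(
            f"cannot plant {config.n_psi_sites} sites: only "
            f"{len(candidates)} uridine positions available"
        )
    chosen = rng.choice(len(candidates), size=config.n_psi_sites, replace=False)
    lo, hi = config.stoichiometry_range
    stoich = rng.uniform(lo, hi, size=config.n_psi_sites) if hi > lo else np.full(
        config.n_psi_sites, lo
    )
    truth = [
        TruthSite(
            reference_id=ref_name,
            position=candidates[idx][0],
            strand=candidates[idx][1],
            gene_id=candidates[idx][2],
            stoichiometry=float(s),
        )
        for idx, s in zip(chosen, stoich)
    ]
    truth.sort(key=lambda t: t.position)
    return truth


def simulate_pileups(
    config: SimConfig,
    reference: Dict[str, str],
    truth: Sequence[TruthSite],
    sample_tag: str = "37C_rep1",
) -> Tuple[PileupTable, PileupTable]:
    """Generate one (treated, untreated) pileup pair over the whole genome.

    Per position: depth ~ Poisson(mean_depth); untreated deletions ~
    Binomial(depth, background [+ heterogeneity at designated positions]);
    treated deletions ~ Binomial(depth, background + stoichiometry) at
    planted sites and Binomial(depth, background [+ heterogeneity]) elsewhere.
    """
    ref_name = config.reference_name
    seq = reference[ref_name]
    for t in truth:
        base = seq[t.position - 1]
        expected = "T" if t.strand == "+" else "A"
        if base != expected:
            raise ValueError(
                f"truth site {t.position} ({t.strand}) is not a uridine "
                f"(reference base {base})"
            )
        if t.stoichiometry + config.background_deletion_rate > 1.0:
            raise ValueError("stoichiometry + background exceeds 1")
    n = len(seq)
    rng = _rng(config, f"pileup:{sample_tag}")

    het_rng = _rng(config, "heterogeneity")
    het_rate = np.zeros(n)
    if config.heterogeneity_rate > 0:
        het_mask = het_rng.random(n) < config.heterogeneity_rate
        het_rate[het_mask] = config.heterogeneity_deletion_rate

    treated_rate = np.full(n, config.background_deletion_rate) + het_rate
    untreated_rate = treated_rate.copy()
    for t in truth:
        treated_rate[t.position - 1] += t.stoichiometry
    np.clip(treated_rate, 0.0, 1.0, out=treated_rate)

    depth_t = rng.poisson(config.mean_depth, size=n)
    depth_u = rng.poisson(config.mean_depth, size=n)
    del_t = rng.binomial(depth_t, treated_rate)
    del_u = rng.binomial(depth_u, untreated_rate)

    treated = PileupTable(sample_id=f"{sample_tag}_BS")
    untreated = PileupTable(sample_id=f"{sample_tag}_untreated")
    for i in range(n):
        base = seq[i]
        treated.add(PileupSite(ref_name, i + 1, base, int(depth_t[i]), int(del_t[i])))
        untreated.add(PileupSite(ref_name, i + 1, base, int(depth_u[i]), int(del_u[i])))
    return treated, untreated


def simulate_experiment(
    config: SimConfig,
) -> Dict[str, object]:
    """Full synthetic experiment: reference, genes, truth, all sample pairs.

    Returns a dict with keys ``reference``, ``annotation``, ``truth`` and
    ``samples`` — the latter a list of (SampleMeta treated, SampleMeta
    untreated, treated PileupTable, untreated PileupTable), one entry per
    condition x replicate.
    """
    reference, annotation = simulate_reference(config)
    truth = plant_truth(config, reference, annotation)
    samples = []
    for condition in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            tag = f"{condition}_rep{rep}"
            treated, untreated = simulate_pileups(config, reference, truth, tag)
            meta_t = SampleMeta(treated.sample_id, True, condition, rep)
            meta_u = SampleMeta(untreated.sample_id, False, condition, rep)
            samples.append((meta_t, meta_u, treated, untreated))
    return {
        "reference": reference,
        "annotation": annotation,
        "truth": truth,
        "samples": samples,
    }


def truth_frame(truth: Sequence[TruthSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reference": t.reference_id,
                "pos": t.position,
                "strand": t.strand,
                "gene_id": t.gene_id or "NA",
                "stoichiometry": t.stoichiometry,
                "planted_pus": t.planted_pus or "NA",
            }
            for t in truth
        ]
    )


def write_simulation(config: SimConfig, outdir: Union[str, Path]) -> Dict[str, Path]:
    """Run :func:`simulate_experiment` and write all artifacts to ``outdir``.

    Emits reference FASTA, gene GFF3, one simple-TSV pileup per sample, and
    the truth table TSV.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = simulate_experiment(config)
    paths: Dict[str, Path] = {}
    paths["reference"] = outdir / "reference.fa"
    write_fasta(exp["reference"], paths["reference"])
    paths["annotation"] = outdir / "genes.gff3"
    write_annotation(exp["annotation"], paths["annotation"])
    paths["truth"] = outdir / "truth.tsv"
    truth_frame(exp["truth"]).to_csv(paths["truth"], sep="\t", index=False)
    for meta_t, meta_u, treated, untreated in exp["samples"]:
        for table in (treated, untreated):
            p = outdir / f"{table.sample_id}.pileup.tsv"
            write_pileup(table, p)
            paths[table.sample_id] = p
    return paths
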