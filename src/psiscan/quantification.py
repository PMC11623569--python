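"""Transcript-level pseudouridylation quantities.

The transcript-level modification load of an RNA is its *Psi-strength*: the
sum of deletion fractions over all Psi sites within the transcript.  An
unmodified transcript has strength 0; a transcript with one fully
stoichiometric site has strength 1.  Psi-strength contrasts between
genotypes assign sites to pseudouridine synthases (PUS), and contrasts
between growth conditions detect stress-responsive pseudouridylation.
Abundance is expressed as TPM with a pseudocount of one per gene.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationSet
from .psi_calling import PsiCall

__all__ = [
    "TranscriptPsiProfile",
    "PusAssignment",
    "psi_strength",
    "tpm",
    "profile_transcripts",
    "assign_pus",
    "differential_stress",
    "pairing_class",
    "sites_vs_abundance",
]


@dataclass
class TranscriptPsiProfile:
    """Per-gene Psi quantification: sites, strength, abundance."""

    gene_id: str
    length: int
    sites: List[Tuple[int, float]] = field(default_factory=list)
    tpm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"gene {self.gene_id!r}: non-positive length")

    @property
    def psi_strength(self) -> float:
        return psi_strength([f for _, f in self.sites])

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sites_per_kb(self) -> float:
        return self.n_sites * 1000.0 / self.length

    @property
    def mean_site_fraction(self) -> float:
        """Mean deletion fraction over the transcript's sites (0 if none)."""
        if not self.sites:
            return 0.0
        return sum(f for _, f in self.sites) / len(self.sites)


@dataclass(frozen=True)
class PusAssignment:
    """Outcome of a WT-vs-PUS-mutant strength contrast for one gene."""

    gene_id: str
    pus_name: str
    delta_strength_per_replicate: Tuple[float, ...]
    assigned: bool


def psi_strength(fractions: Iterable[float]) -> float:
    """Sum of deletion fractions over all Psi sites of one RNA (0 if none)."""
    total = 0.0
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"deletion fraction {f} outside [0, 1]")
        total += f
    return total


def tpm(
    counts: Union[Mapping[str, int], pd.DataFrame, pd.Series],
    lengths: Mapping[str, int],
    pseudocount: int = 1,
    min_reads_prefilter: Optional[int] = None,
) -> Union[pd.Series, pd.DataFrame]:
    """Transcripts-per-million with a per-gene pseudocount.

    rate_g = (count_g + pseudocount) / length_g; TPM_g = rate_g / sum(rates)
    x 1e6, so TPM sums to one million per sample.  With
    ``min_reads_prefilter`` set (microbiome regime), genes whose raw count
    is below the threshold in *every* sample are dropped before
    normalisation.

    Parameters
    ----------
    counts:
        Either a mapping / Series (one sample) or a DataFrame with genes as
        the index and one column per sample.
    lengths:
        Gene lengths in nucleotides.
    """
    if isinstance(counts, Mapping) and not isinstance(counts, pd.Series):
        counts = pd.Series(counts, dtype=float)
    single = isinstance(counts, pd.Series)
    frame = counts.to_frame("sample") if single else counts.astype(float)
    if frame.empty:
        raise ValueError("empty count table")
    missing = [g for g in frame.index if g not in lengths]
    if missing:
        raise KeyError(f"no length for gene(s): {missing[:5]}")
    if (frame < 0).any().any():
        raise ValueError("negative read counts")
    if min_reads_prefilter is not None:
        keep = (frame >= min_reads_prefilter).any(axis=1)
        frame = frame.loc[keep]
        if frame.empty:
            raise ValueError("prefilter removed every gene")
    lens = pd.Series({g: float(lengths[g]) for g in frame.index})
    if (lens <= 0).any():
        raise ValueError("non-positive gene length")
    rates = frame.add(float(pseudocount)).div(lens, axis=0)
    result = rates.div(rates.sum(axis=0), axis=1) * 1e6
    return result["sample"] if single else result


def profile_transcripts(
    calls: Sequence[PsiCall],
    annotation: AnnotationSet,
    tpm_values: Optional[Mapping[str, float]] = None,
    sense_only: bool = True,
) -> Dict[str, TranscriptPsiProfile]:
    """Build per-gene profiles by assigning calls to overlapping genes.

    Every annotated gene gets a profile (strength 0 when no site falls in
    it), so genotype/condition contrasts see absent sites as 0 rather than
    missing.  A call is assigned to a gene when its position lies within the
    gene interval on the same reference and, if ``sense_only``, on the
    gene's strand.
    """
    profiles = {
        g.gene_id: TranscriptPsiProfile(
            gene_id=g.gene_id,
            length=g.length,
            tpm=None if tpm_values is None else tpm_values.get(g.gene_id),
        )
        for g in annotation
    }
    for c in calls:
        for g in annotation:
            if g.reference_id != c.reference_id:
                continue
            if not g.start <= c.position <= g.end:
                continue
            if sense_only and g.strand != c.strand:
                continue
            profiles[g.gene_id].sites.append((c.position, c.psi_proportion))
    return profiles


def _strengths_by_replicate(
    profiles_per_replicate: Sequence[Mapping[str, object]],
) -> List[Dict[str, float]]:
    """Each replicate maps gene -> TranscriptPsiProfile or gene -> strength."""
    out = []
    for rep in profiles_per_replicate:
        out.append(
            {
                g: (p.psi_strength if isinstance(p, TranscriptPsiProfile) else float(p))
                for g, p in rep.items()
            }
        )
    return out


def _paired_deltas(
    a_reps: Sequence[Mapping[str, TranscriptPsiProfile]],
    b_reps: Sequence[Mapping[str, TranscriptPsiProfile]],
) -> Dict[str, Tuple[float, ...]]:
    """Per-gene (a - b) strength deltas paired replicate-by-replicate.

    The gene universe is the union over both groups; a gene absent from one
    replicate contributes strength 0 there — a site lost in the mutant is
    precisely the signal sought.
    """
    if len(a_reps) != len(b_reps):
        raise ValueError(
            f"replicate mismatch: {len(a_reps)} vs {len(b_reps)} replicate sets"
        )
    if not a_reps:
        raise ValueError("no replicates provided")
    a_strengths = _strengths_by_replicate(a_reps)
    b_strengths = _strengths_by_replicate(b_reps)
    genes = set()
    for s in (*a_strengths, *b_strengths):
        genes |= set(s)
    return {
        g: tuple(
            a.get(g, 0.0) - b.get(g, 0.0) for a, b in zip(a_strengths, b_strengths)
        )
        for g in sorted(genes)
    }


def assign_pus(
    wt_profiles: Sequence[Mapping[str, TranscriptPsiProfile]],
    mutant_profiles: Sequence[Mapping[str, TranscriptPsiProfile]],
    pus_name: str,
    min_delta: float = 0.05,
) -> List[PusAssignment]:
    """Assign genes to a PUS enzyme from a WT-vs-knockout strength contrast.

    A gene is attributed to the knocked-out PUS when WT Psi-strength exceeds
    mutant strength by at least ``min_delta`` in every replicate pair
    (replicates paired by index).  Genes can be assigned to several PUS by
    running several contrasts.  Both profile groups should come from the
    same growth condition (the reference condition, 37C).
    """
    deltas = _paired_deltas(wt_profiles, mutant_profiles)
    return [
        PusAssignment(
            gene_id=g,
            pus_name=pus_name,
            delta_strength_per_replicate=d,
            assigned=all(x >= min_delta for x in d),
        )
        for g, d in deltas.items()
    ]


def differential_stress(
    stress_profiles: Sequence[Mapping[str, TranscriptPsiProfile]],
    control_profiles: Sequence[Mapping[str, TranscriptPsiProfile]],
    min_delta: float = 0.05,
) -> pd.DataFrame:
    """Genes with increased pseudouridylation under a stress condition.

    A gene is reported when stress strength exceeds control strength by at
    least ``min_delta`` in both (all) replicate pairs.  Reported genes whose
    control strength comes within ``min_delta / 2`` of the cutoff in any
    replicate are flagged for review rather than removed — these are the
    borderline cases that would otherwise need manual inspection.

    Returns a DataFrame indexed by gene with per-replicate deltas, the
    increased flag and the review flag.
    """
    deltas = _paired_deltas(stress_profiles, control_profiles)
    control_strengths = _strengths_by_replicate(control_profiles)
    rows = []
    for g, d in deltas.items():
        increased = all(x >= min_delta for x in d)
        control = [s.get(g, 0.0) for s in control_strengths]
        review = increased and any(c >= min_delta / 2 for c in control)
        rows.append(
            {
                "gene_id": g,
                **{f"delta_rep{i + 1}": x for i, x in enumerate(d)},
                "increased": increased,
                "review_flag": review,
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["increased", "review_flag"]
    )
    return df


def pairing_class(dot_bracket: str, position: int) -> str:
    """Classify a position of a dot-bracket structure as paired or unpaired.

    ``position`` is 1-based.  '.' is unpaired; '(' or ')' is paired.
    Unbalanced bracket strings produce a warning but still classify.
    """
    if not 1 <= position <= len(dot_bracket):
        raise IndexError(
            f"position {position} outside structure of length {len(dot_bracket)}"
        )
    bad = set(dot_bracket) - set("().")
    if bad:
        raise ValueError(f"invalid structure symbols: {sorted(bad)}")
    if dot_bracket.count("(") != dot_bracket.count(")"):
        warnings.warn("unbalanced dot-bracket string", stacklevel=2)
    return "unpaired" if dot_bracket[position - 1] == "." else "paired"


def sites_vs_abundance(
    profiles: Iterable[TranscriptPsiProfile],
) -> Dict[str, Optional[float]]:
    """Spearman correlation of Psi site density and Psi level against TPM.

    Correlates (a) the length-normalised site count (sites per kb) and
    (b) the mean per-site Psi proportion of each transcript against its
    abundance.  Rank correlations are tie-corrected.  Constant inputs leave
    the corresponding correlation as None.

    Returns a dict with keys ``rho_sites``, ``p_sites``, ``rho_level``,
    ``p_level`` and ``n``.
    """
    rows = [
        (p.sites_per_kb, p.mean_site_fraction, p.tpm)
        for p in profiles
        if p.tpm is not None
    ]
    if len(rows) < 3:
        raise ValueError("need at least 3 profiles with TPM values")
    density, level, abundance = (np.asarray(col, dtype=float) for col in zip(*rows))

    def _spearman(x: np.ndarray, y: np.ndarray):
        if np.all(x == x[0]) or np.all(y == y[0]):
            return None, None
        rho, p = stats.spearmanr(x, y)
        if math.isnan(rho):
            return None, None
        return float(rho), float(p)

    rho_sites, p_sites = _spearman(density, abundance)
    rho_level, p_level = _spearman(level, abundance)
    return {
        "rho_sites": rho_sites,
        "p_sites": p_sites,
        "rho_level": rho_level,
        "p_level": p_level,
        "n": len(rows),
    }
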