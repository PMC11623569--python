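"""Per-site pileup quantities for bisulfite-based pseudouridine mapping.

The atomic observation of the whole pipeline is a pileup site: for one
reference position in one sample, the number of spanning reads (depth) and
the number of reads carrying a single-base deletion at that position.
Bisulfite (BS) treatment converts pseudouridine (Psi) into an adduct that
makes reverse transcriptase skip the base, so in a BS-treated library the
deletion fraction at a uridine position estimates the fraction of transcript
molecules modified there (the stoichiometry).  Untreated libraries carry only
background deletion noise.

This module holds the containers (:class:`PileupSite`, :class:`PileupTable`,
:class:`SampleMeta`) and the three per-site computations everything else
builds on: the deletion fraction, the genome-wide per-base deletion-ratio
diagnostic, and the conversion of deletion fractions into a Psi proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional, Tuple

__all__ = [
    "PileupSite",
    "PileupTable",
    "SampleMeta",
    "BaseDeletionProfile",
    "deletion_fraction",
    "base_deletion_profile",
    "psi_proportion",
]

#: Bases a reference position can take; U on the transcript is T in the
#: DNA reference of the transcribed strand.
BASES = ("A", "C", "G", "T")


class PileupValidationError(ValueError):
    """Raised when pileup data violates a structural invariant."""


@dataclass(frozen=True)
class PileupSite:
    """Counts observed at one reference position in one sample.

    ``depth`` counts all reads spanning the position, including reads that
    carry the deletion; ``del_count`` counts the spanning reads whose
    alignment deletes this base.
    """

    reference_id: str
    position: int  # 1-based
    ref_base: str
    depth: int
    del_count: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise PileupValidationError(
                f"position must be >= 1, got {self.position}"
            )
        if self.depth < 0 or self.del_count < 0:
            raise PileupValidationError(
                f"negative count at {self.reference_id}:{self.position}"
            )
        if self.del_count > self.depth:
            raise PileupValidationError(
                f"del_count {self.del_count} exceeds depth {self.depth} "
                f"at {self.reference_id}:{self.position}"
            )


@dataclass
class PileupTable:
    """All pileup sites of one sample, keyed by (reference_id, position)."""

    sample_id: str
    sites: Dict[Tuple[str, int], PileupSite] = field(default_factory=dict)

    def add(self, site: PileupSite) -> None:
        key = (site.reference_id, site.position)
        if key in self.sites:
            raise PileupValidationError(
                f"duplicate pileup record for {key[0]}:{key[1]} "
                f"in sample {self.sample_id!r}"
            )
        self.sites[key] = site

    def get(self, reference_id: str, position: int) -> Optional[PileupSite]:
        return self.sites.get((reference_id, position))

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[PileupSite]:
        return iter(self.sites.values())


@dataclass(frozen=True)
class SampleMeta:
    """Identity of a library: BS-treated or not, condition, replicate, genotype.

    Every treated sample is expected to have an untreated partner from the
    same condition/replicate/genotype — the two halves of one split RNA
    sample.  ``pair_key`` is what must match between partners.
    """

    sample_id: str
    treated: bool
    condition: str = "37C"
    replicate: int = 1
    genotype: str = "WT"

    @property
    def pair_key(self) -> Tuple[str, int, str]:
        return (self.condition, self.replicate, self.genotype)


@dataclass
class BaseDeletionProfile:
    """Genome-wide per-base deletion frequencies and pairwise ratios.

    ``frequency[b]`` is total deletions over total depth aggregated across
    all positions whose reference base is ``b``.  ``ratio[b]`` is the mean of
    the pairwise frequency ratios of ``b`` against the other three bases,
    e.g. ratio(T) = mean(T:A, T:G, T:C).  Under base-independent deletion
    noise on a balanced (≈50% GC) reference every ratio is ~1; BS treatment
    of Psi-containing RNA drives the U (=T) ratio far above 1.
    """

    depth: Dict[str, int]
    deletions: Dict[str, int]
    frequency: Dict[str, float]
    ratio: Dict[str, Optional[float]]

    def to_rows(self):
        """Rows (base, depth, deletions, frequency, ratio) for a TSV report."""
        for b in BASES:
            yield (
                b,
                self.depth.get(b, 0),
                self.deletions.get(b, 0),
                self.frequency.get(b, float("nan")),
                self.ratio.get(b),
            )


def deletion_fraction(site: PileupSite) -> float:
    """Fraction of spanning reads deleting this base: ``del_count / depth``.

    A fraction of 0.5 at a uridine position in a BS-treated sample means
    half of the transcript molecules carry Psi at that site.

    Raises
    ------
    ValueError
        If depth is 0 (the fraction is undefined; such sites must be
        filtered out upstream).
    """
    if site.depth <= 0:
        raise ValueError(
            f"deletion fraction undefined at zero depth "
            f"({site.reference_id}:{site.position})"
        )
    return site.del_count / site.depth


def base_deletion_profile(
    table: PileupTable, reference: Mapping[str, str]
) -> BaseDeletionProfile:
    """Aggregate deletion frequency per reference base, with pairwise ratios.

    Counts are pooled genome-wide per base class before dividing, which
    stabilises the estimate at low per-site coverage.  Positions with zero
    depth are excluded.  A base class with zero aggregate depth has no
    frequency and its ratio (and its contribution to other bases' ratios)
    is reported as missing, never as zero.

    Parameters
    ----------
    table:
        Pileup of one sample.
    reference:
        Mapping reference_id -> sequence (uppercase A/C/G/T expected); used
        to look up the reference base of each position.  Sites whose
        reference base is not one of A/C/G/T are skipped.
    """
    if len(table) == 0:
        raise ValueError("cannot profile an empty pileup table")
    depth = {b: 0 for b in BASES}
    deletions = {b: 0 for b in BASES}
    for site in table:
        if site.depth == 0:
            continue
        seq = reference.get(site.reference_id)
        if seq is None:
            raise KeyError(
                f"reference {site.reference_id!r} absent from the reference set"
            )
        if site.position > len(seq):
            raise IndexError(
                f"position {site.position} beyond end of {site.reference_id!r}"
            )
        base = seq[site.position - 1].upper()
        if base not in depth:
            continue
        depth[base] += site.depth
        deletions[base] += site.del_count

    frequency: Dict[str, float] = {}
    for b in BASES:
        if depth[b] > 0:
            frequency[b] = deletions[b] / depth[b]

    ratio: Dict[str, Optional[float]] = {}
    for b in BASES:
        if b not in frequency:
            ratio[b] = None
            continue
        others = [frequency[x] for x in BASES if x != b and x in frequency]
        usable = [frequency[b] / f for f in others if f > 0]
        if len(usable) < len([x for x in BASES if x != b]):
            warnings.warn(
                f"ratio for base {b} computed over {len(usable)} of 3 "
                "pairwise comparisons (zero-frequency partners skipped)",
                stacklevel=2,
            )
        ratio[b] = sum(usable) / len(usable) if usable else None
    return BaseDeletionProfile(
        depth=depth, deletions=deletions, frequency=frequency, ratio=ratio
    )


def psi_proportion(
    treated_fraction: float,
    untreated_fraction: float,
    mode: str = "isolate",
) -> float:
    """Psi stoichiometry of a site from its paired deletion fractions.

    In isolate mode the untreated fraction has already been forced near zero
    by the calling filter (< 1%), so the treated deletion fraction itself is
    the stoichiometry.  In microbiome mode untreated deletions can be
    substantial (strain-heterogeneity indels), so the stoichiometry is the
    difference in deletion fraction between treated and untreated (the
    "delta deletion fraction"), floored at 0.
    """
    for name, f in (("treated", treated_fraction), ("untreated", untreated_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} fraction {f} outside [0, 1]")
    if mode == "isolate":
        return treated_fraction
    if mode == "microbiome":
        return max(0.0, treated_fraction - untreated_fraction)
    raise ValueError(f"unknown mode {mode!r}; expected 'isolate' or 'microbiome'")
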