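"""Pseudouridine site callers.

Two calling regimes:

* **isolate mode** — hard thresholds tuned for a clonal culture, where the
  untreated library is essentially deletion-free: a uridine position is
  called when depth >= 20 in both libraries, the treated deletion count is
  >= 5, the treated deletion fraction is >= 5% and the untreated fraction
  is < 1%.

* **microbiome mode** — strain heterogeneity in a community inflates
  untreated deletion rates, so the hard untreated cutoff is replaced by a
  fold-change requirement (treated fraction at least 2x untreated) plus a
  one-sided Fisher exact test (p < 0.01) on the 2x2 deletion/depth table,
  and the reported stoichiometry is the treated-minus-untreated delta
  deletion fraction.

Calling is unstranded: a genomic position is a uridine candidate on the +
strand when the reference base is T and on the - strand when it is A. The
same deletion counts back both, so antisense transcription is detectable
without strand-specific library prep.  Sites inside runs of >= 2
consecutive uridines are flagged: the aligner left-aligns the deletion, so
the exact modified position within the run is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set

from scipy import stats

from .pileup_model import PileupTable, deletion_fraction, psi_proportion

__all__ = [
    "CallThresholds",
    "PsiCall",
    "call_sites_isolate",
    "call_sites_microbiome",
    "aggregate_high_confidence",
    "fisher_exact_one_sided",
    "flag_homopolymer_ambiguity",
]


@dataclass(frozen=True)
class CallThresholds:
    """Filter thresholds for both calling modes.

    Defaults are the published operating point: depth >= 20 in both
    libraries, >= 5 treated deletions, treated fraction >= 5% (isolate) or
    >= 2% (microbiome), untreated fraction < 1% (isolate), >= 2-fold
    enrichment and Fisher p < 0.01 (microbiome), and >= 2 supporting
    samples for a high-confidence site.
    """

    min_depth: int = 20
    min_del_count: int = 5
    min_treated_fraction: float = 0.05
    max_untreated_fraction: float = 0.01
    min_treated_fraction_microbiome: float = 0.02
    min_fold: float = 2.0
    max_p: float = 0.01
    min_samples_high_conf: int = 2

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.min_del_count <= 0:
            raise ValueError("count thresholds must be positive")
        for name in (
            "min_treated_fraction",
            "max_untreated_fraction",
            "min_treated_fraction_microbiome",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.min_fold <= 0 or not 0 < self.max_p <= 1:
            raise ValueError("min_fold must be > 0 and max_p in (0, 1]")
        if self.min_samples_high_conf < 1:
            raise ValueError("min_samples_high_conf must be >= 1")


@dataclass(frozen=True)
class PsiCall:
    """A called pseudouridine site."""

    reference_id: str
    position: int  # 1-based
    strand: str
    treated_fraction: float
    untreated_fraction: float
    psi_proportion: float
    supporting_samples: frozenset = field(default_factory=frozenset)
    high_confidence: bool = False
    p_value: Optional[float] = None
    homopolymer_ambiguous: bool = False
    sample_fractions: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        object.__setattr__(
            self, "supporting_samples", frozenset(self.supporting_samples)
        )

    @property
    def key(self):
        return (self.reference_id, self.position, self.strand)


def fisher_exact_one_sided(
    del_treated: int, nondel_treated: int, del_untreated: int, nondel_untreated: int
) -> float:
    """One-sided Fisher exact p for deletion enrichment in the treated sample.

    Exact hypergeometric tail probability of observing at least
    ``del_treated`` deletions in the treated margin, conditioned on the
    2x2 table margins.  Degenerate tables with an all-zero margin give 1.0.
    """
    for c in (del_treated, nondel_treated, del_untreated, nondel_untreated):
        if c < 0:
            raise ValueError("counts must be non-negative")
    if del_treated + nondel_treated + del_untreated + nondel_untreated == 0:
        raise ValueError("empty 2x2 table")
    _, p = stats.fisher_exact(
        [[del_treated, nondel_treated], [del_untreated, nondel_untreated]],
        alternative="greater",
    )
    return float(p)


def _candidate_strand(base: str) -> Optional[str]:
    # reference T = uridine on the + strand transcript; reference A = uridine
    # on the - strand transcript
    if base == "T":
        return "+"
    if base == "A":
        return "-"
    return None


def _iter_candidates(
    treated: PileupTable,
    untreated: PileupTable,
    reference: Mapping[str, str],
    thresholds: CallThresholds,
):
    """Yield (site, untreated_site_or_None, strand, tf) for positions passing
    the treated-side depth/count/fraction filters common to both modes."""
    for site in treated:
        strand = _candidate_strand(site.ref_base)
        if strand is None:
            continue
        seq = reference.get(site.reference_id)
        if seq is not None and site.position <= len(seq):
            # trust the reference over the pileup's base column if both exist
            strand = _candidate_strand(seq[site.position - 1].upper())
            if strand is None:
                continue
        if site.depth < thresholds.min_depth:
            continue
        if site.del_count < thresholds.min_del_count:
            continue
        u = untreated.get(site.reference_id, site.position)
        # a position absent from the untreated table has depth 0 there and
        # fails the paired depth filter — never an exception
        if u is None or u.depth < thresholds.min_depth:
            continue
        yield site, u, strand


def call_sites_isolate(
    treated: PileupTable,
    untreated: PileupTable,
    reference: Mapping[str, str],
    thresholds: CallThresholds = CallThresholds(),
) -> List[PsiCall]:
    """Call Psi sites from one treated/untreated pair with hard thresholds.

    A uridine position is called iff depth >= ``min_depth`` in both samples,
    treated deletion count >= ``min_del_count``, treated deletion fraction
    >= ``min_treated_fraction`` and untreated fraction <
    ``max_untreated_fraction``.  The reported stoichiometry is the treated
    deletion fraction.  Output sorted by (reference, position).
    """
    calls: List[PsiCall] = []
    for site, u, strand in _iter_candidates(treated, untreated, reference, thresholds):
        tf = deletion_fraction(site)
        uf = deletion_fraction(u)
        if tf < thresholds.min_treated_fraction:
            continue
        if uf >= thresholds.max_untreated_fraction:
            continue
        call = PsiCall(
            reference_id=site.reference_id,
            position=site.position,
            strand=strand,
            treated_fraction=tf,
            untreated_fraction=uf,
            psi_proportion=psi_proportion(tf, uf, mode="isolate"),
            supporting_samples=frozenset({treated.sample_id}),
            sample_fractions={treated.sample_id: tf},
        )
        calls.append(flag_homopolymer_ambiguity(call, reference))
    calls.sort(key=lambda c: (c.reference_id, c.position, c.strand))
    return calls


def call_sites_microbiome(
    treated: PileupTable,
    untreated: PileupTable,
    reference: Mapping[str, str],
    thresholds: CallThresholds = CallThresholds(),
) -> List[PsiCall]:
    """Call Psi sites in a community sample (fold change + Fisher test).

    Filters: depth >= ``min_depth`` in both samples; treated deletion count
    >= ``min_del_count``; treated fraction >=
    ``min_treated_fraction_microbiome``; treated fraction >= ``min_fold`` x
    untreated fraction (an untreated fraction of exactly 0 passes by
    convention); one-sided Fisher exact p < ``max_p``.  The reported
    stoichiometry is the delta deletion fraction (treated - untreated).
    """
    calls: List[PsiCall] = []
    for site, u, strand in _iter_candidates(treated, untreated, reference, thresholds):
        tf = deletion_fraction(site)
        uf = deletion_fraction(u)
        if tf < thresholds.min_treated_fraction_microbiome:
            continue
        if uf > 0 and tf < thresholds.min_fold * uf:
            continue
        p = fisher_exact_one_sided(
            site.del_count, site.depth - site.del_count, u.del_count, u.depth - u.del_count
        )
        if p >= thresholds.max_p:
            continue
        call = PsiCall(
            reference_id=site.reference_id,
            position=site.position,
            strand=strand,
            treated_fraction=tf,
            untreated_fraction=uf,
            psi_proportion=psi_proportion(tf, uf, mode="microbiome"),
            supporting_samples=frozenset({treated.sample_id}),
            p_value=p,
            sample_fractions={treated.sample_id: tf},
        )
        calls.append(flag_homopolymer_ambiguity(call, reference))
    calls.sort(key=lambda c: (c.reference_id, c.position, c.strand))
    return calls


def aggregate_high_confidence(
    per_sample_calls: Mapping[str, Sequence[PsiCall]],
    min_samples: int = 2,
) -> List[PsiCall]:
    """Merge per-sample call lists into high-confidence sites.

    A site is high-confidence when it was called at the identical
    (reference, position, strand) in at least ``min_samples`` distinct
    treated libraries — biological replicates and different conditions both
    count.  The merged record carries the union of supporting samples, the
    per-sample treated fractions, and mean fractions.  With
    ``min_samples=1`` this is the union of the inputs.
    """
    if not per_sample_calls:
        raise ValueError("no call lists provided")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    grouped: Dict[tuple, List[PsiCall]] = {}
    for sample_id, calls in per_sample_calls.items():
        for c in calls:
            # calls usually carry their own library ids; the mapping key is
            # only a fallback for bare records
            grouped.setdefault(c.key, []).append(
                c if c.supporting_samples
                else replace(c, supporting_samples=frozenset({sample_id}))
            )
    merged: List[PsiCall] = []
    for key, group in grouped.items():
        supporting: Set[str] = set()
        fractions: Dict[str, float] = {}
        for c in group:
            supporting |= set(c.supporting_samples)
            if c.sample_fractions:
                fractions.update(c.sample_fractions)
            else:
                for s in c.supporting_samples:
                    fractions[s] = c.treated_fraction
        if len(supporting) < min_samples:
            continue
        n = len(group)
        ref, pos, strand = key
        p_values = [c.p_value for c in group if c.p_value is not None]
        merged.append(
            PsiCall(
                reference_id=ref,
                position=pos,
                strand=strand,
                treated_fraction=sum(c.treated_fraction for c in group) / n,
                untreated_fraction=sum(c.untreated_fraction for c in group) / n,
                psi_proportion=sum(c.psi_proportion for c in group) / n,
                supporting_samples=frozenset(supporting),
                high_confidence=len(supporting) >= min_samples,
                p_value=max(p_values) if p_values else None,
                homopolymer_ambiguous=any(c.homopolymer_ambiguous for c in group),
                sample_fractions=fractions,
            )
        )
    merged.sort(key=lambda c: (c.reference_id, c.position, c.strand))
    return merged


def flag_homopolymer_ambiguity(
    call: PsiCall, reference: Mapping[str, str]
) -> PsiCall:
    """Flag calls inside uridine homopolymer runs and left-align them.

    If the called position sits in a run of >= 2 consecutive uridines on its
    strand (consecutive T for +, consecutive A for -), the exact modified
    base cannot be resolved from left-aligned deletion alignments; the call
    is flagged and reported at the lowest reference coordinate of the run
    (the left-aligned position).
    """
    seq = reference.get(call.reference_id)
    if seq is None or call.position > len(seq):
        return call
    base = "T" if call.strand == "+" else "A"
    i = call.position - 1  # 0-based
    if seq[i].upper() != base:
        return call
    start = i
    while start > 0 and seq[start - 1].upper() == base:
        start -= 1
    end = i
    while end + 1 < len(seq) and seq[end + 1].upper() == base:
        end += 1
    run_length = end - start + 1
    if run_length < 2:
        if call.homopolymer_ambiguous:
            return replace(call, homopolymer_ambiguous=False)
        return call
    return replace(call, homopolymer_ambiguous=True, position=start + 1)
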