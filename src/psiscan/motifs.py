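"""Sequence-context analysis around called pseudouridine sites.

Each called site contributes a k-mer in transcript orientation (minus-strand
sites are reverse-complemented, T is written as U) with the Psi at a fixed
offset; the default window is the 5-mer with the Psi central (2 up, 2 down),
which is the window the most frequent bacterial motif (GGUAU) occupies.
Motifs are filtered on deletion fraction (above the dataset median by
default) and occurrence count, then contrasted between wild type and PUS
knockouts with a two-sided Wilcoxon rank-sum test: a motif whose deletion
fractions drop significantly in a knockout is a sequence preference of that
enzyme.  A transparent position-frequency summary reports the modal
consensus of significant motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .psi_calling import PsiCall

logger = logging.getLogger(__name__)

__all__ = [
    "MotifStat",
    "extract_motifs",
    "filter_motif_sites",
    "motif_genotype_test",
    "motif_contrast_table",
    "consensus_from_motifs",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: group size at or below which the exact rank-sum null is enumerable cheaply
_EXACT_N = 10


@dataclass(frozen=True)
class MotifStat:
    """Test result for one k-mer context in a genotype contrast."""

    kmer: str
    psi_offset: int
    occurrences: int
    wt_fractions: Tuple[float, ...]
    mutant_fractions: Tuple[float, ...]
    p_value: float
    q_value: Optional[float]
    significant: bool


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_motifs(
    calls: Sequence[PsiCall],
    reference: Mapping[str, str],
    k_up: int = 2,
    k_down: int = 2,
) -> List[Tuple[str, PsiCall]]:
    """Extract the k-mer context of each call in transcript orientation.

    The k-mer has length ``k_up + 1 + k_down`` with the Psi at 0-based
    offset ``k_up``; DNA T is rewritten as RNA U.  Minus-strand sites are
    reverse-complemented first, so upstream always means 5' of the Psi on
    the transcript.  Sites too close to a contig edge are skipped with a
    log warning.
    """
    out: List[Tuple[str, PsiCall]] = []
    for c in calls:
        seq = reference.get(c.reference_id)
        if seq is None:
            raise KeyError(f"reference {c.reference_id!r} not found")
        i = c.position - 1
        if c.strand == "+":
            lo, hi = i - k_up, i + k_down + 1
        else:
            lo, hi = i - k_down, i + k_up + 1
        if lo < 0 or hi > len(seq):
            logger.warning(
                "site %s:%d too close to contig edge; skipped", c.reference_id, c.position
            )
            continue
        window = seq[lo:hi].upper()
        if c.strand == "-":
            window = _revcomp(window)
        out.append((window.replace("T", "U"), c))
    return out


def filter_motif_sites(
    sites_with_fractions: Iterable[Tuple[str, float]],
    min_fraction: Optional[float] = None,
    min_occurrences: int = 5,
) -> Dict[str, List[float]]:
    """Filter sites on deletion fraction, then motifs on occurrence count.

    Sites are retained when their deletion fraction is strictly above
    ``min_fraction``; when unset the threshold is the empirical median of
    the input fractions (the published analysis used its dataset median,
    6%).  Motifs observed in fewer than ``min_occurrences`` retained sites
    are dropped.  Returns motif -> retained deletion fractions.
    """
    pairs = list(sites_with_fractions)
    if not pairs:
        return {}
    if min_fraction is None:
        min_fraction = float(np.median([f for _, f in pairs]))
    by_motif: Dict[str, List[float]] = {}
    for kmer, frac in pairs:
        if frac > min_fraction:
            by_motif.setdefault(kmer, []).append(frac)
    return {
        kmer: fr for kmer, fr in by_motif.items() if len(fr) >= min_occurrences
    }


def motif_genotype_test(
    wt_fractions: Sequence[float],
    mutant_fractions: Sequence[float],
) -> float:
    """Two-sided Wilcoxon rank-sum p for a WT-vs-mutant fraction contrast.

    Uses the exact permutation null for small tie-free groups (both sizes
    <= 10) and the tie-corrected normal approximation otherwise.  Two
    identical groups give p = 1.
    """
    wt = np.asarray(wt_fractions, dtype=float)
    mut = np.asarray(mutant_fractions, dtype=float)
    if wt.size == 0 or mut.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([wt, mut])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = (
        "exact"
        if (wt.size <= _EXACT_N and mut.size <= _EXACT_N and not has_ties)
        else "asymptotic"
    )
    _, p = stats.mannwhitneyu(wt, mut, alternative="two-sided", method=method)
    return float(min(p, 1.0))


def motif_contrast_table(
    wt_by_motif: Mapping[str, Sequence[float]],
    mutant_by_motif: Mapping[str, Sequence[float]],
    psi_offset: int = 2,
    alpha: float = 0.05,
    adjust: str = "BH",
) -> List[MotifStat]:
    """Test every motif present in both genotypes; BH-adjust across motifs.

    A motif is significant when its (adjusted, if ``adjust="BH"``) p-value
    is below ``alpha`` *and* the deletion fractions decreased in the mutant
    (median WT > median mutant) — the direction that marks a sequence
    preference of the knocked-out enzyme.
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    motifs = sorted(set(wt_by_motif) & set(mutant_by_motif))
    p_values = [
        motif_genotype_test(wt_by_motif[m], mutant_by_motif[m]) for m in motifs
    ]
    if adjust == "BH" and p_values:
        _, q_values, _, _ = multipletests(p_values, method="fdr_bh")
        q_list: List[Optional[float]] = [float(q) for q in q_values]
        decide = q_list
    else:
        q_list = [None] * len(p_values)
        decide = p_values
    out = []
    for m, p, q, d in zip(motifs, p_values, q_list, decide):
        wt = wt_by_motif[m]
        mut = mutant_by_motif[m]
        decreased = float(np.median(wt)) > float(np.median(mut))
        out.append(
            MotifStat(
                kmer=m,
                psi_offset=psi_offset,
                occurrences=len(wt),
                wt_fractions=tuple(wt),
                mutant_fractions=tuple(mut),
                p_value=p,
                q_value=q,
                significant=bool(d < alpha and decreased),
            )
        )
    return out


def consensus_from_motifs(
    kmers: Sequence[str],
) -> Tuple[pd.DataFrame, str]:
    """Position-frequency matrix and modal consensus of same-length k-mers.

    The consensus takes the modal base at each offset, lowercased when the
    modal frequency is below 0.5 (ambiguous positions).  Input k-mers may
    repeat (multiplicities count).
    """
    if not kmers:
        raise ValueError("no k-mers provided")
    k = len(kmers[0])
    if any(len(m) != k for m in kmers):
        raise ValueError("k-mers must all have the same length")
    alphabet = ["A", "C", "G", "U"]
    counts = pd.DataFrame(0, index=alphabet, columns=range(k))
    for m in kmers:
        for j, b in enumerate(m):
            if b not in alphabet:
                raise ValueError(f"invalid base {b!r} in k-mer {m!r}")
            counts.loc[b, j] += 1
    consensus = []
    n = len(kmers)
    for j in range(k):
        col = counts[j]
        modal = col.idxmax()
        consensus.append(modal if col[modal] / n >= 0.5 else modal.lower())
    return counts, "".join(consensus)
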