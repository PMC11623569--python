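"""Antisense-transcript discovery from opposite-strand pseudouridine sites.

Because the calling step is unstranded, a Psi call on the strand opposite
an annotated gene is direct evidence of an antisense transcript (asRNA):
pseudouridylation happens on RNA, so the opposite strand must have been
transcribed.  This module scans high-confidence calls for such sites,
relates them to known transcription start sites (TSS), attaches externally
computed promoter/terminator probabilities, and predicts the span of
candidate small RNAs as running from the TSS to the midpoint of the
window containing the transcription termination site (TTS).

Coordinate logic is always expressed in the *antisense transcript's*
direction: on the minus strand, downstream means decreasing genomic
coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

from .io_formats import AnnotationSet, PredictorScoreTable
from .psi_calling import PsiCall

__all__ = [
    "AntisenseCandidate",
    "scan_antisense",
    "tss_proximity",
    "attach_predictor_scores",
    "predict_srna_span",
]


@dataclass(frozen=True)
class AntisenseCandidate:
    """A Psi site on the strand opposite an annotated gene."""

    gene_id: str
    gene_strand: str
    psi_site: PsiCall
    distance_to_known_tss: Optional[int] = None
    promoter_score: Optional[float] = None
    tts_score: Optional[float] = None
    predicted_tss: Optional[int] = None
    predicted_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.psi_site.strand == self.gene_strand:
            raise ValueError("antisense candidate must be on the opposite strand")
        if self.predicted_length is not None and self.predicted_length <= 0:
            raise ValueError("predicted_length must be positive")

    @property
    def strand(self) -> str:
        """Strand of the antisense transcript (the Psi site's strand)."""
        return self.psi_site.strand


def scan_antisense(
    calls: Sequence[PsiCall],
    annotation: AnnotationSet,
    min_samples: int = 2,
) -> List[AntisenseCandidate]:
    """Find calls lying within a gene's interval on the opposite strand.

    Only calls supported by at least ``min_samples`` treated libraries are
    considered.  A call overlapping annotated genes on *both* strands is
    excluded: its transcript of origin is ambiguous.
    """
    candidates: List[AntisenseCandidate] = []
    for c in calls:
        if len(c.supporting_samples) < min_samples:
            continue
        overlapping = [
            g
            for g in annotation
            if g.reference_id == c.reference_id and g.start <= c.position <= g.end
        ]
        if any(g.strand == c.strand for g in overlapping):
            continue  # a sense gene could explain the site
        for g in overlapping:
            candidates.append(
                AntisenseCandidate(gene_id=g.gene_id, gene_strand=g.strand, psi_site=c)
            )
    candidates.sort(key=lambda a: (a.psi_site.reference_id, a.psi_site.position, a.gene_id))
    return candidates


def tss_proximity(
    candidate: AntisenseCandidate,
    known_tss: Sequence[Tuple[int, str]],
    window: int = 200,
) -> Optional[int]:
    """Distance from the nearest known same-strand TSS down to the Psi site.

    The distance is measured in the antisense transcript's direction of
    transcription: positive when the Psi site lies downstream of the TSS.
    Returned only when 0 <= distance <= ``window`` (bounds inclusive);
    sites upstream of every TSS, or farther than the window, give None.
    """
    distances = []
    for pos, strand in known_tss:
        if strand != candidate.strand:
            continue
        d = candidate.psi_site.position - pos if strand == "+" else pos - candidate.psi_site.position
        if 0 <= d <= window:
            distances.append(d)
    return min(distances) if distances else None


def _best_window_score(
    table: Optional[PredictorScoreTable],
    reference_id: str,
    region: Tuple[int, int],
    min_score: float,
) -> Optional[Tuple[float, Tuple[int, int]]]:
    """Highest-scoring predictor window fully inside ``region`` (inclusive)."""
    if table is None or len(table) == 0:
        return None
    lo, hi = region
    df = table.rows
    sel = df[
        (df["reference_id"] == reference_id)
        & (df["window_start"] >= lo)
        & (df["window_end"] <= hi)
        & (df["score"] >= min_score)
    ]
    if sel.empty:
        return None
    best = sel.loc[sel["score"].idxmax()]
    return float(best["score"]), (int(best["window_start"]), int(best["window_end"]))


def attach_predictor_scores(
    candidates: Sequence[AntisenseCandidate],
    promoter_scores: Optional[PredictorScoreTable] = None,
    tts_scores: Optional[PredictorScoreTable] = None,
    min_score: float = 0.9,
    promoter_window: int = 200,
    tts_window: int = 150,
) -> List[AntisenseCandidate]:
    """Attach promoter/terminator probabilities and predict sRNA spans.

    For each candidate, the promoter search region is the ``promoter_window``
    bases upstream of the Psi site and the TTS search region the
    ``tts_window`` bases downstream (both in antisense orientation, starting
    one base away from the Psi site).  Only predictor windows scoring at
    least ``min_score`` qualify; the highest-scoring window is attached.
    The predicted TSS is the promoter window's edge nearest the Psi site;
    when both a promoter and a TTS window qualify, the sRNA length from TSS
    to the TTS-window midpoint is filled in.
    """
    out: List[AntisenseCandidate] = []
    for cand in candidates:
        pos = cand.psi_site.position
        if cand.strand == "+":
            promoter_region = (pos - promoter_window, pos - 1)
            tts_region = (pos + 1, pos + tts_window)
        else:
            promoter_region = (pos + 1, pos + promoter_window)
            tts_region = (pos - tts_window, pos - 1)
        prom = _best_window_score(
            promoter_scores, cand.psi_site.reference_id, promoter_region, min_score
        )
        tts = _best_window_score(
            tts_scores, cand.psi_site.reference_id, tts_region, min_score
        )
        updated = cand
        if prom is not None:
            score, (wstart, wend) = prom
            # the transcript starts at the promoter edge facing the Psi site
            predicted_tss = wend if cand.strand == "+" else wstart
            updated = replace(updated, promoter_score=score, predicted_tss=predicted_tss)
        if tts is not None:
            score, window = tts
            updated = replace(updated, tts_score=score)
            if updated.predicted_tss is not None:
                updated = replace(
                    updated,
                    predicted_length=predict_srna_span(
                        updated.predicted_tss, window, cand.strand
                    ),
                )
        out.append(updated)
    return out


def predict_srna_span(
    predicted_tss: int, tts_window: Tuple[int, int], strand: str
) -> int:
    """Length of a putative sRNA: TSS to the midpoint of the TTS window.

    The span is counted inclusively from the TSS to the midpoint of the
    window containing the TTS.  For even-length windows the midpoint is
    taken at the lower coordinate on the + strand and mirrored (upper
    coordinate side) on the - strand, i.e. always floored in the direction
    of transcription, so mirrored inputs give identical lengths.
    """
    start, end = tts_window
    if start > end:
        raise ValueError(f"invalid TTS window {tts_window}")
    if strand == "+":
        if start < predicted_tss:
            raise ValueError("TTS window upstream of TSS")
        midpoint = math.floor((start + end) / 2)
        return midpoint - predicted_tss + 1
    if strand == "-":
        if end > predicted_tss:
            raise ValueError("TTS window upstream of TSS")
        midpoint = math.ceil((start + end) / 2)
        return predicted_tss - midpoint + 1
    raise ValueError(f"strand must be + or -, got {strand!r}")
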