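"""Readers and writers for every external format the pipeline touches.

Two pileup dialects are accepted: the ``bam-readcount`` text output the
upstream alignment pipeline emits (per-allele colon-separated fields, one
row per position), and a simplified 6-column TSV (ref, pos, base, depth,
del_count, nondel_count) that the bundled simulator writes so the method
can be exercised without any aligner plumbing.

Coordinate conventions: the internal model is 1-based inclusive (pileup
semantics); BED exports are 0-based half-open and every written file states
its convention in a header comment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pileup_model import PileupSite, PileupTable, PileupValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "AnnotationSet",
    "PredictorScoreTable",
    "read_pileup",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "read_predictor_scores",
    "write_calls",
    "read_calls",
    "FormatError",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# annotations


@dataclass(frozen=True)
class Gene:
    """One annotated gene: 1-based inclusive interval on a strand."""

    gene_id: str
    reference_id: str
    start: int
    end: int
    strand: str
    feature_class: str = "gene"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotationSet:
    """A collection of genes with unique ids."""

    genes: List[Gene]

    def __post_init__(self) -> None:
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise FormatError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def by_id(self) -> Dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}

    def lengths(self) -> Dict[str, int]:
        return {g.gene_id: g.length for g in self.genes}


@dataclass
class PredictorScoreTable:
    """Ingested scores of an external predictor (promoter/terminator/target).

    One row per scored window: (reference_id, window_start, window_end,
    score in [0, 1], predictor_name).  Coordinates 1-based inclusive.
    """

    rows: pd.DataFrame

    REQUIRED = ("reference_id", "window_start", "window_end", "score", "predictor_name")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise FormatError(f"predictor table missing columns: {missing}")
        bad = self.rows[(self.rows["score"] < 0) | (self.rows["score"] > 1)]
        if len(bad):
            raise FormatError(
                f"predictor scores outside [0, 1] at rows {list(bad.index[:5])}"
            )

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# pileups

# minimum column count of a bam-readcount row: ref, pos, base, depth + alleles
_BRC_MIN_FIELDS = 5


def _parse_brc_row(fields: Sequence[str], lineno: int) -> PileupSite:
    if len(fields) < _BRC_MIN_FIELDS:
        raise FormatError(
            f"line {lineno}: expected >= {_BRC_MIN_FIELDS} fields, got {len(fields)}"
        )
    try:
        ref, pos, base, depth = fields[0], int(fields[1]), fields[2], int(fields[3])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: {exc}") from None
    del_count = 0
    for allele_field in fields[4:]:
        parts = allele_field.split(":")
        if len(parts) < 2:
            raise FormatError(
                f"line {lineno}: malformed allele field {allele_field!r}"
            )
        allele = parts[0]
        try:
            count = int(parts[1])
        except ValueError:
            raise FormatError(
                f"line {lineno}: non-integer count in {allele_field!r}"
            ) from None
        # deletion alleles are reported as "-<deleted bases>:count:..."
        if allele.startswith("-"):
            del_count += count
    try:
        return PileupSite(ref, pos, base.upper(), depth, del_count)
    except PileupValidationError as exc:
        raise FormatError(f"line {lineno}: {exc}") from None


def _parse_simple_row(fields: Sequence[str], lineno: int) -> PileupSite:
    if len(fields) != 6:
        raise FormatError(f"line {lineno}: expected 6 columns, got {len(fields)}")
    try:
        ref, pos, base = fields[0], int(fields[1]), fields[2]
        depth, del_count = int(fields[3]), int(fields[4])
        int(fields[5])  # nondel_count; redundant but must be an integer
    except ValueError as exc:
        raise FormatError(f"line {lineno}: {exc}") from None
    try:
        return PileupSite(ref, pos, base.upper(), depth, del_count)
    except PileupValidationError as exc:
        raise FormatError(f"line {lineno}: {exc}") from None


def read_pileup(
    path: PathLike, dialect: str = "simple-tsv", sample_id: Optional[str] = None
) -> PileupTable:
    """Read a per-base pileup count table.

    Parameters
    ----------
    path:
        Tab- or whitespace-separated text file.  Lines starting with ``#``
        are ignored.
    dialect:
        ``"bam-readcount"`` for the aligner-pipeline output (deletion count
        extracted from ``-<bases>:count`` allele fields) or ``"simple-tsv"``
        for the 6-column format (ref, pos, base, depth, del_count,
        nondel_count).
    sample_id:
        Defaults to the file stem.
    """
    path = Path(path)
    if dialect not in ("bam-readcount", "simple-tsv"):
        raise ValueError(f"unknown pileup dialect {dialect!r}")
    parser = _parse_brc_row if dialect == "bam-readcount" else _parse_simple_row
    table = PileupTable(sample_id=sample_id or path.stem)
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            site = parser(line.split("\t") if "\t" in line else line.split(), lineno)
            try:
                table.add(site)
            except PileupValidationError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            n_rows += 1
    if n_rows == 0:
        logger.warning("pileup file %s contained no data rows", path)
    return table


def write_pileup(table: PileupTable, path: PathLike) -> None:
    """Write a pileup in the simple 6-column dialect (1-based positions)."""
    with open(Path(path), "w") as fh:
        fh.write("# simple pileup: ref\tpos(1-based)\tbase\tdepth\tdel\tnondel\n")
        for site in sorted(table, key=lambda s: (s.reference_id, s.position)):
            fh.write(
                f"{site.reference_id}\t{site.position}\t{site.ref_base}\t"
                f"{site.depth}\t{site.del_count}\t{site.depth - site.del_count}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read reference sequences into a dict reference_id -> uppercase string."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# annotations (GFF3 / BED)

_GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff3_attr(attributes: str, key: str) -> Optional[str]:
    for item in attributes.split(";"):
        item = item.strip()
        if item.startswith(key + "="):
            return item[len(key) + 1 :]
    return None


def read_annotation(path: PathLike, fmt: str = "GFF3") -> AnnotationSet:
    """Read gene annotations from GFF3 or BED.

    GFF3: every non-comment row becomes a gene; the id is the ``ID`` (or
    ``gene_id``) attribute.  BED: columns chrom, start (0-based), end,
    name, score, strand; converted to the internal 1-based inclusive model.
    """
    path = Path(path)
    if fmt.upper() == "GFF3":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=_GFF3_COLUMNS,
            dtype={"seqid": str, "attributes": str},
        )
        genes = []
        for i, row in df.iterrows():
            gene_id = _gff3_attr(row["attributes"], "ID") or _gff3_attr(
                row["attributes"], "gene_id"
            )
            if gene_id is None:
                raise FormatError(f"GFF3 row {i + 1}: no ID/gene_id attribute")
            genes.append(
                Gene(
                    gene_id=gene_id,
                    reference_id=row["seqid"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=str(row["strand"]),
                    feature_class=str(row["type"]),
                )
            )
        return AnnotationSet(genes)
    if fmt.upper() == "BED":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6), dtype={"chrom": str, "name": str},
        )
        genes = [
            Gene(
                gene_id=str(row["name"]),
                reference_id=row["chrom"],
                start=int(row["start"]) + 1,  # BED is 0-based half-open
                end=int(row["end"]),
                strand=str(row["strand"]),
            )
            for _, row in df.iterrows()
        ]
        return AnnotationSet(genes)
    raise ValueError(f"unknown annotation format {fmt!r}")


def write_annotation(annotation: AnnotationSet, path: PathLike) -> None:
    """Write genes as GFF3 (1-based inclusive)."""
    with open(Path(path), "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            fh.write(
                f"{g.reference_id}\tpsiscan\t{g.feature_class}\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# predictor scores


def read_predictor_scores(path: PathLike, predictor_name: Optional[str] = None) -> PredictorScoreTable:
    """Read an external predictor's score table (TSV).

    Expected columns: reference_id, window_start, window_end, score
    [, predictor_name].  Coordinates 1-based inclusive.
    """
    df = pd.read_csv(Path(path), sep="\t", comment="#")
    if "predictor_name" not in df.columns:
        df["predictor_name"] = predictor_name or "unknown"
    return PredictorScoreTable(df)


# ---------------------------------------------------------------------------
# call tables

_CALL_COLUMNS = [
    "reference",
    "pos",
    "strand",
    "treated_frac",
    "untreated_frac",
    "psi_proportion",
    "p_value",
    "n_supporting",
    "supporting_samples",
    "high_confidence",
    "homopolymer_flag",
]


def write_calls(calls: Iterable, path: PathLike, bed: Optional[PathLike] = None) -> None:
    """Write Psi calls as a TSV (1-based positions) and optionally a BED.

    The BED uses 0-based half-open coordinates with the Psi proportion in
    the score column.
    """
    from .psi_calling import PsiCall  # local import to avoid a cycle

    calls = sorted(calls, key=lambda c: (c.reference_id, c.position, c.strand))
    with open(Path(path), "w") as fh:
        fh.write("# psiscan calls; pos is 1-based inclusive\n")
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            assert isinstance(c, PsiCall)
            fh.write(
                "\t".join(
                    [
                        c.reference_id,
                        str(c.position),
                        c.strand,
                        f"{c.treated_fraction:.6g}",
                        f"{c.untreated_fraction:.6g}",
                        f"{c.psi_proportion:.6g}",
                        "NA" if c.p_value is None else f"{c.p_value:.6g}",
                        str(len(c.supporting_samples)),
                        ",".join(sorted(c.supporting_samples)) or "NA",
                        "1" if c.high_confidence else "0",
                        "1" if c.homopolymer_ambiguous else "0",
                    ]
                )
                + "\n"
            )
    if bed is not None:
        with open(Path(bed), "w") as fh:
            fh.write("# BED: 0-based half-open; score = psi_proportion\n")
            for c in calls:
                fh.write(
                    f"{c.reference_id}\t{c.position - 1}\t{c.position}\t"
                    f"psi\t{c.psi_proportion:.6g}\t{c.strand}\n"
                )


def read_calls(path: PathLike) -> List:
    """Read a call TSV written by :func:`write_calls` back into PsiCall objects."""
    from .psi_calling import PsiCall

    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype={"reference": str})
    calls = []
    for _, row in df.iterrows():
        supporting = (
            set()
            if pd.isna(row["supporting_samples"]) or row["supporting_samples"] == "NA"
            else set(str(row["supporting_samples"]).split(","))
        )
        calls.append(
            PsiCall(
                reference_id=row["reference"],
                position=int(row["pos"]),
                strand=str(row["strand"]),
                treated_fraction=float(row["treated_frac"]),
                untreated_fraction=float(row["untreated_frac"]),
                psi_proportion=float(row["psi_proportion"]),
                p_value=None if str(row["p_value"]) == "NA" or pd.isna(row["p_value"])
                else float(row["p_value"]),
                supporting_samples=supporting,
                high_confidence=bool(int(row["high_confidence"])),
                homopolymer_ambiguous=bool(int(row["homopolymer_flag"])),
            )
        )
    return calls
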