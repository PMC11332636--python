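"""Gene models and strand-aware genomic feature intervals.

Genes are read from GFF3 and decomposed into the five feature classes used
throughout the pipeline: distal promoter (P6), proximal promoter (P1), gene
start (GS, the first 1.5 kb of the gene), gene body (GB, the remainder to the
transcription termination site) and the transcription terminal region (TTR,
1 kb past the TTS).  All internal coordinates are 0-based half-open;
"upstream"/"downstream" are strand-aware.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

__all__ = [
    "FEATURE_CLASSES",
    "GeneModel",
    "FeatureGeometry",
    "FeatureInterval",
    "GffParseError",
    "parse_gene_models",
    "build_feature_intervals",
    "write_bed",
    "mean_gene_body_length",
]

#: Feature classes in hierarchy order (highest priority first).
FEATURE_CLASSES = ("P1", "GS", "P6", "GB", "TTR")


class GffParseError(ValueError):
    """Raised for malformed GFF3 input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class GeneModel:
    """A gene record in 0-based half-open coordinates.

    The TSS is the strand-aware 5' terminus of the gene span (``start`` on the
    + strand, ``end - 1`` on the - strand); the TTS is the opposite terminus.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FeatureGeometry:
    """Spans (bp) defining the promoter/gene feature windows.

    ``p6_excludes_p1`` makes the distal promoter the window from
    ``p1_span`` to ``p6_span`` upstream of the TSS (a 5 kb window with the
    defaults) rather than the full 6 kb upstream window, so P1 and P6 do not
    overlap and the per-bp feature densities use disjoint denominators.
    """

    p6_span: int = 6000
    p1_span: int = 1000
    gs_span: int = 1500
    ttr_span: int = 1000
    p6_excludes_p1: bool = True

    def __post_init__(self):
        for name in ("p6_span", "p1_span", "gs_span", "ttr_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p6_excludes_p1 and self.p6_span <= self.p1_span:
            raise ValueError("p6_span must exceed p1_span when p6_excludes_p1")

    def canonical_length(self, feature_class: str, mean_gene_body_length: float | None = None) -> float:
        """Canonical feature length in bp used as the density denominator."""
        if feature_class == "P1":
            return float(self.p1_span)
        if feature_class == "GS":
            return float(self.gs_span)
        if feature_class == "TTR":
            return float(self.ttr_span)
        if feature_class == "P6":
            return float(self.p6_span - self.p1_span if self.p6_excludes_p1 else self.p6_span)
        if feature_class == "GB":
            if mean_gene_body_length is None or mean_gene_body_length <= 0:
                raise ValueError("GB density requires a positive mean gene-body length")
            return float(mean_gene_body_length)
        raise KeyError(f"unknown feature class {feature_class!r}")


@dataclass(frozen=True)
class FeatureInterval:
    """One feature window of one gene, 0-based half-open."""

    gene_id: str
    feature_class: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}/{self.feature_class}: empty interval "
                f"[{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _parse_attributes(column: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in column.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def parse_gene_models(
    gff: str | IO[str] | Iterable[str],
    feature_types: tuple[str, ...] = ("gene",),
) -> list[GeneModel]:
    """Parse gene records from a GFF3 stream or path into :class:`GeneModel`.

    GFF3 1-based inclusive coordinates become 0-based half-open.  Duplicate
    gene IDs are rejected.  Records whose type is not in ``feature_types``
    are ignored, as are comment and directive lines.
    """
    close = False
    if isinstance(gff, str) and "\n" not in gff and "\t" not in gff:
        handle: Iterator[str] = open(gff)
        close = True
    elif isinstance(gff, str):
        handle = iter(gff.splitlines())
    else:
        handle = iter(gff)

    genes: list[GeneModel] = []
    seen: set[str] = set()
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # trailing FASTA section
                break
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(
                    f"expected 9 tab-separated columns, got {len(cols)}", lineno
                )
            if cols[2] not in feature_types:
                continue
            try:
                start1 = int(cols[3])
                end1 = int(cols[4])
            except ValueError as exc:
                raise GffParseError(f"non-integer coordinates: {exc}", lineno) from None
            if end1 < start1:
                raise GffParseError(f"end {end1} < start {start1}", lineno)
            strand = cols[6]
            if strand not in ("+", "-"):
                raise GffParseError(f"unsupported strand {strand!r}", lineno)
            attrs = _parse_attributes(cols[8])
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise GffParseError("gene record lacks an ID attribute", lineno)
            if gene_id in seen:
                raise GffParseError(f"duplicate gene ID {gene_id!r}", lineno)
            seen.add(gene_id)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    contig=cols[0],
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                )
            )
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]
    return genes


def _clip(start: int, end: int, contig_length: int) -> tuple[int, int]:
    return max(start, 0), min(end, contig_length)


def build_feature_intervals(
    genes: Iterable[GeneModel],
    geometry: FeatureGeometry = FeatureGeometry(),
    contig_lengths: Mapping[str, int] | None = None,
) -> list[FeatureInterval]:
    """Construct the P6/P1/GS/GB/TTR windows of every gene.

    Upstream/downstream are strand-aware; windows are clipped to
    ``[0, contig_length)`` and dropped when empty after clipping.  Genes no
    longer than ``gs_span`` contribute their whole span as GS and no GB.
    When ``contig_lengths`` is None, clipping applies only at zero.
    """
    out: list[FeatureInterval] = []
    for gene in genes:
        if contig_lengths is not None:
            if gene.contig not in contig_lengths:
                raise KeyError(f"contig {gene.contig!r} missing from contig_lengths")
            clen = contig_lengths[gene.contig]
        else:
            clen = 2**62
        g = geometry
        if gene.strand == "+":
            raw = {
                "P1": (gene.start - g.p1_span, gene.start),
                "P6": (
                    (gene.start - g.p6_span, gene.start - g.p1_span)
                    if g.p6_excludes_p1
                    else (gene.start - g.p6_span, gene.start)
                ),
                "GS": (gene.start, min(gene.start + g.gs_span, gene.end)),
                "GB": (gene.start + g.gs_span, gene.end),
                "TTR": (gene.end, gene.end + g.ttr_span),
            }
        else:
            raw = {
                "P1": (gene.end, gene.end + g.p1_span),
                "P6": (
                    (gene.end + g.p1_span, gene.end + g.p6_span)
                    if g.p6_excludes_p1
                    else (gene.end, gene.end + g.p6_span)
                ),
                "GS": (max(gene.start, gene.end - g.gs_span), gene.end),
                "GB": (gene.start, gene.end - g.gs_span),
                "TTR": (gene.start - g.ttr_span, gene.start),
            }
        for cls in FEATURE_CLASSES:
            start, end = _clip(*raw[cls], clen)
            if start >= end:
                continue
            out.append(
                FeatureInterval(
                    gene_id=gene.gene_id,
                    feature_class=cls,
                    contig=gene.contig,
                    start=start,
                    end=end,
                    strand=gene.strand,
                )
            )
    return out


def mean_gene_body_length(
    genes: Iterable[GeneModel], geometry: FeatureGeometry = FeatureGeometry()
) -> float:
    """Mean GB length over genes longer than ``gs_span`` (density denominator)."""
    lengths = [g.length - geometry.gs_span for g in genes if g.length > geometry.gs_span]
    if not lengths:
        raise ValueError("no gene longer than gs_span; mean gene-body length undefined")
    return float(sum(lengths)) / len(lengths)


def write_bed(intervals: Iterable[FeatureInterval], path: str) -> None:
    """Write intervals as BED6 (name = ``gene_id|class``), 0-based half-open."""
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda v: (v.contig, v.start, v.end)):
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t"
                f"{iv.gene_id}|{iv.feature_class}\t0\t{iv.strand}\n"
            )
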