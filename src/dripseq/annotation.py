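"""Gene models and intron feature derivation from GFF3 annotation.

A coding gene is represented by the union of its exons; introns are the
gaps between consecutive exons that meet a minimum length (50 bp by
default, matching the intron set used for retention analysis in small
intron-poor yeast genomes). A dedicated intron-only GFF3 can be written
so that read counting against introns is not confounded by exonic
features.

Coordinates are 0-based half-open internally; GFF3 on disk is 1-based
closed. Conversion happens only in the readers/writers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

#: Minimum intron length (bp) retained by default.
DEFAULT_MIN_INTRON_LENGTH = 50

_GENE_TYPES = {"gene", "protein_coding_gene"}
_TRANSCRIPT_TYPES = {"mRNA", "transcript"}
_EXON_TYPES = {"exon", "CDS"}


class AnnotationError(ValueError):
    """Malformed annotation input (broken hierarchy, overlapping exons...)."""


@dataclass
class GeneModel:
    """Exon structure of a coding gene.

    ``exons`` are 0-based half-open ``(start, end)`` intervals, sorted by
    coordinate and non-overlapping.
    """

    gene_id: str
    chrom: str
    strand: str  # '+', '-' or '.'
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon ({start},{end}) has end <= start"
                )
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: overlapping exons"
                )
            prev_end = end
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")

    @property
    def length(self) -> int:
        """Sum of exon lengths in bp."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Locus interval from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    def gaps(self) -> list[tuple[int, int]]:
        """All inter-exon gaps in coordinate order, unfiltered."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass(frozen=True)
class IntronFeature:
    """An intron interval derived from a gene model.

    ``intron_id`` is ``<gene_id>.i<k>`` with ``k`` the 1-based ordinal in
    transcription order (reverse coordinate order on the minus strand).
    """

    intron_id: str
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start


def parse_annotation(source: str | IO[str]) -> list[GeneModel]:
    """Parse a GFF3 stream into gene models.

    Accepts the usual gene → mRNA → exon/CDS hierarchy, or exons parented
    directly on genes. Genes with several transcripts are collapsed to the
    union of their exons (with a warning): the analysis operates on one
    effective transcript per gene.

    Raises
    ------
    AnnotationError
        On an exon whose Parent is unknown (the offending line is named),
        or overlapping exons within one transcript.
    """
    lines = _iter_lines(source)
    genes: dict[str, dict] = {}
    transcript_parent: dict[str, str] = {}
    exon_records: list[tuple[str, int, str, int, int]] = []  # line no kept for errors
    pending: list[tuple[int, str, object]] = []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        feat = feature_from_line(line)
        ftype = feat.featuretype
        if ftype in _GENE_TYPES:
            gid = feat.attributes.get("ID", [feat.id])[0]
            genes[gid] = {
                "chrom": feat.seqid,
                "strand": feat.strand if feat.strand in "+-" else ".",
            }
        elif ftype in _TRANSCRIPT_TYPES:
            tid = feat.attributes.get("ID", [feat.id])[0]
            parents = feat.attributes.get("Parent", [])
            if not parents:
                raise AnnotationError(
                    f"line {lineno}: transcript {tid!r} has no Parent"
                )
            transcript_parent[tid] = parents[0]
        elif ftype in _EXON_TYPES:
            parents = feat.attributes.get("Parent", [])
            if not parents:
                raise AnnotationError(f"line {lineno}: exon has no Parent")
            # gffutils gives 1-based closed coordinates
            exon_records.append(
                (parents[0], lineno, feat.seqid, feat.start - 1, feat.end)
            )
        # other feature types are ignored

    # group exons per (gene, transcript)
    per_transcript: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for parent, lineno, chrom, start, end in exon_records:
        if parent in genes:
            gid, tid = parent, parent
        elif parent in transcript_parent:
            gid, tid = transcript_parent[parent], parent
        else:
            raise AnnotationError(
                f"line {lineno}: exon references unknown parent {parent!r}"
            )
        if gid not in genes:
            raise AnnotationError(
                f"line {lineno}: transcript {parent!r} references unknown gene {gid!r}"
            )
        per_transcript.setdefault((gid, tid), []).append((start, end))

    # per-transcript overlap check, then union per gene
    gene_exons: dict[str, list[tuple[int, int]]] = {}
    gene_n_transcripts: dict[str, int] = {}
    for (gid, tid), exons in per_transcript.items():
        exons.sort()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"gene {gid}, transcript {tid}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        gene_exons.setdefault(gid, []).extend(exons)
        gene_n_transcripts[gid] = gene_n_transcripts.get(gid, 0) + 1

    models = []
    for gid, info in genes.items():
        exons = gene_exons.get(gid)
        if not exons:
            continue  # gene without exon children carries no model
        if gene_n_transcripts.get(gid, 0) > 1:
            logger.warning(
                "gene %s has %d transcripts; using exon union",
                gid,
                gene_n_transcripts[gid],
            )
            exons = _merge_intervals(exons)
        models.append(
            GeneModel(gene_id=gid, chrom=info["chrom"], strand=info["strand"],
                      exons=exons)
        )
    models.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return models


def _merge_intervals(ivals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _iter_lines(source: str | IO[str]) -> Iterator[str]:
    if isinstance(source, str):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def extract_introns(
    genes: Iterable[GeneModel],
    min_intron_length: int = DEFAULT_MIN_INTRON_LENGTH,
) -> list[IntronFeature]:
    """Derive intron features from inter-exon gaps.

    A gap of length >= ``min_intron_length`` bp (inclusive) becomes an
    intron. Introns are numbered 1..k in transcription order, so on the
    minus strand the last gap in genomic coordinates is intron 1.
    Single-exon genes contribute nothing. Sub-threshold gaps are dropped
    silently; the number dropped is logged.
    """
    introns: list[IntronFeature] = []
    n_dropped = 0
    for gene in genes:
        gaps = [(s, e) for s, e in gene.gaps() if e - s >= min_intron_length]
        n_dropped += len(gene.gaps()) - len(gaps)
        if gene.strand == "-":
            gaps = gaps[::-1]
        for k, (s, e) in enumerate(gaps, start=1):
            introns.append(
                IntronFeature(
                    intron_id=f"{gene.gene_id}.i{k}",
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    start=s,
                    end=e,
                    strand=gene.strand,
                )
            )
    if n_dropped:
        logger.info("dropped %d gaps shorter than %d bp", n_dropped,
                    min_intron_length)
    return introns


def write_intron_gff(introns: Iterable[IntronFeature], dest: str | IO[str]) -> None:
    """Write an intron-only GFF3 (1-based closed on disk).

    Round-trips exactly through :func:`read_intron_gff`.
    """
    own = isinstance(dest, str)
    fh = open(dest, "w") if own else dest
    try:
        fh.write("##gff-version 3\n")
        for it in introns:
            fh.write(
                "\t".join(
                    [
                        it.chrom,
                        "dripseq",
                        "intron",
                        str(it.start + 1),
                        str(it.end),
                        ".",
                        it.strand if it.strand in "+-" else ".",
                        ".",
                        f"ID={it.intron_id};Parent={it.gene_id}",
                    ]
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()


def write_gene_gff(genes: Iterable[GeneModel], dest: str | IO[str]) -> None:
    """Write gene models as a gene/exon GFF3 readable by
    :func:`parse_annotation`."""
    own = isinstance(dest, str)
    fh = open(dest, "w") if own else dest
    try:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            strand = g.strand if g.strand in "+-" else "."
            fh.write(f"{g.chrom}\tdripseq\tgene\t{s + 1}\t{e}\t.\t{strand}\t."
                     f"\tID={g.gene_id}\n")
            for xs, xe in g.exons:
                fh.write(f"{g.chrom}\tdripseq\texon\t{xs + 1}\t{xe}\t.\t"
                         f"{strand}\t.\tParent={g.gene_id}\n")
    finally:
        if own:
            fh.close()


def read_intron_gff(source: str | IO[str]) -> list[IntronFeature]:
    """Read an intron-only GFF3 written by :func:`write_intron_gff`."""
    introns = []
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        feat = feature_from_line(line)
        if feat.featuretype != "intron":
            continue
        try:
            iid = feat.attributes["ID"][0]
            gid = feat.attributes["Parent"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"line {lineno}: intron feature missing {exc} attribute"
            ) from exc
        introns.append(
            IntronFeature(
                intron_id=iid,
                gene_id=gid,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else ".",
            )
        )
    return introns
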