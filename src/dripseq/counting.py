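"""Intersection-strict read counting and count matrices.

Implements the intersection-strict assignment contract: for every aligned
base of a read, take the set of features covering that base, and
intersect these sets across all aligned bases of all blocks. A singleton
intersection assigns the read; an empty intersection (including any
uncovered base) is NO_FEATURE; more than one feature is AMBIGUOUS. A
read overlapping an exon/intron boundary is therefore ambiguous whenever
both feature kinds are in the index — which is why gene counting and
intron counting are run as two separate passes over two feature sets.

Because every feature here is a single interval, the intersection over
bases equals the set of features that contain the whole read; the naive
per-base oracle in the test-suite checks exactly this equivalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import GeneModel, IntronFeature

logger = logging.getLogger(__name__)

#: Sentinel assignment outcomes.
AMBIGUOUS = "__ambiguous__"
NO_FEATURE = "__no_feature__"


@dataclass(frozen=True)
class AlignedRead:
    """A consumed alignment record: sorted, non-overlapping aligned blocks
    (0-based half-open); spliced alignments have two or more blocks."""

    read_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id}: no aligned blocks")
        prev = None
        for s, e in self.blocks:
            if e <= s or (prev is not None and s < prev):
                raise ValueError(f"read {self.read_id}: malformed blocks")
            prev = e


@dataclass
class AssignmentTally:
    """Per-library bookkeeping; assigned + ambiguous + no_feature equals
    the number of reads processed."""

    assigned: int = 0
    ambiguous: int = 0
    no_feature: int = 0

    @property
    def total(self) -> int:
        return self.assigned + self.ambiguous + self.no_feature


@dataclass
class CountMatrix:
    """Integer counts, features x libraries, with feature lengths and
    library metadata (strain, replicate)."""

    counts: pd.DataFrame  # features x libraries, int
    lengths: pd.Series  # bp per feature
    meta: pd.DataFrame  # index=library_id, columns=[strain, replicate]

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("missing feature lengths")
        if (self.lengths <= 0).any():
            raise ValueError("non-positive feature length")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"libraries without metadata: {sorted(missing)}")
        self.meta = self.meta.loc[list(self.counts.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    def libraries_of_strain(self, strain: str) -> list[str]:
        return list(self.meta.index[self.meta["strain"] == strain])

    def subset_features(self, ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(ids)],
                           self.lengths.loc[list(ids)], self.meta.copy())

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, meta: pd.DataFrame) -> "CountMatrix":
        tbl = pd.read_csv(path, sep="\t", index_col="feature_id")
        lengths = tbl.pop("length")
        return cls(tbl, lengths, meta)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV with columns library_id, strain, replicate and
    optionally path (to a SAM/BAM file)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library_id", "strain", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return meta.set_index("library_id")


class FeatureIndex:
    """Per-chromosome interval index over single-interval features."""

    def __init__(
        self,
        features: Iterable[IntronFeature | GeneModel] | None = None,
    ) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._lengths: dict[str, int] = {}
        self._strands: dict[str, str] = {}
        self._order: list[str] = []
        if features:
            for f in features:
                self.add_feature(f)

    def add(self, feature_id: str, chrom: str, start: int, end: int,
            length: int | None = None, strand: str = ".") -> None:
        if feature_id in self._lengths:
            raise ValueError(f"duplicate feature id {feature_id!r}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, feature_id)
        self._lengths[feature_id] = length if length is not None else end - start
        self._strands[feature_id] = strand
        self._order.append(feature_id)

    def add_feature(self, f: IntronFeature | GeneModel) -> None:
        if isinstance(f, GeneModel):
            # a gene locus counts over its whole span; length is exonic bp
            s, e = f.span
            self.add(f.gene_id, f.chrom, s, e, length=f.length, strand=f.strand)
        else:
            self.add(f.intron_id, f.chrom, f.start, f.end, strand=f.strand)

    @property
    def feature_ids(self) -> list[str]:
        return list(self._order)

    @property
    def lengths(self) -> pd.Series:
        return pd.Series(self._lengths, dtype=np.int64).loc[self._order]

    def overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def containing(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)
                if iv.begin <= start and iv.end >= end}


def assign_read(read: AlignedRead, index: FeatureIndex) -> str:
    """Intersection-strict assignment of one read.

    Returns a feature id, or the :data:`AMBIGUOUS` / :data:`NO_FEATURE`
    sentinel.
    """
    result: set[str] | None = None
    for s, e in read.blocks:
        covering = index.containing(read.chrom, s, e)
        result = covering if result is None else (result & covering)
        if not result:
            return NO_FEATURE
    assert result is not None
    if len(result) > 1:
        return AMBIGUOUS
    return next(iter(result))


def count_reads(
    reads_by_library: dict[str, Iterable[AlignedRead]],
    index: FeatureIndex,
    meta: pd.DataFrame,
    stranded: bool = False,
) -> tuple[CountMatrix, dict[str, AssignmentTally]]:
    """Count intersection-strict assignments per feature per library.

    ``reads_by_library`` maps library_id to a read stream; every library
    must be present in ``meta`` (a hard error otherwise). ``stranded`` is
    accepted for completeness but strand-non-specific counting is the
    default mode of this pipeline; when set, only features on the read's
    strand (or unstranded features) are eligible.
    """
    unknown = set(reads_by_library) - set(meta.index)
    if unknown:
        raise ValueError(f"libraries absent from sample sheet: {sorted(unknown)}")
    feature_ids = index.feature_ids
    pos = {f: i for i, f in enumerate(feature_ids)}
    libs = list(reads_by_library)
    mat = np.zeros((len(feature_ids), len(libs)), dtype=np.int64)
    tallies: dict[str, AssignmentTally] = {}
    for j, lib in enumerate(libs):
        tally = AssignmentTally()
        for read in reads_by_library[lib]:
            outcome = assign_read(read, index)
            if stranded and outcome not in (AMBIGUOUS, NO_FEATURE):
                fs = index._strands.get(outcome, ".")
                if fs in "+-" and fs != read.strand:
                    outcome = NO_FEATURE
            if outcome == AMBIGUOUS:
                tally.ambiguous += 1
            elif outcome == NO_FEATURE:
                tally.no_feature += 1
            else:
                mat[pos[outcome], j] += 1
                tally.assigned += 1
        tallies[lib] = tally
    counts = pd.DataFrame(mat, index=feature_ids, columns=libs)
    return CountMatrix(counts, index.lengths, meta), tallies


def reads_from_sam(path: str | Path) -> Iterable[AlignedRead]:
    """Yield primary alignments from a SAM/BAM file as AlignedRead.

    Secondary, supplementary and unmapped records are skipped.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            blocks = _merge_adjacent(rec.get_blocks())
            if not blocks:
                continue
            yield AlignedRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                blocks=tuple(blocks),
                strand="-" if rec.is_reverse else "+",
            )


def _merge_adjacent(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    # pysam splits blocks at insertions; merge abutting blocks back
    merged: list[list[int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def count_sam_files(
    meta: pd.DataFrame,
    index: FeatureIndex,
    stranded: bool = False,
) -> tuple[CountMatrix, dict[str, AssignmentTally]]:
    """Count all libraries listed in a sample sheet carrying a 'path' column."""
    if "path" not in meta.columns:
        raise ValueError("sample sheet has no 'path' column")
    streams = {lib: reads_from_sam(meta.loc[lib, "path"]) for lib in meta.index}
    return count_reads(streams, index, meta, stranded=stranded)


def rpk(matrix: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of feature length, from raw counts.

    No depth normalization: the low-expression filter operates on raw
    library-level counts.
    """
    if (matrix.lengths <= 0).any():
        raise ValueError("zero or negative feature length")
    return matrix.counts.div(matrix.lengths, axis=0) * 1000.0
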