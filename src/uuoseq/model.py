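"""Core domain types shared by every stage of the pipeline.

Coordinate convention: all in-memory intervals are 0-based half-open
``[start, end)`` on a named chromosome with an explicit strand.  GTF I/O
(1-based inclusive) converts at the file boundary only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

PROTEIN_CODING = "protein_coding"
LNCRNA = "lncRNA"

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 when the spans overlap or touch."""
        if self.chrom != other.chrom:
            raise ValidationError("gap undefined across chromosomes")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


def merge_exons(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of exon coverage as a sorted list of disjoint intervals.

    Touching intervals are merged.  All inputs must share one chromosome
    and strand.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    strands = {iv.strand for iv in intervals}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValidationError(
            f"cannot merge intervals across chromosomes/strands: {chroms}, {strands}"
        )
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start <= last.end:  # overlap or touch
            if iv.end > last.end:
                merged[-1] = dataclasses.replace(last, end=iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass(frozen=True)
class GeneModel:
    """A gene as a set of exons on one chromosome and strand.

    ``biotype`` is free-form; the pipeline gives special meaning to
    ``protein_coding`` and ``lncRNA`` and carries anything else through
    untouched (real annotations contain pseudogenes and the like).
    """

    gene_id: str
    symbol: str
    biotype: str
    exons: tuple[GenomicInterval, ...]

    def __init__(self, gene_id: str, symbol: str, biotype: str,
                 exons: Iterable[GenomicInterval]):
        object.__setattr__(self, "gene_id", gene_id)
        object.__setattr__(self, "symbol", symbol)
        object.__setattr__(self, "biotype", biotype)
        object.__setattr__(self, "exons", tuple(exons))
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if not self.exons:
            raise ValidationError(f"gene {gene_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"gene {gene_id}: exons span multiple chromosomes/strands"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base (0-based)."""
        s = self.span
        return s.start if self.strand == "+" else s.end - 1

    @property
    def merged_exons(self) -> list[GenomicInterval]:
        return merge_exons(self.exons)

    @property
    def exon_union_length(self) -> int:
        return exon_union_length(self)

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive merged exons (may be empty)."""
        blocks = self.merged_exons
        out = []
        for a, b in zip(blocks, blocks[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def is_coding(self) -> bool:
        return self.biotype == PROTEIN_CODING

    def is_lncrna(self) -> bool:
        return self.biotype == LNCRNA


def exon_union_length(gene: GeneModel) -> int:
    """Total bp covered by the gene's exons (overlaps counted once)."""
    return sum(iv.length for iv in merge_exons(gene.exons))


@dataclass
class GenomeAnnotation:
    """A set of gene models on a genome with known chromosome lengths."""

    chromosomes: dict[str, int]
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.genes, (list, tuple)):
            genes = {}
            for g in self.genes:
                if g.gene_id in genes:
                    raise ValidationError(f"duplicate gene_id {g.gene_id}")
                genes[g.gene_id] = g
            self.genes = genes
        self.validate()

    def validate(self) -> None:
        for length in self.chromosomes.values():
            if length <= 0:
                raise ValidationError("chromosome lengths must be positive")
        for g in self.genes.values():
            if g.chrom not in self.chromosomes:
                raise ValidationError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            span = g.span
            if span.end > self.chromosomes[g.chrom]:
                raise ValidationError(
                    f"gene {g.gene_id}: span {span.start}-{span.end} exceeds "
                    f"{g.chrom} length {self.chromosomes[g.chrom]}"
                )

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self if g.is_coding()]

    def lncrna_genes(self) -> list[GeneModel]:
        return [g for g in self if g.is_lncrna()]

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self if g.chrom == chrom]

    def sorted_genes(self) -> list[GeneModel]:
        return sorted(self, key=lambda g: (g.chrom, g.span.start, g.gene_id))


class CountMatrix:
    """Non-negative integer read counts, genes x samples."""

    def __init__(self, gene_ids: Sequence[str], sample_ids: Sequence[str],
                 counts) -> None:
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.counts = np.asarray(counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in count matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in count matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.integer):
                rounded = np.rint(self.counts)
                if not np.array_equal(rounded, self.counts):
                    bad = np.argwhere(rounded != self.counts)[0]
                    raise ValidationError(
                        f"non-integer count at gene {self.gene_ids[bad[0]]}, "
                        f"sample {self.sample_ids[bad[1]]}"
                    )
                self.counts = rounded.astype(np.int64)
            if (self.counts < 0).any():
                bad = np.argwhere(self.counts < 0)[0]
                raise ValidationError(
                    f"negative count at gene {self.gene_ids[bad[0]]}, "
                    f"sample {self.sample_ids[bad[1]]}"
                )
        self.counts = self.counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), self.sample_ids, self.counts[rows, :])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


DEFAULT_CONTRASTS = (("SO", "2D"), ("SO", "8D"), ("2D", "8D"))


@dataclass
class StudyDesign:
    """Sample-to-group assignment plus the ordered contrasts to test.

    A contrast is an ordered pair ``(reference, test)``; fold changes are
    test over reference.
    """

    groups: dict[str, str]
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS

    def __post_init__(self) -> None:
        self.contrasts = tuple(tuple(c) for c in self.contrasts)
        counts: dict[str, int] = {}
        for group in self.groups.values():
            counts[group] = counts.get(group, 0) + 1
        for ref, test in self.contrasts:
            if ref == test:
                raise ValidationError(f"contrast {ref} vs {test}: groups must differ")
            for g in (ref, test):
                if g not in counts:
                    raise ValidationError(f"contrast group {g!r} has no samples")
                if counts[g] < 2:
                    raise ValidationError(
                        f"contrast group {g!r} has {counts[g]} sample(s); need >= 2"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen

    def contrast_id(self, contrast: tuple[str, str]) -> str:
        return f"{contrast[0]}_vs_{contrast[1]}"


@dataclass
class PipelineConfig:
    """All thresholds and tunables of the pipeline, in one place.

    Units are bp for distances, raw fractions for quantiles/thresholds,
    log2 units for fold-change cutoffs.
    """

    min_gene_length: int = 500
    lowcount_quantile: float = 0.25
    apply_median_filter: bool = True
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    log2fc_cutoff: float = 1.0
    neighbor_window: int = 100_000
    proximity_cutoff: int = 3_000
    bidirectional_tss_window: int = 1_000
    detection_rpkm_threshold: float = 0.0
    pseudocount: float = 0.5
    mds_top_genes: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.lowcount_quantile < 1.0):
            raise ValidationError("lowcount_quantile must lie in (0, 1)")
        for name in ("min_gene_length", "p_threshold", "fdr_threshold",
                     "log2fc_cutoff", "neighbor_window", "proximity_cutoff",
                     "bidirectional_tss_window", "detection_rpkm_threshold",
                     "pseudocount"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
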