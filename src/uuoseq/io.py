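"""Readers and writers for the interchange formats at the package edge.

GTF is the Ensembl dialect (1-based inclusive coordinates, ``key "value";``
attributes); counts and design tables are UTF-8 TSV with ``#`` comment
lines; candidate loci export as BED6 (0-based half-open).
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    LNCRNA,
    PROTEIN_CODING,
    CountMatrix,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    StudyDesign,
    ValidationError,
)


class GtfParseError(ValueError):
    """Malformed GTF input; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"GTF line {lineno}: {message}")
        self.lineno = lineno


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"\s*;')

#: biotype spellings seen in Ensembl/GENCODE GTFs, mapped to the two
#: classes this pipeline distinguishes; anything else passes through.
BIOTYPE_ALIASES = {
    "protein_coding": PROTEIN_CODING,
    "lncRNA": LNCRNA,
    "lincRNA": LNCRNA,
    "antisense": LNCRNA,
    "antisense_RNA": LNCRNA,
    "bidirectional_promoter_lncRNA": LNCRNA,
    "processed_transcript": LNCRNA,
}


def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(raw))
    if not attrs:
        raise GtfParseError(lineno, f"no parsable attributes in {raw!r}")
    return attrs


def read_gtf(path, chrom_sizes: Mapping[str, int] | None = None,
             biotype_map: Mapping[str, str] | None = None) -> GenomeAnnotation:
    """Read an Ensembl-dialect GTF into a :class:`GenomeAnnotation`.

    Exon features are grouped by ``gene_id``; 1-based inclusive coordinates
    become 0-based half-open.  ``chrom_sizes`` supplies chromosome lengths
    (and bounds checking); without it, lengths default to each chromosome's
    maximum observed end.  ``biotype_map`` optionally overrides per-gene
    biotypes for files lacking ``gene_biotype`` attributes.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict[str, str]] = {}
    max_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(lineno, f"expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_raw = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(lineno, f"non-integer coordinates {start_s!r}, {end_s!r}")
            if start1 < 1 or end1 < start1:
                raise GtfParseError(lineno, f"invalid 1-based interval {start1}-{end1}")
            if strand not in ("+", "-"):
                raise GtfParseError(lineno, f"invalid strand {strand!r}")
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr_raw, lineno)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise GtfParseError(lineno, "exon without gene_id attribute")
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise ValidationError(
                        f"GTF line {lineno}: unknown chromosome {chrom!r}"
                    )
                if iv.end > chrom_sizes[chrom]:
                    raise ValidationError(
                        f"GTF line {lineno}: exon end {iv.end} exceeds "
                        f"{chrom} length {chrom_sizes[chrom]}"
                    )
            exons.setdefault(gene_id, []).append(iv)
            meta.setdefault(gene_id, {})
            if "gene_name" in attrs:
                meta[gene_id].setdefault("symbol", attrs["gene_name"])
            bio = attrs.get("gene_biotype") or attrs.get("gene_type")
            if bio:
                meta[gene_id].setdefault("biotype", bio)
            max_end[chrom] = max(max_end.get(chrom, 0), iv.end)

    genes = {}
    for gene_id, ivs in exons.items():
        raw_bio = meta[gene_id].get("biotype", "")
        if biotype_map and gene_id in biotype_map:
            raw_bio = biotype_map[gene_id]
        biotype = BIOTYPE_ALIASES.get(raw_bio, raw_bio or "unknown")
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            symbol=meta[gene_id].get("symbol", gene_id),
            biotype=biotype,
            exons=ivs,
        )
    if chrom_sizes is None:
        chrom_sizes = dict(max_end)
    return GenomeAnnotation(chromosomes=dict(chrom_sizes), genes=genes)


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Write gene + exon features, 1-based inclusive, ordered by locus."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#!genome-version uuoseq-synthetic\n")
        for gene in annotation.sorted_genes():
            span = gene.span
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.symbol}"; '
                f'gene_biotype "{gene.biotype}";'
            )
            fh.write(
                f"{gene.chrom}\tuuoseq\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            for exon in sorted(gene.exons, key=lambda e: (e.start, e.end)):
                fh.write(
                    f"{gene.chrom}\tuuoseq\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )


def read_counts_tsv(path) -> CountMatrix:
    """Counts TSV: first column gene_id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in counts file: {dupes}")
    if df.columns.has_duplicates:
        raise ValidationError("duplicate sample ids in counts file")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            gene = df.index[vals.isna().argmax()]
            raise ValidationError(
                f"non-numeric count at gene {gene}, sample {col}"
            )
        df[col] = vals
    return CountMatrix(df.index.tolist(), df.columns.tolist(), df.to_numpy())


def write_counts_tsv(counts: CountMatrix, path) -> None:
    counts.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


def read_design_tsv(path, contrasts=None,
                    counts: CountMatrix | None = None) -> StudyDesign:
    """Design TSV with columns ``sample`` and ``group``.

    If ``counts`` is given, samples must match the count matrix exactly.
    Contrasts default to all ordered group pairs in first-seen group order
    when not supplied.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = [c.lower() for c in df.columns]
    if cols[:2] != ["sample", "group"]:
        raise ValidationError(
            f"design file must have columns sample, group; got {list(df.columns)}"
        )
    if df.iloc[:, 0].duplicated().any():
        raise ValidationError("duplicate sample in design file")
    groups = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if counts is not None:
        missing = set(counts.sample_ids) - set(groups)
        extra = set(groups) - set(counts.sample_ids)
        if missing or extra:
            raise ValidationError(
                f"design/counts sample mismatch: missing {sorted(missing)}, "
                f"extra {sorted(extra)}"
            )
    if contrasts is None:
        names: list[str] = []
        for g in groups.values():
            if g not in names:
                names.append(g)
        contrasts = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    return StudyDesign(groups=groups, contrasts=tuple(contrasts))


def write_design_tsv(design: StudyDesign, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in design.groups.items():
            fh.write(f"{sample}\t{group}\n")


def write_bed6(intervals: Sequence[tuple[str, GenomicInterval, float]], path) -> None:
    """BED6 export: (name, interval, score) triples, 0-based half-open."""
    with open(path, "w") as fh:
        for name, iv, score in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Published worked-example table

def load_tf_table() -> pd.DataFrame:
    """Fold-change table of 42 up-regulated transcription factors/regulators
    from the UUO renal-fibrosis RNA-seq cohort (2-day and 8-day ligation vs
    sham), as printed: linear fold, log2 fold and p-value per comparison.

    Genes not statistically significant in the 8-day comparison carry NA in
    the ``*_8d`` columns.
    """
    with resources.files("uuoseq.data").joinpath("uuo_tf_fold_changes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    for col in df.columns[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
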