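"""Genomic context of lncRNAs relative to protein-coding genes.

A lncRNA receives exactly one positional class, resolved in precedence
order:

  antisense      span overlap (>= 1 bp) with a coding gene on the opposite
                 strand;
  intronic       span entirely inside a single intron of a same-strand
                 coding gene (no exon overlap);
  bidirectional  no overlap, opposite strands, divergent orientation, and
                 TSS-to-TSS distance within the divergent-promoter window;
  intergenic     none of the above.

Coding neighbors are scanned within a symmetric window around the lncRNA
span (edge-to-edge distances; 0 means overlap), each neighbor carries a
per-contrast concordance label against the lncRNA's differential
expression, and candidates are the differentially expressed lncRNAs whose
nearest coding neighbor lies closer than the proximity cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .diffexpr import STATUS_DOWN, STATUS_UP
from .model import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    PipelineConfig,
    ValidationError,
)

CLASS_ANTISENSE = "antisense"
CLASS_INTRONIC = "intronic"
CLASS_BIDIRECTIONAL = "bidirectional"
CLASS_INTERGENIC = "intergenic"
CLASSES = (CLASS_INTERGENIC, CLASS_INTRONIC, CLASS_ANTISENSE, CLASS_BIDIRECTIONAL)


@dataclass
class Neighbor:
    gene_id: str
    distance: int          # edge-to-edge bp; 0 when overlapping
    signed_distance: int   # negative = upstream in the lncRNA's orientation
    side: str              # upstream / downstream / overlapping


@dataclass
class LncRNAContext:
    lncrna_id: str
    positional_class: str
    neighbors: list = field(default_factory=list)
    # contrast id -> {neighbor gene_id: similar|opposite|none}
    concordance: dict = field(default_factory=dict)

    @property
    def nearest(self) -> Neighbor | None:
        return self.neighbors[0] if self.neighbors else None


class _CodingIndex:
    """Interval index over coding-gene spans for fast window queries."""

    def __init__(self, annotation: GenomeAnnotation):
        self.genes = {g.gene_id: g for g in annotation.coding_genes()}
        self.trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            span = g.span
            self.trees.setdefault(g.chrom, IntervalTree()).addi(
                span.start, span.end, g.gene_id
            )

    def query(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in tree.overlap(start, end)]


def _divergent_tss_distance(lnc: GeneModel, coding: GeneModel) -> int | None:
    """TSS-to-TSS distance when the pair is divergently oriented (pointing
    away from each other) on opposite strands without overlap, else None."""
    if lnc.strand == coding.strand or lnc.span.overlaps(coding.span):
        return None
    if lnc.strand == "-":
        # lnc points left; coding (+) points right; divergent iff lnc TSS
        # is left of (or at) the coding TSS
        d = coding.tss - lnc.tss
    else:
        # lnc (+) points right; coding (-) points left
        d = lnc.tss - coding.tss
    return d if d >= 0 else None


def classify_lncrna(lnc: GeneModel, annotation: GenomeAnnotation,
                    config: PipelineConfig,
                    index: _CodingIndex | None = None) -> str:
    """Positional class of one lncRNA (precedence antisense > intronic >
    bidirectional > intergenic)."""
    if not lnc.is_lncrna():
        raise ValidationError(f"{lnc.gene_id} is not a lncRNA (biotype {lnc.biotype})")
    index = index or _CodingIndex(annotation)
    span = lnc.span
    window = max(config.neighbor_window, config.bidirectional_tss_window)
    nearby = index.query(span.chrom, span.start - window, span.end + window)

    overlapping = [g for g in nearby if g.span.overlaps(span)]
    if any(g.strand != lnc.strand for g in overlapping):
        return CLASS_ANTISENSE
    for g in overlapping:
        if g.strand != lnc.strand:
            continue
        for intron in g.introns:
            if intron.start <= span.start and span.end <= intron.end:
                return CLASS_INTRONIC
    for g in nearby:
        d = _divergent_tss_distance(lnc, g)
        if d is not None and d <= config.bidirectional_tss_window:
            return CLASS_BIDIRECTIONAL
    return CLASS_INTERGENIC


def find_neighbors(lnc: GeneModel, annotation: GenomeAnnotation,
                   window: int | None = None,
                   config: PipelineConfig | None = None,
                   index: _CodingIndex | None = None) -> list[Neighbor]:
    """Coding genes whose span lies within ``window`` bp of the lncRNA span
    (edge-to-edge), sorted by |distance| then gene id.

    The signed distance is negative for neighbors upstream of the lncRNA
    in its own strand orientation.
    """
    if window is None:
        window = (config or PipelineConfig()).neighbor_window
    if window <= 0:
        raise ValidationError("neighbor window must be > 0")
    index = index or _CodingIndex(annotation)
    span = lnc.span
    out: list[Neighbor] = []
    for g in index.query(span.chrom, span.start - window, span.end + window):
        gspan = g.span
        gap = span.gap_to(gspan)
        if gap > window:
            continue
        if gap == 0:
            side, signed = "overlapping", 0
        else:
            # genomically left or right of the lncRNA span
            left_of_lnc = gspan.end <= span.start
            if lnc.strand == "+":
                upstream = left_of_lnc
            else:
                upstream = not left_of_lnc
            side = "upstream" if upstream else "downstream"
            signed = -gap if upstream else gap
        out.append(Neighbor(g.gene_id, gap, signed, side))
    out.sort(key=lambda n: (n.distance, n.gene_id))
    return out


CONCORDANT_SIMILAR = "similar"
CONCORDANT_OPPOSITE = "opposite"
CONCORDANT_NONE = "none"


def concordance(lnc_row: pd.Series, neighbor_row: pd.Series,
                config: PipelineConfig) -> str:
    """Per-contrast expression concordance of a lncRNA/neighbor pair:
    ``similar`` when both are significant with same-signed log2 fold
    changes, ``opposite`` when both significant with opposite signs,
    ``none`` otherwise (a zero log2fc never counts as concordant)."""
    p_l, p_n = float(lnc_row["p"]), float(neighbor_row["p"])
    if p_l >= config.p_threshold or p_n >= config.p_threshold:
        return CONCORDANT_NONE
    s_l = np.sign(lnc_row["log2fc"])
    s_n = np.sign(neighbor_row["log2fc"])
    if s_l == 0 or s_n == 0:
        return CONCORDANT_NONE
    return CONCORDANT_SIMILAR if s_l == s_n else CONCORDANT_OPPOSITE


def build_contexts(annotation: GenomeAnnotation, config: PipelineConfig,
                   de_tables: dict[str, pd.DataFrame] | None = None
                   ) -> dict[str, LncRNAContext]:
    """Classify every lncRNA, find its coding neighbors and (when DE tables
    are supplied) label per-contrast concordance with each neighbor."""
    index = _CodingIndex(annotation)
    indexed_de = {}
    if de_tables:
        indexed_de = {
            cid: tbl.set_index("gene_id") for cid, tbl in de_tables.items()
        }
    contexts: dict[str, LncRNAContext] = {}
    for lnc in annotation.lncrna_genes():
        cls = classify_lncrna(lnc, annotation, config, index=index)
        neighbors = find_neighbors(lnc, annotation,
                                   window=config.neighbor_window, index=index)
        ctx = LncRNAContext(lnc.gene_id, cls, neighbors)
        for cid, tbl in indexed_de.items():
            if lnc.gene_id not in tbl.index:
                continue
            labels = {}
            for nb in neighbors:
                if nb.gene_id in tbl.index:
                    labels[nb.gene_id] = concordance(
                        tbl.loc[lnc.gene_id], tbl.loc[nb.gene_id], config
                    )
            ctx.concordance[cid] = labels
        contexts[lnc.gene_id] = ctx
    return contexts


def class_distribution(contexts: dict[str, LncRNAContext],
                       cohort: set | None = None) -> pd.Series:
    """Counts per positional class, optionally over a gene-id cohort."""
    counts = {c: 0 for c in CLASSES}
    for ctx in contexts.values():
        if cohort is not None and ctx.lncrna_id not in cohort:
            continue
        counts[ctx.positional_class] += 1
    return pd.Series(counts, name="n_lncrna")


@dataclass
class CandidateLncRNA:
    lncrna_id: str
    nearest_neighbor: str
    distance: int
    de_contrasts: list
    max_abs_log2fc: float
    concordance_summary: dict


def select_candidates(contexts: dict[str, LncRNAContext],
                      de_tables: dict[str, pd.DataFrame],
                      config: PipelineConfig) -> list[CandidateLncRNA]:
    """Differentially expressed lncRNAs (up/down in >= 1 contrast) whose
    nearest coding neighbor is closer than the proximity cutoff, ranked by
    max |log2fc| (ties: smaller distance, then id)."""
    indexed = {cid: tbl.set_index("gene_id") for cid, tbl in de_tables.items()}
    out: list[CandidateLncRNA] = []
    for ctx in contexts.values():
        nearest = ctx.nearest
        if nearest is None or nearest.distance >= config.proximity_cutoff:
            continue
        de_in, max_fc = [], 0.0
        for cid, tbl in indexed.items():
            if ctx.lncrna_id not in tbl.index:
                continue
            row = tbl.loc[ctx.lncrna_id]
            if row["status"] in (STATUS_UP, STATUS_DOWN):
                de_in.append(cid)
                max_fc = max(max_fc, abs(float(row["log2fc"])))
        if not de_in:
            continue
        summary = {
            cid: ctx.concordance.get(cid, {}).get(nearest.gene_id, CONCORDANT_NONE)
            for cid in indexed
        }
        out.append(CandidateLncRNA(ctx.lncrna_id, nearest.gene_id,
                                   nearest.distance, de_in, max_fc, summary))
    out.sort(key=lambda c: (-c.max_abs_log2fc, c.distance, c.lncrna_id))
    return out


def contexts_frame(contexts: dict[str, LncRNAContext]) -> pd.DataFrame:
    rows = []
    for ctx in contexts.values():
        nearest = ctx.nearest
        rows.append(
            {
                "lncrna_id": ctx.lncrna_id,
                "class": ctx.positional_class,
                "n_neighbors": len(ctx.neighbors),
                "nearest_neighbor": nearest.gene_id if nearest else None,
                "nearest_distance": nearest.distance if nearest else None,
            }
        )
    return pd.DataFrame(rows).sort_values("lncrna_id").reset_index(drop=True)


def candidates_frame(candidates: list[CandidateLncRNA]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": c.lncrna_id,
                "nearest_neighbor": c.nearest_neighbor,
                "distance": c.distance,
                "de_contrasts": ",".join(c.de_contrasts),
                "max_abs_log2fc": c.max_abs_log2fc,
                **{f"concordance_{cid}": lab
                   for cid, lab in c.concordance_summary.items()},
            }
            for c in candidates
        ]
    )
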