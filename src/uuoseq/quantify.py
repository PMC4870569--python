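"""Normalization, expression units and the pre-testing filter cascade.

Counts are normalized by median-of-ratios size factors (the DESeq-style
definition: per-sample median of the ratio of each gene's count to that
gene's geometric mean across samples, over genes observed in every
sample).  Before testing, genes pass a three-rule filter applied in order:

  i)   exon-union length below a minimum (default 500 bp);
  ii)  average normalized reads per 100 bp below the 25th quantile of that
       statistic's distribution over the genes entering the rule;
  iii) average normalized count below the median of that distribution over
       the genes entering the rule.

All three comparisons are strict ("less than"); thresholds for ii/iii are
recomputed on the genes surviving the preceding rules, and the realized
values are recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    CountMatrix,
    GenomeAnnotation,
    PipelineConfig,
    StudyDesign,
    ValidationError,
)


@dataclass
class NormalizedCounts:
    """Counts divided by per-sample size factors; raw = normalized * s."""

    gene_ids: list
    sample_ids: list
    size_factors: np.ndarray          # per sample, > 0
    normalized: np.ndarray            # genes x samples, float
    method: str = "median_of_ratios"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.normalized, index=self.gene_ids,
                            columns=self.sample_ids)

    def size_factor_series(self) -> pd.Series:
        return pd.Series(self.size_factors, index=self.sample_ids,
                         name="size_factor")

    def subset_genes(self, gene_ids) -> "NormalizedCounts":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return NormalizedCounts(list(gene_ids), self.sample_ids,
                                self.size_factors, self.normalized[rows, :],
                                self.method)


@dataclass
class FilterReport:
    """Bookkeeping of the filter cascade; removals are attributed to the
    first failing rule, so the four removal sets are disjoint."""

    n_input: int
    removed_by_zero_rows: list = field(default_factory=list)
    removed_by_length: list = field(default_factory=list)
    removed_by_low_density: list = field(default_factory=list)
    removed_by_median: list = field(default_factory=list)
    surviving: list = field(default_factory=list)
    realized_density_quantile: float = float("nan")
    realized_median: float = float("nan")

    @property
    def n_removed(self) -> int:
        return (len(self.removed_by_zero_rows) + len(self.removed_by_length)
                + len(self.removed_by_low_density) + len(self.removed_by_median))

    def check(self) -> None:
        if self.n_input != self.n_removed + len(self.surviving):
            raise AssertionError("filter report does not add up")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, ids in (
            ("zero_rows", self.removed_by_zero_rows),
            ("min_length", self.removed_by_length),
            ("low_density", self.removed_by_low_density),
            ("below_median", self.removed_by_median),
        ):
            rows.extend({"rule": name, "gene_id": g} for g in ids)
        rows.extend({"rule": "kept", "gene_id": g} for g in self.surviving)
        return pd.DataFrame(rows)


def compute_rpkm(counts: CountMatrix, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Reads per kilobase of exon per million mapped reads, per gene and
    sample; the per-sample library size is the column total over all genes
    in the matrix."""
    missing = [g for g in counts.gene_ids if g not in annotation]
    if missing:
        raise ValidationError(f"genes missing from annotation: {missing[:10]}"
                              + ("..." if len(missing) > 10 else ""))
    col_totals = counts.counts.sum(axis=0).astype(float)
    if (col_totals == 0).any():
        bad = [counts.sample_ids[j] for j in np.flatnonzero(col_totals == 0)]
        raise ValidationError(f"zero total counts in samples: {bad}")
    lengths = np.array([annotation[g].exon_union_length for g in counts.gene_ids],
                       dtype=float)
    rpkm = counts.counts / (lengths[:, None] / 1e3) / (col_totals[None, :] / 1e6)
    return pd.DataFrame(rpkm, index=counts.gene_ids, columns=counts.sample_ids)


def count_detected_genes(rpkm: pd.DataFrame, design: StudyDesign,
                         threshold: float = 0.0) -> tuple[pd.Series, pd.Series]:
    """Number of genes with RPKM strictly above ``threshold`` per sample,
    and the arithmetic mean of those tallies per group."""
    per_sample = (rpkm > threshold).sum(axis=0)
    per_sample.name = "detected_genes"
    group_means = {}
    for grp in design.group_names():
        members = design.samples_in(grp)
        group_means[grp] = float(per_sample[members].mean())
    return per_sample, pd.Series(group_means, name="mean_detected_genes")


def drop_zero_rows(counts: CountMatrix) -> tuple[CountMatrix, list]:
    """Remove genes with zero counts in every sample; order preserved."""
    keep = counts.counts.sum(axis=1) > 0
    kept_ids = [g for g, k in zip(counts.gene_ids, keep) if k]
    dropped = [g for g, k in zip(counts.gene_ids, keep) if not k]
    return CountMatrix(kept_ids, counts.sample_ids, counts.counts[keep, :]), dropped


def size_factors_median_of_ratios(counts: CountMatrix) -> NormalizedCounts:
    """Median-of-ratios size factors over genes positive in all samples."""
    mat = counts.counts.astype(float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError(
            "no gene has positive counts in every sample; filter the matrix "
            "(drop_zero_rows removes only all-zero rows) or merge samples"
        )
    ref = np.exp(np.log(mat[all_positive, :]).mean(axis=1))  # geometric mean
    ratios = mat[all_positive, :] / ref[:, None]
    s = np.median(ratios, axis=0)
    return NormalizedCounts(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        size_factors=s,
        normalized=mat / s[None, :],
    )


def _type7_quantile(values: np.ndarray, q: float) -> float:
    return float(np.quantile(values, q, method="linear"))


def filter_genes(normalized: NormalizedCounts, annotation: GenomeAnnotation,
                 config: PipelineConfig,
                 already_dropped: list | None = None) -> FilterReport:
    """Apply the three-rule cascade to normalized counts.

    ``already_dropped`` lets the caller record all-zero rows removed before
    normalization in the same report.
    """
    report = FilterReport(
        n_input=len(normalized.gene_ids) + len(already_dropped or []))
    report.removed_by_zero_rows = list(already_dropped or [])

    gene_ids = np.array(normalized.gene_ids)
    mean_norm = normalized.normalized.mean(axis=1)
    lengths = np.array([annotation[g].exon_union_length for g in gene_ids],
                       dtype=float)

    # rule i: minimum exon-union length, strict <
    fail_i = lengths < config.min_gene_length
    report.removed_by_length = gene_ids[fail_i].tolist()
    keep = ~fail_i

    # rule ii: average normalized reads per 100 bp vs its 25th quantile,
    # distribution taken over genes entering the rule
    density = mean_norm / (lengths / 100.0)
    if keep.any():
        thr = _type7_quantile(density[keep], config.lowcount_quantile)
        report.realized_density_quantile = thr
        fail_ii = keep & (density < thr)
        report.removed_by_low_density = gene_ids[fail_ii].tolist()
        keep = keep & ~fail_ii

    # rule iii: average normalized count vs its median over survivors
    if config.apply_median_filter and keep.any():
        thr = float(np.median(mean_norm[keep]))
        report.realized_median = thr
        fail_iii = keep & (mean_norm < thr)
        report.removed_by_median = gene_ids[fail_iii].tolist()
        keep = keep & ~fail_iii

    report.surviving = gene_ids[keep].tolist()
    report.check()
    return report


def normalize_and_filter(counts: CountMatrix, annotation: GenomeAnnotation,
                         config: PipelineConfig
                         ) -> tuple[NormalizedCounts, FilterReport]:
    """Convenience: drop all-zero rows, normalize, filter; returns the full
    normalized matrix plus the filter report (subset with
    ``normalized.subset_genes(report.surviving)``)."""
    nonzero, dropped = drop_zero_rows(counts)
    normalized = size_factors_median_of_ratios(nonzero)
    report = filter_genes(normalized, annotation, config, already_dropped=dropped)
    return normalized, report


def estimate_mate_inner_dist(mean_fragment: float, sd_fragment: float,
                             read_length: float) -> tuple[float, float]:
    """Paired-end inner-mate distance: fragment size minus twice the read
    length (may be negative for overlapping mates); the fragment-size
    standard deviation passes through unchanged."""
    if min(mean_fragment, sd_fragment, read_length) < 0:
        raise ValidationError("fragment and read metrics must be >= 0")
    return mean_fragment - 2.0 * read_length, sd_fragment
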