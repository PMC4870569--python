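"""Sample-QC ordination, clustering for heatmaps, volcano tables, the
qPCR ddCt utility, and the end-to-end pipeline driver.

Ordination is classical (Torgerson) multidimensional scaling on Euclidean
sample distances of the most variable genes; clustering is agglomerative
Ward on Euclidean distances.  Both are deterministic: MDS axis signs are
fixed and the Ward leaf order follows a fixed recursive rule (subtree with
the smaller minimum original index first).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import __version__
from .diffexpr import STATUS_NS, run_contrasts, venn, de_gene_set
from .enrichment import enrich_de_lists, read_gmt
from .io import (
    read_counts_tsv,
    read_design_tsv,
    read_gtf,
    write_bed6,
)
from .lncrna import (
    build_contexts,
    candidates_frame,
    class_distribution,
    contexts_frame,
    select_candidates,
)
from .model import PipelineConfig, ValidationError
from .quantify import (
    compute_rpkm,
    count_detected_genes,
    normalize_and_filter,
)

logger = logging.getLogger("uuoseq")


# ---------------------------------------------------------------------------
# Classical MDS

def classical_mds(matrix: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of the rows of ``matrix`` into k
    dimensions via double-centering and eigendecomposition.

    Coordinates are centered; each axis's sign is fixed so that the first
    sample with a non-zero coordinate on that axis is positive.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValidationError("classical MDS needs >= 3 samples")
    if k >= n:
        raise ValidationError(f"k = {k} must be < number of samples {n}")
    d = np.zeros((n, n))
    diffs = pdist(x)
    iu = np.triu_indices(n, 1)
    d[iu] = diffs
    d = d + d.T
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:k]
    vals = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(vals)[None, :]
    for axis in range(k):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return coords


def mds_qc(normalized, config: PipelineConfig, k: int = 2) -> pd.DataFrame:
    """Sample ordination on log2(normalized + pseudocount) of the top
    variance genes (count set by ``config.mds_top_genes``)."""
    logmat = np.log2(normalized.normalized + config.pseudocount)
    variances = logmat.var(axis=1)
    top = np.argsort(variances)[::-1][: config.mds_top_genes]
    coords = classical_mds(logmat[top, :].T, k=k)
    return pd.DataFrame(
        coords, index=normalized.sample_ids,
        columns=[f"dim{i + 1}" for i in range(k)],
    ).rename_axis("sample")


# ---------------------------------------------------------------------------
# Ward clustering

@dataclass
class ClusterResult:
    """Agglomerative clustering output: scipy-style linkage merge history
    plus a deterministic leaf order."""

    linkage: np.ndarray        # (n-1, 4): children, height, size
    leaf_order: list
    item_ids: list
    metric: str = "euclidean"
    method: str = "ward"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "left": self.linkage[:, 0].astype(int),
                "right": self.linkage[:, 1].astype(int),
                "height": self.linkage[:, 2],
                "size": self.linkage[:, 3].astype(int),
            }
        )


def _deterministic_leaf_order(linkage: np.ndarray, n: int) -> list[int]:
    """Leaf order by recursive subtree ordering, the subtree containing the
    smaller minimum original index coming first."""
    min_idx: dict[int, int] = {i: i for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for m, (a, b, _h, _s) in enumerate(linkage):
        node = n + m
        a, b = int(a), int(b)
        children[node] = (a, b)
        min_idx[node] = min(min_idx[a], min_idx[b])

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        first, second = (a, b) if min_idx[a] <= min_idx[b] else (b, a)
        return walk(first) + walk(second)

    return walk(n + len(linkage) - 1)


def ward_cluster(matrix: np.ndarray, item_ids=None) -> ClusterResult:
    """Ward clustering of the rows of ``matrix`` on Euclidean distances."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 items")
    if np.isnan(x).any():
        raise ValidationError("matrix contains NaN")
    linkage = hierarchy.linkage(x, method="ward", metric="euclidean")
    order = _deterministic_leaf_order(linkage, x.shape[0])
    ids = list(item_ids) if item_ids is not None else list(range(x.shape[0]))
    return ClusterResult(linkage=linkage, leaf_order=order, item_ids=ids)


def heatmap_selection(de_tables: dict[str, pd.DataFrame], normalized,
                      config: PipelineConfig) -> tuple[list, pd.DataFrame]:
    """Genes FDR-significant in >= 1 contrast, with their
    log2(normalized + pseudocount) expression matrix."""
    selected: set = set()
    for table in de_tables.values():
        selected |= set(table.loc[table["fdr"] < config.fdr_threshold, "gene_id"])
    genes = sorted(selected)
    idx = {g: i for i, g in enumerate(normalized.gene_ids)}
    rows = [idx[g] for g in genes]
    mat = np.log2(normalized.normalized[rows, :] + config.pseudocount)
    return genes, pd.DataFrame(mat, index=genes, columns=normalized.sample_ids)


# ---------------------------------------------------------------------------
# qPCR ddCt

def ddct_fold(ct_target_cond: float, ct_ref_cond: float,
              ct_target_baseline: float, ct_ref_baseline: float) -> float:
    """Relative expression by the ddCt method.

    dCt = Ct(target) - Ct(reference) per condition; ddCt is the condition
    dCt minus the baseline dCt; fold = 2 ** -ddCt.  Replicate Cts should
    be arithmetically averaged (in cycles) before calling.
    """
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_baseline - ct_ref_baseline)
    return float(2.0 ** (-ddct))


def qpcr_folds(ct_table: pd.DataFrame, reference_gene: str = "Gapdh",
               baseline_condition: str = "SO") -> pd.DataFrame:
    """Fold changes for a tidy Ct table with columns target, condition,
    ct (replicates as repeated rows); each target/condition is averaged
    then referenced to ``reference_gene`` and ``baseline_condition``."""
    required = {"target", "condition", "ct"}
    if not required <= set(ct_table.columns):
        raise ValidationError(f"Ct table needs columns {sorted(required)}")
    if (ct_table["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive cycles")
    mean_ct = ct_table.groupby(["target", "condition"])["ct"].mean()
    rows = []
    for (target, cond) in mean_ct.index:
        if target == reference_gene or cond == baseline_condition:
            continue
        try:
            fold = ddct_fold(
                mean_ct[(target, cond)],
                mean_ct[(reference_gene, cond)],
                mean_ct[(target, baseline_condition)],
                mean_ct[(reference_gene, baseline_condition)],
            )
        except KeyError as err:
            raise ValidationError(f"missing Ct for {err.args[0]}") from None
        rows.append({"target": target, "condition": cond, "fold": fold})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Volcano tables

def volcano_table(de_table: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Significant genes only, with -log10 p for plotting; metadata about
    the fold-change cutoff travels in ``DataFrame.attrs``."""
    sig = de_table[de_table["status"] != STATUS_NS].copy()
    sig["neg_log10_p"] = -np.log10(sig["p"])
    out = sig[["gene_id", "log2fc", "neg_log10_p", "status"]].reset_index(drop=True)
    out.attrs["log2fc_cutoff"] = config.log2fc_cutoff
    return out


# ---------------------------------------------------------------------------
# Pipeline driver

def run_pipeline(config: PipelineConfig, input_dir, out_dir,
                 gmt_path=None) -> Path:
    """quantify -> differential expression -> lncRNA context -> optional
    enrichment -> reports, from a fixture-style input directory
    (annotation.gtf, counts.tsv, design.tsv)."""
    input_dir, out = Path(input_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "read inputs"
    try:
        annotation = read_gtf(input_dir / "annotation.gtf")
        counts = read_counts_tsv(input_dir / "counts.tsv")
        design = read_design_tsv(input_dir / "design.tsv", counts=counts)

        stage = "quantify"
        rpkm = compute_rpkm(counts, annotation)
        rpkm.rename_axis("gene_id").to_csv(out / "rpkm.tsv", sep="\t")
        per_sample, per_group = count_detected_genes(
            rpkm, design, config.detection_rpkm_threshold)
        pd.concat(
            [per_sample.rename_axis("sample"),
             pd.Series(design.groups, name="group")],
            axis=1,
        ).to_csv(out / "detected_genes.tsv", sep="\t")
        per_group.rename_axis("group").to_csv(out / "detected_genes_per_group.tsv",
                                              sep="\t")
        normalized, report = normalize_and_filter(counts, annotation, config)
        normalized.to_frame().rename_axis("gene_id").to_csv(
            out / "normalized.tsv", sep="\t")
        normalized.size_factor_series().rename_axis("sample").to_csv(
            out / "size_factors.tsv", sep="\t")
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        with open(out / "filter_thresholds.tsv", "w") as fh:
            fh.write("statistic\tvalue\n")
            fh.write(f"density_quantile\t{report.realized_density_quantile}\n")
            fh.write(f"median_normalized\t{report.realized_median}\n")
        surviving = normalized.subset_genes(report.surviving)

        stage = "differential expression"
        de_tables = run_contrasts(surviving, design, config)
        for cid, table in de_tables.items():
            table.to_csv(out / f"de_{cid}.tsv", sep="\t", index=False)
            for direction in ("up", "down"):
                genes = sorted(de_gene_set(table, direction))
                (out / f"{direction}_{cid}.txt").write_text(
                    "\n".join(genes) + ("\n" if genes else ""))
            volcano_table(table, config).to_csv(
                out / f"volcano_{cid}.tsv", sep="\t", index=False)
        cids = list(de_tables)
        if len(cids) >= 2:
            part = venn(de_gene_set(de_tables[cids[0]], "significant"),
                        de_gene_set(de_tables[cids[1]], "significant"))
            with open(out / f"venn_{cids[0]}_{cids[1]}.tsv", "w") as fh:
                fh.write("partition\tn\tgenes\n")
                for name, s in (("only_a", part.only_a), ("both", part.both),
                                ("only_b", part.only_b)):
                    fh.write(f"{name}\t{len(s)}\t{','.join(sorted(s))}\n")

        stage = "lncRNA context"
        contexts = build_contexts(annotation, config, de_tables)
        contexts_frame(contexts).to_csv(out / "lncrna_context.tsv", sep="\t",
                                        index=False)
        class_distribution(contexts).rename_axis("class").to_csv(
            out / "class_distribution.tsv", sep="\t")
        candidates = select_candidates(contexts, de_tables, config)
        candidates_frame(candidates).to_csv(out / "candidates.tsv", sep="\t",
                                            index=False)
        write_bed6(
            [(c.lncrna_id, annotation[c.lncrna_id].span, c.max_abs_log2fc)
             for c in candidates],
            out / "candidates.bed",
        )

        if gmt_path is not None:
            stage = "enrichment"
            collection = read_gmt(gmt_path)
            for direction in ("up", "down"):
                results = enrich_de_lists(de_tables, collection, direction)
                for cid, res in results.items():
                    res.to_csv(out / f"enrichment_{cid}_{direction}.tsv",
                               sep="\t", index=False)

        stage = "report"
        mds_qc(surviving, config).to_csv(out / "mds.tsv", sep="\t")
        genes, heat = heatmap_selection(de_tables, surviving, config)
        heat.rename_axis("gene_id").to_csv(out / "heatmap_matrix.tsv", sep="\t")
        if len(genes) >= 2:
            result = ward_cluster(heat.to_numpy(), item_ids=genes)
            (out / "cluster_genes.txt").write_text(
                "\n".join(result.item_ids[i] for i in result.leaf_order) + "\n")
            result.merges_frame().to_csv(out / "merges.tsv", sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    config_blob = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "uuoseq_version": __version__,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 3),
    }
    with open(out / "run_manifest.txt", "w") as fh:
        for key, value in manifest.items():
            fh.write(f"{key}\t{value}\n")
    logger.info("pipeline finished in %.1fs -> %s", manifest["elapsed_s"], out)
    return out
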