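"""Synthetic genomes and count matrices with planted ground truth.

The generator emulates the study design of an obstructive-nephropathy
RNA-seq time course: three groups (sham-operated ``SO``, 2-day ``2D`` and
8-day ``8D`` post-ligation), a genome of protein-coding genes plus lncRNAs
planted in four positional classes (intergenic, intronic, antisense,
bidirectional), and negative-binomial counts

    mu_gj = s_j * q_g * 2**delta_g(group_j),   Var = mu + alpha * mu**2

with per-sample size factors ``s_j``, per-gene baselines ``q_g``,
dispersions ``alpha_g`` and planted per-group log2 effects ``delta_g``
(``delta(SO) = 0``).  The per-contrast effect is the delta difference, so a
gene is truly differential in a contrast exactly when that difference is
non-zero.

Every stochastic choice flows from one integer seed through named
substreams, so identical parameters give bit-identical output regardless
of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_counts_tsv, write_design_tsv, write_gtf
from .model import (
    LNCRNA,
    PROTEIN_CODING,
    CountMatrix,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    StudyDesign,
)

LNC_CLASSES = ("intergenic", "intronic", "antisense", "bidirectional")


class CapacityError(ValueError):
    """Requested gene layout does not fit on the requested chromosomes."""


@dataclass
class SimulationParams:
    """Tunables of the synthetic study; defaults are the standard scenario
    (2000 genes, 10 lncRNAs per class, 4+3+3 samples)."""

    n_chromosomes: int = 5
    chrom_length: int = 100_000_000
    n_coding_genes: int = 1960
    n_lncrna_per_class: dict = field(
        default_factory=lambda: {c: 10 for c in LNC_CLASSES}
    )
    n_samples_per_group: dict = field(
        default_factory=lambda: {"SO": 4, "2D": 3, "8D": 3}
    )
    # log-normal baseline expression q_g (log-space mean/sd)
    baseline_log_mean: float = float(np.log(150.0))
    baseline_log_sd: float = 1.2
    # log-normal dispersion alpha_g
    dispersion_log_mean: float = float(np.log(0.08))
    dispersion_log_sd: float = 0.5
    fraction_de: float = 0.15
    effect_low: float = 1.0
    effect_high: float = 2.5
    size_factor_range: tuple = (0.7, 1.4)
    # lncRNA/neighbor pairing
    intergenic_proximal_fraction: float = 0.5
    concordant_fraction: float = 0.5
    # geometry
    neighbor_window: int = 100_000
    bidirectional_tss_window: int = 1_000
    proximity_cutoff: int = 3_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fraction_de < 0 or self.fraction_de > 1:
            raise ValueError("fraction_de must lie in [0, 1]")
        if self.size_factor_range[0] <= 0:
            raise ValueError("size factors must be positive")
        for cls in self.n_lncrna_per_class:
            if cls not in LNC_CLASSES:
                raise ValueError(f"unknown lncRNA class {cls!r}")


@dataclass
class SimulationTruth:
    """Planted quantities downstream stages are measured against."""

    baseline: dict = field(default_factory=dict)          # gene -> q_g
    dispersion: dict = field(default_factory=dict)        # gene -> alpha_g
    group_effects: dict = field(default_factory=dict)     # gene -> {group: delta}
    size_factors: dict = field(default_factory=dict)      # sample -> s_j
    lnc_class: dict = field(default_factory=dict)         # lnc -> class
    lnc_neighbor: dict = field(default_factory=dict)      # lnc -> coding gene_id|None
    lnc_neighbor_distance: dict = field(default_factory=dict)  # lnc -> bp
    pair_concordant: dict = field(default_factory=dict)   # lnc -> bool|None

    def beta(self, gene_id: str, contrast: tuple[str, str]) -> float:
        """Planted log2 effect of ``contrast = (reference, test)``."""
        eff = self.group_effects.get(gene_id, {})
        return eff.get(contrast[1], 0.0) - eff.get(contrast[0], 0.0)

    def is_de(self, gene_id: str, contrast: tuple[str, str]) -> bool:
        return self.beta(gene_id, contrast) != 0.0

    def genes_frame(self) -> pd.DataFrame:
        genes = sorted(self.baseline)
        groups = sorted({g for eff in self.group_effects.values() for g in eff})
        rows = {
            "gene_id": genes,
            "baseline": [self.baseline[g] for g in genes],
            "dispersion": [self.dispersion[g] for g in genes],
        }
        for grp in groups:
            rows[f"delta_{grp}"] = [
                self.group_effects.get(g, {}).get(grp, 0.0) for g in genes
            ]
        return pd.DataFrame(rows)

    def lnc_frame(self) -> pd.DataFrame:
        lncs = sorted(self.lnc_class)
        return pd.DataFrame(
            {
                "lncrna_id": lncs,
                "class": [self.lnc_class[l] for l in lncs],
                "neighbor": [self.lnc_neighbor.get(l) for l in lncs],
                "neighbor_distance": [self.lnc_neighbor_distance.get(l) for l in lncs],
                "concordant": [self.pair_concordant.get(l) for l in lncs],
            }
        )


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Annotation synthesis

def _make_coding_gene(rng: np.random.Generator, gene_id: str, chrom: str,
                      start: int) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(3, 6))
    exons = []
    pos = start
    for i in range(n_exons):
        exon_len = int(rng.integers(150, 1201))
        exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand))
        pos += exon_len
        if i < n_exons - 1:
            pos += int(rng.integers(1500, 6001))
    return GeneModel(gene_id, gene_id, PROTEIN_CODING, exons)


def _single_exon_lnc(lnc_id: str, chrom: str, start: int, end: int,
                     strand: str) -> GeneModel:
    return GeneModel(lnc_id, lnc_id, LNCRNA,
                     [GenomicInterval(chrom, start, end, strand)])


def simulate_annotation(params: SimulationParams) -> tuple[GenomeAnnotation, SimulationTruth]:
    """Lay out coding genes with wide spacing and plant lncRNAs of each
    positional class against chosen host coding genes.

    Coding genes sit >= 2x the neighbor window apart edge-to-edge, so each
    planted lncRNA has a single unambiguous coding gene in its vicinity and
    the intended class is exactly recoverable from the emitted geometry.
    """
    rng = _stream(params.seed, 0)
    chroms = {f"chr{i + 1}": params.chrom_length for i in range(params.n_chromosomes)}
    chrom_names = list(chroms)

    spacing_base = 2 * params.neighbor_window + 10_000
    genes: list[GeneModel] = []
    per_chrom = -(-params.n_coding_genes // params.n_chromosomes)  # ceil
    placed = 0
    for chrom in chrom_names:
        cursor = 1_000_000
        for _ in range(per_chrom):
            if placed >= params.n_coding_genes:
                break
            gene_id = f"PCG{placed + 1:05d}"
            gene = _make_coding_gene(rng, gene_id, chrom, cursor)
            span = gene.span
            if span.end > params.chrom_length - 1_000_000:
                raise CapacityError(
                    f"cannot fit {params.n_coding_genes} coding genes on "
                    f"{params.n_chromosomes} x {params.chrom_length} bp"
                )
            genes.append(gene)
            placed += 1
            cursor = span.end + spacing_base + int(rng.integers(0, 20_000))
    if placed < params.n_coding_genes:
        raise CapacityError("ran out of chromosomes while placing coding genes")

    truth = SimulationTruth()
    coding_by_id = {g.gene_id: g for g in genes}
    order = [g.gene_id for g in genes]

    # eligible hosts, shuffled once; each host used for at most one lncRNA
    host_pool = list(order)
    rng.shuffle(host_pool)

    def take_host(predicate) -> GeneModel:
        for i, gid in enumerate(host_pool):
            g = coding_by_id[gid]
            if predicate(g):
                host_pool.pop(i)
                return g
        raise CapacityError("no eligible host coding gene left for lncRNA placement")

    lnc_genes: list[GeneModel] = []
    counter = 0
    n_intergenic = params.n_lncrna_per_class.get("intergenic", 0)
    n_proximal = int(round(n_intergenic * params.intergenic_proximal_fraction))

    for cls in LNC_CLASSES:
        for k in range(params.n_lncrna_per_class.get(cls, 0)):
            counter += 1
            lnc_id = f"LNC{counter:04d}"
            if cls == "intronic":
                host = take_host(
                    lambda g: any(iv.length >= 1200 for iv in g.introns)
                )
                intron = max(host.introns, key=lambda iv: iv.length)
                lnc_len = int(rng.integers(500, min(2500, intron.length - 400) + 1))
                offset = int(rng.integers(100, intron.length - lnc_len - 100 + 1))
                start = intron.start + offset
                lnc = _single_exon_lnc(lnc_id, host.chrom, start, start + lnc_len,
                                       host.strand)
                dist = 0
            elif cls == "antisense":
                host = take_host(lambda g: g.span.length >= 4000)
                span = host.span
                lnc_len = int(rng.integers(600, 2501))
                lo = span.start + span.length // 4
                start = lo + int(rng.integers(0, max(1, span.length // 4)))
                end = min(start + lnc_len, span.end - 1)
                opp = "-" if host.strand == "+" else "+"
                lnc = _single_exon_lnc(lnc_id, host.chrom, start, end, opp)
                dist = 0
            elif cls == "bidirectional":
                host = take_host(lambda g: True)
                gap = int(rng.integers(150, min(900, params.bidirectional_tss_window) + 1))
                lnc_len = int(rng.integers(500, 2001))
                if host.strand == "+":
                    tss = host.span.start
                    end = tss - gap + 1
                    lnc = _single_exon_lnc(lnc_id, host.chrom, end - lnc_len, end, "-")
                else:
                    tss = host.span.end - 1
                    start = tss + gap
                    lnc = _single_exon_lnc(lnc_id, host.chrom, start, start + lnc_len, "+")
                dist = lnc.span.gap_to(host.span)
            else:  # intergenic
                proximal = k < n_proximal
                host = take_host(lambda g: True)
                if proximal:
                    d = int(rng.integers(200, params.proximity_cutoff - 200))
                else:
                    d = int(rng.integers(5_000, params.neighbor_window - 10_000))
                lnc_len = int(rng.integers(500, 2501))
                start = host.span.end + d
                lnc = _single_exon_lnc(lnc_id, host.chrom, start, start + lnc_len,
                                       host.strand)
                dist = d
            truth.lnc_class[lnc_id] = cls
            truth.lnc_neighbor[lnc_id] = host.gene_id
            truth.lnc_neighbor_distance[lnc_id] = dist
            lnc_genes.append(lnc)

    all_genes = {g.gene_id: g for g in genes + lnc_genes}
    annotation = GenomeAnnotation(chromosomes=chroms, genes=all_genes)
    return annotation, truth


# ---------------------------------------------------------------------------
# Count synthesis

def _plant_effects(rng: np.random.Generator, gene_ids: list[str],
                   params: SimulationParams,
                   truth: SimulationTruth) -> None:
    """Plant per-group log2 effects; lncRNA/neighbor pairs get coupled
    effects whose sign relation encodes concordant vs opposite regulation."""
    test_groups = [g for g in params.n_samples_per_group if g != "SO"]
    paired: set[str] = set()
    for lnc_id, host_id in truth.lnc_neighbor.items():
        if lnc_id not in truth.baseline:
            continue  # lncRNA not in the count matrix
        concordant = bool(rng.random() < params.concordant_fraction)
        truth.pair_concordant[lnc_id] = concordant
        sign = 1.0 if rng.random() < 0.5 else -1.0
        rel = 1.0 if concordant else -1.0
        lnc_eff, host_eff = {}, {}
        for grp in test_groups:
            lnc_eff[grp] = sign * float(rng.uniform(params.effect_low, params.effect_high))
            host_eff[grp] = rel * sign * float(
                rng.uniform(params.effect_low, params.effect_high)
            )
        truth.group_effects[lnc_id] = lnc_eff
        truth.group_effects[host_id] = host_eff
        paired.update((lnc_id, host_id))
    for gid in gene_ids:
        if gid in paired:
            continue
        eff = {}
        for grp in test_groups:
            if rng.random() < params.fraction_de:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                eff[grp] = sign * float(rng.uniform(params.effect_low, params.effect_high))
        if eff:
            truth.group_effects[gid] = eff


def simulate_counts(annotation: GenomeAnnotation, design: StudyDesign,
                    params: SimulationParams,
                    truth: SimulationTruth | None = None
                    ) -> tuple[CountMatrix, SimulationTruth]:
    """Draw NB counts for every annotated gene under the planted model.

    ``truth`` may carry the positional classes from
    :func:`simulate_annotation`; it is completed in place (baselines,
    dispersions, effects, size factors) and returned.
    """
    if truth is None:
        truth = SimulationTruth()
    rng = _stream(params.seed, 1)
    gene_ids = [g.gene_id for g in annotation.sorted_genes()]
    sample_ids = design.sample_ids
    n_g, n_s = len(gene_ids), len(sample_ids)

    q = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, size=n_g)
    alpha = rng.lognormal(params.dispersion_log_mean, params.dispersion_log_sd,
                          size=n_g)
    lo, hi = params.size_factor_range
    s = rng.uniform(lo, hi, size=n_s)

    truth.baseline = dict(zip(gene_ids, q))
    truth.dispersion = dict(zip(gene_ids, alpha))
    truth.size_factors = dict(zip(sample_ids, s))
    if params.fraction_de > 0:
        _plant_effects(rng, gene_ids, params, truth)

    delta = np.zeros((n_g, n_s))
    for j, sample in enumerate(sample_ids):
        grp = design.groups[sample]
        for i, gid in enumerate(gene_ids):
            delta[i, j] = truth.group_effects.get(gid, {}).get(grp, 0.0)

    mu = q[:, None] * s[None, :] * np.exp2(delta)
    counts = _draw_nb(rng, mu, alpha)
    return CountMatrix(gene_ids, sample_ids, counts), truth


def _draw_nb(rng: np.random.Generator, mu: np.ndarray,
             alpha: np.ndarray) -> np.ndarray:
    """NB draw with Var = mu + alpha mu^2; alpha below 1e-12 degenerates to
    Poisson."""
    out = np.empty(mu.shape, dtype=np.int64)
    poisson_rows = alpha < 1e-12
    if poisson_rows.any():
        out[poisson_rows] = rng.poisson(mu[poisson_rows])
    nb_rows = ~poisson_rows
    if nb_rows.any():
        a = alpha[nb_rows][:, None]
        m = mu[nb_rows]
        size = 1.0 / a
        p = size / (size + m)
        out[nb_rows] = rng.negative_binomial(size, p)
    return out


# ---------------------------------------------------------------------------
# Named fixture scenarios

def design_for(params: SimulationParams) -> StudyDesign:
    groups = {}
    for grp, n in params.n_samples_per_group.items():
        for i in range(n):
            groups[f"{grp}_{i + 1}"] = grp
    return StudyDesign(groups=groups)


SCENARIOS = {
    "tiny": dict(
        n_chromosomes=1,
        chrom_length=12_000_000,
        n_coding_genes=32,
        n_lncrna_per_class={c: 2 for c in LNC_CLASSES},
        n_samples_per_group={"SO": 2, "2D": 2, "8D": 2},
        fraction_de=0.2,
    ),
    "default": dict(),
    "null": dict(fraction_de=0.0, concordant_fraction=0.0),
}


def scenario_params(name: str, seed: int = 0) -> SimulationParams:
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    params = SimulationParams(seed=seed, **SCENARIOS[name])
    if name == "null":
        # no planted effects at all: clear the lncRNA pairing channel too
        params.intergenic_proximal_fraction = 0.5
    return params


def simulate_scenario(name: str, seed: int = 0):
    """Convenience: annotation, design, counts and truth for a named scenario."""
    params = scenario_params(name, seed)
    annotation, truth = simulate_annotation(params)
    design = design_for(params)
    if name == "null":
        truth.group_effects = {}
        truth.pair_concordant = {}
    counts, truth = simulate_counts(annotation, design, params, truth)
    if name == "null":
        truth.group_effects = {}
        truth.pair_concordant = {}
    return annotation, design, counts, truth, params


def make_fixture(name: str, out_dir, seed: int = 0) -> Path:
    """Write a self-contained fixture directory: GTF, counts TSV, design
    TSV and planted-truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation, design, counts, truth, _params = simulate_scenario(name, seed)
    write_gtf(annotation, out / "annotation.gtf")
    write_counts_tsv(counts, out / "counts.tsv")
    write_design_tsv(design, out / "design.tsv")
    truth.genes_frame().to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    truth.lnc_frame().to_csv(out / "truth_lncrna.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"sample": list(truth.size_factors),
         "size_factor": list(truth.size_factors.values())}
    ).to_csv(out / "truth_size_factors.tsv", sep="\t", index=False)
    return out
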