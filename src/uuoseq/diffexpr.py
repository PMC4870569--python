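"""Per-gene negative-binomial differential testing across group contrasts.

For each contrast (reference, test) and each gene the module estimates a
moment-based NB dispersion from the two groups, forms the log2 fold change
of pseudocount-offset normalized group means, and tests equality of means
with a two-sided Wald statistic on the log scale whose variance comes from
the NB model (Var = mu + alpha mu^2) by the delta method.  P-values are
Benjamini-Hochberg adjusted within each contrast.

The Wald statistic is referred to a Student t distribution with
``n_ref + n_test - 2`` degrees of freedom rather than a normal: the
variance entering the statistic is itself estimated from very few
replicates, and the t reference keeps the test calibrated at the group
sizes bulk designs actually have (3-5 per group).

Genes are then categorized the way volcano plots are drawn: ``up`` /
``down`` when significant and past the absolute log2 fold-change cutoff,
``significant_subthreshold`` when significant but inside the cutoff, and
``not_significant`` otherwise.  Significance for DE-list membership uses
the raw p-value gate; heatmap-style selection uses the FDR gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CountMatrix, PipelineConfig, StudyDesign, ValidationError
from .quantify import NormalizedCounts

DISPERSION_FLOOR = 1e-8

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_SUB = "significant_subthreshold"
STATUS_NS = "not_significant"


def estimate_dispersion(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Method-of-moments NB dispersion from within-group residuals.

    alpha = max(floor, (pooled within-group variance - pooled mean) /
    pooled mean^2), with the pooled mean over all samples of both groups.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 samples per group to estimate dispersion")
    pooled_mean = np.concatenate([a, b]).mean()
    if pooled_mean <= 0:
        return DISPERSION_FLOOR
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    var_within = ss / (a.size + b.size - 2)
    alpha = (var_within - pooled_mean) / pooled_mean**2
    return max(DISPERSION_FLOOR, float(alpha))


def test_gene(group_a: np.ndarray, group_b: np.ndarray, alpha: float,
              config: PipelineConfig) -> tuple[float, float]:
    """Wald test of equal NB means for one gene; inputs are normalized
    counts (reference group first).  Returns (log2fc, p).

    The statistic is the log mean ratio over its delta-method standard
    error under Var = mu + alpha mu^2, referred to t with
    ``n_a + n_b - 2`` degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    pc = config.pseudocount
    mu_a, mu_b = a.mean(), b.mean()
    log2fc = float(np.log2((mu_b + pc) / (mu_a + pc)))
    var_a = mu_a + alpha * mu_a**2
    var_b = mu_b + alpha * mu_b**2
    se2 = var_a / (a.size * (mu_a + pc) ** 2) + var_b / (b.size * (mu_b + pc) ** 2)
    if se2 <= 0:
        return log2fc, 1.0
    z = np.log((mu_b + pc) / (mu_a + pc)) / np.sqrt(se2)
    p = float(2.0 * stats.t.sf(abs(z), a.size + b.size - 2))
    return log2fc, float(min(max(p, np.nextafter(0, 1)), 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_status(log2fc: float, p: float, fdr: float,
                    config: PipelineConfig, gate: str = "p") -> str:
    """Volcano-style category for one gene.

    ``gate`` selects the significance criterion: ``"p"`` (raw p-value,
    DE-list membership) or ``"fdr"`` (adjusted, heatmap selection).
    Boundary |log2fc| == cutoff counts as up/down.
    """
    if gate == "p":
        significant = p < config.p_threshold
    elif gate == "fdr":
        significant = fdr < config.fdr_threshold
    else:
        raise ValueError(f"gate must be 'p' or 'fdr', got {gate!r}")
    if not significant:
        return STATUS_NS
    if log2fc >= config.log2fc_cutoff:
        return STATUS_UP
    if log2fc <= -config.log2fc_cutoff:
        return STATUS_DOWN
    return STATUS_SUB


def run_contrast(normalized: NormalizedCounts, design: StudyDesign,
                 contrast: tuple[str, str], config: PipelineConfig,
                 gate: str = "p") -> pd.DataFrame:
    """DE table for one contrast over all genes in ``normalized``.

    Columns: gene_id, base_mean_ref, base_mean_test, log2fc, dispersion,
    p, fdr, status.  Deterministic given its inputs.
    """
    ref, test = contrast
    sample_idx = {s: j for j, s in enumerate(normalized.sample_ids)}
    idx_a = [sample_idx[s] for s in design.samples_in(ref) if s in sample_idx]
    idx_b = [sample_idx[s] for s in design.samples_in(test) if s in sample_idx]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValidationError(
            f"contrast {ref} vs {test}: need >= 2 samples per group"
        )
    mat = normalized.normalized
    a = mat[:, idx_a]
    b = mat[:, idx_b]
    n_a, n_b = a.shape[1], b.shape[1]

    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)
    pooled_mean = np.concatenate([a, b], axis=1).mean(axis=1)
    ss = ((a - mu_a[:, None]) ** 2).sum(axis=1) + ((b - mu_b[:, None]) ** 2).sum(axis=1)
    var_within = ss / (n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(
            pooled_mean > 0,
            (var_within - pooled_mean) / np.where(pooled_mean > 0, pooled_mean, 1.0) ** 2,
            DISPERSION_FLOOR,
        )
    alpha = np.maximum(DISPERSION_FLOOR, alpha)

    pc = config.pseudocount
    log2fc = np.log2((mu_b + pc) / (mu_a + pc))
    var_model_a = mu_a + alpha * mu_a**2
    var_model_b = mu_b + alpha * mu_b**2
    se2 = var_model_a / (n_a * (mu_a + pc) ** 2) + var_model_b / (n_b * (mu_b + pc) ** 2)
    lnfc = np.log((mu_b + pc) / (mu_a + pc))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se2 > 0, lnfc / np.sqrt(np.where(se2 > 0, se2, 1.0)), 0.0)
    p = 2.0 * stats.t.sf(np.abs(z), n_a + n_b - 2)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    p[se2 <= 0] = 1.0
    fdr = bh_adjust(p)

    status = [
        classify_status(fc, pv, fd, config, gate=gate)
        for fc, pv, fd in zip(log2fc, p, fdr)
    ]
    return pd.DataFrame(
        {
            "gene_id": normalized.gene_ids,
            "base_mean_ref": mu_a,
            "base_mean_test": mu_b,
            "log2fc": log2fc,
            "dispersion": alpha,
            "p": p,
            "fdr": fdr,
            "status": status,
        }
    )


def run_contrasts(normalized: NormalizedCounts, design: StudyDesign,
                  config: PipelineConfig, gate: str = "p"
                  ) -> dict[str, pd.DataFrame]:
    """One DE table per contrast of the design, keyed by contrast id."""
    return {
        design.contrast_id(c): run_contrast(normalized, design, c, config, gate=gate)
        for c in design.contrasts
    }


def de_gene_set(table: pd.DataFrame, direction: str = "all") -> set:
    """Gene ids in a DE list: up, down, or all genes past the cutoff."""
    if direction == "up":
        mask = table["status"] == STATUS_UP
    elif direction == "down":
        mask = table["status"] == STATUS_DOWN
    elif direction == "all":
        mask = table["status"].isin([STATUS_UP, STATUS_DOWN])
    elif direction == "significant":
        mask = table["status"] != STATUS_NS
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return set(table.loc[mask, "gene_id"])


@dataclass
class VennPartition:
    """Exact two-set partition for Venn display."""

    only_a: set
    only_b: set
    both: set

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.only_a), len(self.both), len(self.only_b)


def venn(set_a, set_b) -> VennPartition:
    a, b = set(set_a), set(set_b)
    return VennPartition(only_a=a - b, only_b=b - a, both=a & b)
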