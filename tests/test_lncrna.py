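import numpy as np
import pandas as pd
import pytest

from uuoseq.lncrna import (
    CONCORDANT_NONE,
    CONCORDANT_OPPOSITE,
    CONCORDANT_SIMILAR,
    build_contexts,
    class_distribution,
    classify_lncrna,
    concordance,
    find_neighbors,
    select_candidates,
)
from uuoseq.model import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    PipelineConfig,
    ValidationError,
)
from uuoseq.simulate import scenario_params, simulate_annotation

from .oracles import classify_oracle, neighbors_oracle


def gene(gid, chrom, start, end, strand, biotype="protein_coding", exons=None):
    if exons is None:
        exons = [GenomicInterval(chrom, start, end, strand)]
    return GeneModel(gid, gid, biotype, exons)


def annotation_of(*genes, chrom_len=10_000_000):
    return GenomeAnnotation(chromosomes={"chr1": chrom_len},
                            genes={g.gene_id: g for g in genes})


class TestClassification:
    def test_intronic_definition_instance(self, config):
        coding = gene("pc", "chr1", 0, 3500, "+", exons=[
            GenomicInterval("chr1", 0, 500, "+"),
            GenomicInterval("chr1", 3000, 3500, "+"),
        ])
        lnc = gene("lnc", "chr1", 1000, 2000, "+", biotype="lncRNA")
        ann = annotation_of(coding, lnc)
        assert classify_lncrna(lnc, ann, config) == "intronic"

    def test_antisense_definition_instance(self, config):
        coding = gene("pc", "chr1", 1000, 5000, "+")
        lnc = gene("lnc", "chr1", 1500, 2500, "-", biotype="lncRNA")
        ann = annotation_of(coding, lnc)
        assert classify_lncrna(lnc, ann, config) == "antisense"

    def test_antisense_beats_intronic_precedence(self, config):
        """A lncRNA inside a same-strand intron that also overlaps an
        opposite-strand coding gene is antisense."""
        host = gene("pc1", "chr1", 0, 10_000, "+", exons=[
            GenomicInterval("chr1", 0, 500, "+"),
            GenomicInterval("chr1", 9500, 10_000, "+"),
        ])
        other = gene("pc2", "chr1", 1000, 2000, "-")
        lnc = gene("lnc", "chr1", 1500, 2500, "+", biotype="lncRNA")
        ann = annotation_of(host, other, lnc)
        assert classify_lncrna(lnc, ann, config) == "antisense"

    def test_bidirectional_divergent_promoter(self, config):
        coding = gene("pc", "chr1", 10_000, 15_000, "+")
        lnc = gene("lnc", "chr1", 8_000, 9_500, "-", biotype="lncRNA")
        ann = annotation_of(coding, lnc)
        # TSS distance 10_000 - 9_499 = 501 <= 1000, divergent
        assert classify_lncrna(lnc, ann, config) == "bidirectional"

    def test_convergent_pair_is_not_bidirectional(self, config):
        coding = gene("pc", "chr1", 10_000, 15_000, "+")
        lnc = gene("lnc", "chr1", 15_200, 16_000, "-", biotype="lncRNA")
        ann = annotation_of(coding, lnc)
        assert classify_lncrna(lnc, ann, config) == "intergenic"

    def test_non_lncrna_rejected(self, config):
        coding = gene("pc", "chr1", 0, 1000, "+")
        ann = annotation_of(coding)
        with pytest.raises(ValidationError):
            classify_lncrna(coding, ann, config)

    def test_random_placements_match_brute_force(self, config):
        """500 random lncRNA placements against a synthetic coding genome:
        the indexed classifier equals the all-pairs oracle."""
        params = scenario_params("tiny", seed=9)
        params.n_coding_genes = 60
        params.chrom_length = 30_000_000
        params.n_lncrna_per_class = {}
        annotation, _ = simulate_annotation(params)
        coding = annotation.coding_genes()
        rng = np.random.default_rng(10)
        genes = dict(annotation.genes)
        lncs = []
        for i in range(500):
            start = int(rng.integers(0, params.chrom_length - 3000))
            length = int(rng.integers(200, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            lnc = gene(f"L{i}", "chr1", start, start + length, strand,
                       biotype="lncRNA")
            genes[lnc.gene_id] = lnc
            lncs.append(lnc)
        ann = GenomeAnnotation(
            chromosomes={"chr1": params.chrom_length}, genes=genes)
        mismatches = []
        for lnc in lncs:
            got = classify_lncrna(lnc, ann, config)
            want = classify_oracle(lnc, coding, config.bidirectional_tss_window)
            if got != want:
                mismatches.append((lnc.gene_id, got, want))
        assert mismatches == []

    def test_every_lncrna_gets_exactly_one_class(self, default_scenario, config):
        annotation = default_scenario[0]
        contexts = build_contexts(annotation, config)
        dist = class_distribution(contexts)
        assert dist.sum() == len(annotation.lncrna_genes())


class TestNeighbors:
    def test_inclusion_and_exclusion_at_window(self, config):
        near = gene("near", "chr1", 0, 10_000, "+")
        far = gene("far", "chr1", 300_000, 310_000, "+")
        lnc = gene("lnc", "chr1", 60_000, 61_000, "+", biotype="lncRNA")
        ann = annotation_of(near, far, lnc)
        hits = find_neighbors(lnc, ann, window=config.neighbor_window)
        assert [n.gene_id for n in hits] == ["near"]
        assert hits[0].distance == 50_000
        assert hits[0].side == "upstream"
        assert hits[0].signed_distance == -50_000

    def test_signed_distance_respects_strand(self, config):
        near = gene("near", "chr1", 0, 10_000, "+")
        lnc = gene("lnc", "chr1", 60_000, 61_000, "-", biotype="lncRNA")
        ann = annotation_of(near, lnc)
        hit = find_neighbors(lnc, ann, window=config.neighbor_window)[0]
        # genomically left, but downstream in the minus-strand orientation
        assert hit.side == "downstream"
        assert hit.signed_distance == 50_000

    def test_random_annotation_matches_all_pairs_scan(self, config):
        params = scenario_params("tiny", seed=12)
        params.n_coding_genes = 40
        params.chrom_length = 20_000_000
        annotation, _ = simulate_annotation(params)
        coding = annotation.coding_genes()
        rng = np.random.default_rng(13)
        for i in range(100):
            start = int(rng.integers(0, params.chrom_length - 2000))
            lnc = gene(f"L{i}", "chr1", start, start + 1000,
                       "+" if rng.random() < 0.5 else "-", biotype="lncRNA")
            got = [(n.gene_id, n.distance)
                   for n in find_neighbors(lnc, annotation,
                                           window=config.neighbor_window)]
            assert got == neighbors_oracle(lnc, coding, config.neighbor_window)

    def test_window_monotonicity(self, default_scenario, config):
        annotation = default_scenario[0]
        for lnc in annotation.lncrna_genes()[:10]:
            small = {n.gene_id for n in find_neighbors(lnc, annotation, window=20_000)}
            large = {n.gene_id for n in find_neighbors(lnc, annotation, window=100_000)}
            assert small <= large


def de_row(log2fc, p):
    return pd.Series({"log2fc": log2fc, "p": p})


class TestConcordance:
    def test_both_up_is_similar(self, config):
        assert concordance(de_row(2.0, 0.001), de_row(1.2, 0.01),
                           config) == CONCORDANT_SIMILAR

    def test_down_vs_up_is_opposite(self, config):
        assert concordance(de_row(-1.5, 0.001), de_row(2.0, 0.02),
                           config) == CONCORDANT_OPPOSITE

    def test_non_significant_neighbor_is_none(self, config):
        assert concordance(de_row(2.0, 0.001), de_row(1.5, 0.4),
                           config) == CONCORDANT_NONE

    def test_zero_fold_change_is_none(self, config):
        assert concordance(de_row(0.0, 0.001), de_row(1.5, 0.01),
                           config) == CONCORDANT_NONE


class TestCandidates:
    def _tables(self, ids, log2fc, p, status):
        return {"SO_vs_2D": pd.DataFrame(
            {"gene_id": ids, "log2fc": log2fc, "p": p,
             "fdr": p, "status": status})}

    def test_proximity_cutoff_is_strict(self, config):
        for dist, expected in ((2999, 1), (3000, 0)):
            coding = gene("pc", "chr1", 0, 10_000, "+")
            lnc = gene("lnc", "chr1", 10_000 + dist, 12_000 + dist, "+",
                       biotype="lncRNA")
            ann = annotation_of(coding, lnc)
            tables = self._tables(["pc", "lnc"], [1.0, 2.0], [0.001, 0.001],
                                  ["up", "up"])
            contexts = build_contexts(ann, config, tables)
            cands = select_candidates(contexts, tables, config)
            assert len(cands) == expected, f"distance {dist}"

    def test_non_de_lncrna_never_candidate(self, config):
        coding = gene("pc", "chr1", 0, 10_000, "+")
        lnc = gene("lnc", "chr1", 10_100, 12_000, "+", biotype="lncRNA")
        ann = annotation_of(coding, lnc)
        tables = self._tables(["pc", "lnc"], [1.0, 0.1], [0.001, 0.9],
                              ["up", "not_significant"])
        contexts = build_contexts(ann, config, tables)
        assert select_candidates(contexts, tables, config) == []

    def test_default_fixture_candidates_match_truth_scan(
            self, default_scenario, config):
        """End-to-end: mechanical candidate selection equals a brute-force
        filter over the planted truth and DE tables."""
        from uuoseq.diffexpr import run_contrasts
        from uuoseq.quantify import normalize_and_filter

        annotation, design, counts, truth, params = default_scenario
        normalized, report = normalize_and_filter(counts, annotation, config)
        surv = normalized.subset_genes(report.surviving)
        de_tables = run_contrasts(surv, design, config)
        contexts = build_contexts(annotation, config, de_tables)
        cands = select_candidates(contexts, de_tables, config)
        got = {c.lncrna_id for c in cands}

        expected = set()
        for lnc in annotation.lncrna_genes():
            hits = neighbors_oracle(lnc, annotation.coding_genes(),
                                    config.neighbor_window)
            if not hits or min(d for _, d in hits) >= config.proximity_cutoff:
                continue
            for table in de_tables.values():
                row = table[table["gene_id"] == lnc.gene_id]
                if len(row) and row.iloc[0]["status"] in ("up", "down"):
                    expected.add(lnc.gene_id)
                    break
        assert got == expected
        assert len(got) > 0

    def test_concordance_labels_on_planted_pairs(self, default_scenario, config):
        """Planted concordant pairs that come out significant on both sides
        are labelled similar (and opposite pairs opposite)."""
        from uuoseq.diffexpr import run_contrasts
        from uuoseq.quantify import normalize_and_filter

        annotation, design, counts, truth, params = default_scenario
        normalized, report = normalize_and_filter(counts, annotation, config)
        surv = normalized.subset_genes(report.surviving)
        de_tables = run_contrasts(surv, design, config)
        contexts = build_contexts(annotation, config, de_tables)
        checked = 0
        for cid in ("SO_vs_2D", "SO_vs_8D"):
            table = de_tables[cid].set_index("gene_id")
            for lnc_id, host in truth.lnc_neighbor.items():
                if truth.pair_concordant.get(lnc_id) is None:
                    continue
                if lnc_id not in table.index or host not in table.index:
                    continue
                lnc_row, host_row = table.loc[lnc_id], table.loc[host]
                if (lnc_row["p"] >= config.p_threshold
                        or host_row["p"] >= config.p_threshold):
                    continue
                label = contexts[lnc_id].concordance[cid].get(host)
                expected = (CONCORDANT_SIMILAR if truth.pair_concordant[lnc_id]
                            else CONCORDANT_OPPOSITE)
                assert label == expected, (lnc_id, host, cid)
                checked += 1
        assert checked >= 10
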