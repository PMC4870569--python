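import numpy as np
import pytest

from uuoseq.model import (
    CountMatrix,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    PipelineConfig,
    ValidationError,
)
from uuoseq.quantify import (
    compute_rpkm,
    count_detected_genes,
    drop_zero_rows,
    estimate_mate_inner_dist,
    filter_genes,
    normalize_and_filter,
    size_factors_median_of_ratios,
)
from uuoseq.simulate import scenario_params, simulate_annotation, simulate_counts, design_for

from .oracles import filter_oracle


def annotation_with_lengths(lengths, chrom_len=10_000_000):
    genes = {}
    pos = 0
    for i, length in enumerate(lengths):
        gid = f"g{i}"
        genes[gid] = GeneModel(
            gid, gid, "protein_coding",
            [GenomicInterval("chr1", pos, pos + length, "+")])
        pos += length + 1000
    return GenomeAnnotation(chromosomes={"chr1": chrom_len}, genes=genes)


class TestRpkm:
    def test_closed_form(self):
        ann = annotation_with_lengths([2000, 1000])
        counts = CountMatrix(["g0", "g1"], ["s"], [[1000], [10_000_000 - 1000]])
        rpkm = compute_rpkm(counts, ann)
        # count 1000, length 2 kb, library 10^7 -> 50
        assert rpkm.loc["g0", "s"] == pytest.approx(50.0)

    def test_zero_count_gives_zero(self):
        ann = annotation_with_lengths([500, 500])
        counts = CountMatrix(["g0", "g1"], ["s"], [[0], [100]])
        assert compute_rpkm(counts, ann).loc["g0", "s"] == 0.0

    def test_scale_invariance_per_sample(self):
        rng = np.random.default_rng(1)
        ann = annotation_with_lengths(list(rng.integers(200, 5000, size=30)))
        base = rng.integers(0, 500, size=(30, 3))
        base[0, :] = 1  # keep library sizes positive
        doubled = base.copy()
        doubled[:, 1] *= 2
        ids = [f"g{i}" for i in range(30)]
        r1 = compute_rpkm(CountMatrix(ids, list("abc"), base), ann)
        r2 = compute_rpkm(CountMatrix(ids, list("abc"), doubled), ann)
        np.testing.assert_allclose(r1["b"], r2["b"])

    def test_missing_gene_and_zero_library_errors(self):
        ann = annotation_with_lengths([500])
        with pytest.raises(ValidationError):
            compute_rpkm(CountMatrix(["zz"], ["s"], [[1]]), ann)
        with pytest.raises(ValidationError):
            compute_rpkm(CountMatrix(["g0"], ["s"], [[0]]), ann)


class TestDetectedGenes:
    def test_examples(self, tiny_scenario, config):
        annotation, design, counts, *_ = tiny_scenario
        rpkm = compute_rpkm(counts, annotation)
        per_sample, per_group = count_detected_genes(rpkm, design, 0.0)
        # independent tally
        for s in counts.sample_ids:
            assert per_sample[s] == int((rpkm[s] > 0).sum())
        for grp in design.group_names():
            members = design.samples_in(grp)
            assert per_group[grp] == pytest.approx(
                np.mean([per_sample[s] for s in members]))

    def test_zero_sample_detects_nothing(self):
        ann = annotation_with_lengths([500, 600])
        counts = CountMatrix(["g0", "g1"], ["a", "b"], [[0, 5], [0, 3]])
        rpkm = compute_rpkm(
            CountMatrix(["g0", "g1"], ["b"], [[5], [3]]), ann)
        assert (rpkm > 0).sum().sum() == 2


class TestDropZeroRows:
    def test_examples_and_set_oracle(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 3, size=(50, 4))
        mat[3, :] = 0
        ids = [f"g{i}" for i in range(50)]
        cm = CountMatrix(ids, list("wxyz"), mat)
        kept, dropped = drop_zero_rows(cm)
        expected = {g for g, row in zip(ids, mat) if row.sum() > 0}
        assert set(kept.gene_ids) == expected
        assert set(dropped) == set(ids) - expected
        # order preserved
        assert kept.gene_ids == [g for g in ids if g in expected]


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        mat = np.tile([[10], [20], [30]], (1, 4))
        cm = CountMatrix(["a", "b", "c"], list("wxyz"), mat)
        nc = size_factors_median_of_ratios(cm)
        np.testing.assert_allclose(nc.size_factors, 1.0)

    def test_doubled_sample_hand_oracle(self):
        """5-gene table, sample B = 2 x sample A: s_B/s_A = 2 and the
        factors match a hand-computed median of ratios."""
        a = np.array([10, 20, 30, 40, 50])
        cm = CountMatrix([f"g{i}" for i in range(5)], ["A", "B"],
                         np.column_stack([a, 2 * a]))
        nc = size_factors_median_of_ratios(cm)
        # reference = geometric mean of (x, 2x) = x*sqrt(2);
        # ratios: A -> 1/sqrt(2), B -> sqrt(2) for every gene
        np.testing.assert_allclose(
            nc.size_factors, [1 / np.sqrt(2), np.sqrt(2)])
        assert nc.size_factors[1] / nc.size_factors[0] == pytest.approx(2.0)

    def test_normalization_exactness(self, tiny_scenario):
        counts = tiny_scenario[2]
        kept, _ = drop_zero_rows(counts)
        nc = size_factors_median_of_ratios(kept)
        reconstructed = nc.normalized * nc.size_factors[None, :]
        np.testing.assert_allclose(reconstructed, kept.counts.astype(float))

    def test_permutation_equivariance(self, tiny_scenario):
        counts = tiny_scenario[2]
        kept, _ = drop_zero_rows(counts)
        nc = size_factors_median_of_ratios(kept)
        perm = list(reversed(range(len(kept.sample_ids))))
        shuffled = CountMatrix(kept.gene_ids,
                               [kept.sample_ids[j] for j in perm],
                               kept.counts[:, perm])
        nc2 = size_factors_median_of_ratios(shuffled)
        np.testing.assert_allclose(nc2.size_factors, nc.size_factors[perm])

    def test_no_always_positive_gene_errors(self):
        cm = CountMatrix(["a", "b"], ["x", "y"], [[0, 5], [5, 0]])
        with pytest.raises(ValidationError):
            size_factors_median_of_ratios(cm)

    def test_recovers_planted_size_factors(self):
        """Median over 20 replicate simulations of the per-sample relative
        error (after matching the scale convention) stays below 5%."""
        params = scenario_params("default", seed=0)
        annotation, truth0 = simulate_annotation(params)
        design = design_for(params)
        errors = []
        for rep in range(20):
            p = scenario_params("default", seed=100 + rep)
            counts, truth = simulate_counts(annotation, design, p)
            kept, _ = drop_zero_rows(counts)
            nc = size_factors_median_of_ratios(kept)
            est = nc.size_factors / np.exp(np.log(nc.size_factors).mean())
            true = np.array([truth.size_factors[s] for s in kept.sample_ids])
            true = true / np.exp(np.log(true).mean())
            errors.append(np.abs(est - true) / true)
        median_err = np.median(np.array(errors), axis=0)
        assert (median_err < 0.05).all()

    def test_pydeseq2_agrees_on_small_fixture(self):
        """Independent cross-check against DESeq2's median-of-ratios as
        implemented in pydeseq2, on a no-zero fixture.

        An odd number of genes is used so the plain ratio median and
        pydeseq2's log-space median pick the same element.
        """
        pydeseq2_prep = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(3)
        mat = rng.integers(1, 500, size=(61, 5))
        cm = CountMatrix([f"g{i}" for i in range(61)], list("abcde"), mat)
        nc = size_factors_median_of_ratios(cm)
        _, sf = pydeseq2_prep.deseq2_norm(mat.T.astype(float))
        np.testing.assert_allclose(nc.size_factors, sf, rtol=1e-10)


class TestFilterCascade:
    def test_length_rule_is_strict(self, config):
        ann = annotation_with_lengths([499, 500, 600])
        mat = np.full((3, 4), 50)
        cm = CountMatrix(["g0", "g1", "g2"], list("wxyz"), mat)
        nc = size_factors_median_of_ratios(cm)
        report = filter_genes(nc, ann, config)
        assert report.removed_by_length == ["g0"]
        assert "g1" in report.surviving

    def test_uniform_matrix_rules_ii_iii_remove_nothing(self, config):
        ann = annotation_with_lengths([600] * 8)
        mat = np.full((8, 3), 40)
        cm = CountMatrix([f"g{i}" for i in range(8)], list("abc"), mat)
        nc = size_factors_median_of_ratios(cm)
        report = filter_genes(nc, ann, config)
        assert report.removed_by_low_density == []
        assert report.removed_by_median == []
        assert len(report.surviving) == 8

    def test_report_counts_add_up_and_removals_disjoint(self, default_scenario, config):
        annotation, design, counts, *_ = default_scenario
        normalized, report = normalize_and_filter(counts, annotation, config)
        report.check()
        all_sets = [set(report.removed_by_zero_rows),
                    set(report.removed_by_length),
                    set(report.removed_by_low_density),
                    set(report.removed_by_median),
                    set(report.surviving)]
        union = set().union(*all_sets)
        assert len(union) == sum(len(s) for s in all_sets)
        assert set(report.surviving) <= set(counts.gene_ids)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed, config):
        rng = np.random.default_rng(seed)
        n = 300
        lengths = rng.integers(200, 4000, size=n)
        ann = annotation_with_lengths(list(lengths), chrom_len=10**9)
        mat = rng.negative_binomial(2, 0.01, size=(n, 5))
        cm = CountMatrix([f"g{i}" for i in range(n)], list("abcde"), mat)
        kept, dropped = drop_zero_rows(cm)
        nc = size_factors_median_of_ratios(kept)
        report = filter_genes(nc, ann, config, already_dropped=dropped)
        kept_lengths = [ann[g].exon_union_length for g in kept.gene_ids]
        mask = filter_oracle(nc.normalized, kept_lengths,
                             config.min_gene_length, config.lowcount_quantile,
                             config.apply_median_filter)
        expected = {g for g, m in zip(kept.gene_ids, mask) if m}
        assert set(report.surviving) == expected


class TestInsertSize:
    @pytest.mark.parametrize(
        "fragment,read,expected",
        [(300, 100, 100), (300, 150, 0), (180, 100, -20)],
    )
    def test_inner_distance_formula(self, fragment, read, expected):
        inner, sd = estimate_mate_inner_dist(fragment, 25.0, read)
        assert inner == expected
        assert sd == 25.0
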