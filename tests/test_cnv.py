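import numpy as np
import pandas as pd
import pytest
from scipy.stats import ranksums, spearmanr

from sctnbc.cnv import (
    CenteredExpression,
    reference_normalize,
    infer_cnv_profiles,
    call_cnv_subclones,
    cnv_burden,
    correlation_map,
)
from sctnbc.synthetic import CNVSpec, SimulationConfig, generate_tumor_dataset, generate_normal_reference
from sctnbc.types import SCTNBCError, ExpressionMatrix, log2_tpm1


def make_centered(values, gene_ids=None, scaled_mean=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{j}" for j in range(values.shape[1])]
    return CenteredExpression(
        values=values,
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
        gene_ids=gene_ids,
        scaled_mean=scaled_mean if scaled_mean is not None else np.ones(values.shape[1]),
        n_shared_genes=values.shape[1],
    )


class TestReferenceNormalize:
    def test_cell_equal_to_reference_mean_is_zero(self, make_expr):
        ref = make_expr([[100.0, 200.0, 50.0]] * 3)
        tumor = make_expr([[100.0, 200.0, 50.0]])
        cen = reference_normalize(tumor, ref)
        np.testing.assert_allclose(cen.values, 0.0, atol=1e-12)

    def test_toy_matches_hand_computation(self, make_expr):
        rng = np.random.default_rng(0)
        tum_vals = rng.uniform(0, 500, (2, 5))
        ref_vals = rng.uniform(0, 500, (3, 5))
        tumor, ref = make_expr(tum_vals), make_expr(ref_vals)
        cen = reference_normalize(tumor, ref)
        expected = np.log2(tum_vals + 1) / 10 - (np.log2(ref_vals + 1) / 10).mean(axis=0)
        np.testing.assert_allclose(cen.values, expected)
        np.testing.assert_allclose(cen.scaled_mean, (np.log2(tum_vals + 1) / 10).mean(axis=0))

    def test_disjoint_panels_error(self, make_expr):
        tumor = make_expr([[1.0]], gene_ids=["a"])
        ref = make_expr([[1.0], [2.0]], gene_ids=["b"])
        with pytest.raises(SCTNBCError, match="no genes"):
            reference_normalize(tumor, ref)

    def test_intersection_only(self, make_expr):
        tumor = make_expr([[1.0, 2.0]], gene_ids=["a", "b"])
        ref = make_expr([[5.0, 6.0], [7.0, 8.0]], gene_ids=["b", "c"])
        cen = reference_normalize(tumor, ref)
        assert cen.gene_ids == ["b"]
        assert cen.n_shared_genes == 1


def brute_force_moving_average(clipped, window, chrom_of):
    """Enumeration oracle: truncated window average per chromosome."""
    n_cells, n_genes = clipped.shape
    half = window // 2
    out = np.empty_like(clipped)
    for g in range(n_genes):
        members = [
            j
            for j in range(n_genes)
            if chrom_of[j] == chrom_of[g] and abs(j - g) <= half
        ]
        out[:, g] = clipped[:, members].mean(axis=1)
    return out


class TestInferCNVProfiles:
    def test_all_zero_input(self, single_chrom_genes):
        cen = make_centered(np.zeros((4, 12)))
        cnv = infer_cnv_profiles(cen, single_chrom_genes(12), window=3)
        np.testing.assert_allclose(cnv.values, 0.0)

    def test_12_gene_window3_matches_enumeration(self, single_chrom_genes):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 1, (5, 12))
        cen = make_centered(values)
        cnv = infer_cnv_profiles(cen, single_chrom_genes(12), window=3, clip=3.0)
        clipped = np.clip(values, -3, 3)
        expected = brute_force_moving_average(clipped, 3, ["chr1"] * 12)
        expected -= expected.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(cnv.values, expected, atol=1e-12)

    def test_two_chromosomes_truncate_at_boundary(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 1, (3, 10))
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{j}" for j in range(10)],
                "chromosome": ["chr1"] * 6 + ["chr2"] * 4,
                "start": list(range(1, 7)) + list(range(1, 5)),
                "order_index": range(1, 11),
            }
        )
        cnv = infer_cnv_profiles(make_centered(values), genes, window=5, clip=3.0)
        expected = brute_force_moving_average(
            np.clip(values, -3, 3), 5, ["chr1"] * 6 + ["chr2"] * 4
        )
        expected -= expected.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(cnv.values, expected, atol=1e-12)

    def test_window1_is_identity_before_centering(self, single_chrom_genes):
        rng = np.random.default_rng(9)
        values = rng.normal(0, 2, (4, 8))
        cnv = infer_cnv_profiles(make_centered(values), single_chrom_genes(8), window=1, clip=3.0)
        np.testing.assert_allclose(cnv.smoothed, np.clip(values, -3, 3), atol=1e-12)

    def test_even_window_incremented(self, single_chrom_genes):
        cnv = infer_cnv_profiles(make_centered(np.zeros((3, 12))), single_chrom_genes(12), window=4)
        assert cnv.window == 5

    def test_gene_filter_uses_scaled_mean(self, single_chrom_genes):
        values = np.random.default_rng(1).normal(0, 1, (3, 6))
        scaled_mean = np.array([1.0, 0.05, 1.0, 1.0, 0.01, 1.0])
        cen = make_centered(values, scaled_mean=scaled_mean)
        cnv = infer_cnv_profiles(cen, single_chrom_genes(6), window=1, min_mean=0.1)
        assert cnv.gene_ids == ["g0", "g2", "g3", "g5"]

    def test_small_chromosome_excluded(self):
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{j}" for j in range(6)],
                "chromosome": ["chr1"] * 4 + ["chr2"] * 2,
                "start": [1, 2, 3, 4, 1, 2],
                "order_index": range(1, 7),
            }
        )
        cnv = infer_cnv_profiles(make_centered(np.zeros((3, 6))), genes, window=3)
        assert all(g.startswith("g") and int(g[1]) < 4 for g in cnv.gene_ids)

    def test_per_gene_centering_and_clip_bound(self, single_chrom_genes):
        rng = np.random.default_rng(10)
        values = rng.normal(0, 5, (6, 20))
        cnv = infer_cnv_profiles(make_centered(values), single_chrom_genes(20), window=5, clip=3.0)
        np.testing.assert_allclose(cnv.values.mean(axis=0), 0.0, atol=1e-8)
        assert np.abs(cnv.values).max() <= 2 * 3.0 + 1e-12

    def test_column_permutation_equivariance(self, single_chrom_genes):
        rng = np.random.default_rng(11)
        values = rng.normal(0, 1, (5, 15))
        perm = rng.permutation(5)
        a = infer_cnv_profiles(make_centered(values), single_chrom_genes(15), window=5)
        b = infer_cnv_profiles(make_centered(values[perm]), single_chrom_genes(15), window=5)
        np.testing.assert_allclose(b.values, a.values[perm], atol=1e-12)

    def test_implanted_block_separates_carriers(self):
        # dosage 1.5 over a 150-gene block in 50 of 100 cells
        cfg = SimulationConfig(
            n_patients=1,
            cells_per_patient=100,
            n_genes=1500,
            n_chromosomes=5,
            cell_type_fractions={"epithelial": 1.0},
            marker_genes_per_type=10,
            marker_effect=0.0,
            cycling_fraction=0.0,
            dropout_rate=0.0,
            cnv_specs=[CNVSpec("P1", 0.5, 310, 460, 1.5)],
            seed=21,
        )
        expr, _, genes, truth = generate_tumor_dataset(cfg)
        ref = generate_normal_reference(cfg, n_cells=60, seed=99)
        cen = reference_normalize(expr, ref)
        cnv = infer_cnv_profiles(cen, genes)
        block_genes = [g for g in truth.cnv_blocks[list(truth.cnv_blocks)[0]]["genes"] if g in cnv.gene_ids]
        idx = [cnv.gene_ids.index(g) for g in block_genes]
        block_mean = cnv.values[:, idx].mean(axis=1)
        carrier = truth.cells["cnv_carrier"].to_numpy()
        stat, p = ranksums(block_mean[carrier], block_mean[~carrier])
        assert p < 1e-6 and stat > 0


class TestSubcloneCalls:
    def test_no_reference_error(self, single_chrom_genes):
        cnv = infer_cnv_profiles(make_centered(np.zeros((3, 12))), single_chrom_genes(12), window=3)
        empty = infer_cnv_profiles(make_centered(np.zeros((3, 12))), single_chrom_genes(12), window=3)
        empty.values = empty.values[:0]
        empty.smoothed = empty.smoothed[:0]
        empty.cell_ids = []
        with pytest.raises(SCTNBCError, match="reference"):
            call_cnv_subclones(cnv, empty)

    def test_carrier_implies_subclone_label(self, single_chrom_genes):
        rng = np.random.default_rng(12)
        genes = single_chrom_genes(40)
        tumor = make_centered(rng.normal(0, 0.05, (30, 40)))
        tumor.values[:10, 5:25] += 0.3
        ref = make_centered(rng.normal(0, 0.05, (30, 40)))
        calls = call_cnv_subclones(
            infer_cnv_profiles(tumor, genes, window=5),
            infer_cnv_profiles(ref, genes, window=5),
        )
        df = calls.calls
        assert df.loc[df["carrier"], "subclone"].notna().all()
        assert df.loc[~df["carrier"], "subclone"].isna().all()

    def test_burden_uses_uncentered_values(self, single_chrom_genes):
        # with a 50%-prevalent gain, centering would equalize burdens; the
        # uncentered smoothed values must separate carriers
        rng = np.random.default_rng(13)
        values = rng.normal(0, 0.02, (40, 60))
        values[:20, 10:50] += 0.2
        cnv = infer_cnv_profiles(make_centered(values), single_chrom_genes(60), window=5)
        burden = cnv_burden(cnv)
        assert burden[:20].min() > burden[20:].max()


class TestCorrelationMap:
    def test_self_correlation_and_symmetry(self, make_expr):
        rng = np.random.default_rng(14)
        cm = correlation_map(rng.normal(size=(4, 30)))
        np.testing.assert_allclose(np.diag(cm.matrix.to_numpy()), 1.0)
        np.testing.assert_allclose(cm.matrix.to_numpy(), cm.matrix.to_numpy().T, atol=1e-12)

    def test_rank_identical_cells(self):
        base = np.array([1.0, 5.0, 2.0, 9.0, 3.0])
        values = np.vstack([base, base**3, np.arange(5, dtype=float)])
        cm = correlation_map(values)
        assert cm.matrix.iloc[0, 1] == pytest.approx(1.0)

    def test_four_cell_enumeration_oracle(self):
        rng = np.random.default_rng(15)
        values = rng.normal(size=(4, 12))
        cm = correlation_map(values)
        for i in range(4):
            for j in range(4):
                rho = spearmanr(values[i], values[j]).statistic
                assert cm.matrix.iloc[i, j] == pytest.approx(rho, abs=1e-12)

    def test_constant_profile_excluded(self):
        values = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0)[::-1]])
        cm = correlation_map(values, cell_ids=["flat", "up", "down"])
        assert cm.excluded_cells == ["flat"]
        assert list(cm.matrix.index) == ["up", "down"]

    def test_group_means(self):
        rng = np.random.default_rng(16)
        shared = rng.normal(size=20)
        values = np.vstack(
            [shared + rng.normal(0, 0.1, 20) for _ in range(3)]
            + [rng.normal(size=20) for _ in range(3)]
        )
        ids = [f"c{i}" for i in range(6)]
        labels = pd.Series(["clonal"] * 3 + ["other"] * 3, index=ids)
        cm = correlation_map(values, cell_ids=ids, group_labels=labels)
        assert cm.group_means["clonal"] > cm.group_means["other"]

    def test_clonal_concordance_exceeds_nonclonal(self):
        # within-group correlation ordering: implanted clone > heterogeneous pool
        rng = np.random.default_rng(17)
        n_genes = 300
        clone_shift = np.zeros(n_genes)
        clone_shift[50:150] = 1.5
        clonal = rng.normal(clone_shift, 1.0, (15, n_genes))
        hetero = np.vstack(
            [rng.normal(rng.normal(0, 1.0, n_genes), 1.0, (1, n_genes)) for _ in range(15)]
        )
        values = np.vstack([clonal, hetero])
        ids = [f"c{i}" for i in range(30)]
        labels = pd.Series(["clonal"] * 15 + ["nonclonal"] * 15, index=ids)
        cm = correlation_map(values, cell_ids=ids, group_labels=labels)
        assert cm.group_means["clonal"] > cm.group_means["nonclonal"]


class TestDetectionPowerMonotone:
    @staticmethod
    def _recall(dosage, block_len, seed):
        rng = np.random.default_rng(seed)
        n_cells, n_genes = 60, 600
        noise = 0.07
        shift = np.log2(dosage) / 10.0
        tumor = rng.normal(0, noise, (n_cells, n_genes))
        carriers = np.zeros(n_cells, dtype=bool)
        carriers[: n_cells // 2] = True
        tumor[carriers, 100 : 100 + block_len] += shift
        ref = rng.normal(0, noise, (n_cells, n_genes))
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{j}" for j in range(n_genes)],
                "chromosome": "chr1",
                "start": np.arange(1, n_genes + 1),
                "order_index": np.arange(1, n_genes + 1),
            }
        )
        calls = call_cnv_subclones(
            infer_cnv_profiles(make_centered(tumor), genes),
            infer_cnv_profiles(make_centered(ref), genes),
        )
        called = calls.calls["carrier"].to_numpy()
        return (called & carriers).sum() / carriers.sum()

    def test_monotone_in_dosage_and_length(self):
        reps = 10
        by_dosage = [
            np.mean([self._recall(d, 100, 100 * r + i) for i, d in [(0, d)] for r in range(reps)])
            for d in (1.2, 1.5, 2.0)
        ]
        assert by_dosage[0] <= by_dosage[1] + 0.05 and by_dosage[1] <= by_dosage[2] + 0.05
        assert by_dosage[2] > by_dosage[0]
        by_length = [
            np.mean([self._recall(1.4, L, 7000 + 100 * r) for r in range(reps)])
            for L in (30, 100, 300)
        ]
        assert by_length[0] <= by_length[1] + 0.05 and by_length[1] <= by_length[2] + 0.05
        assert by_length[2] > by_length[0]
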