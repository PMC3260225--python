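import numpy as np
import pandas as pd
import pytest

from conftest import random_genes
from teoutliers import outlier_detection as od
from teoutliers.model import HomologyGroup
from teoutliers.stats import wilcoxon_rank_sum


def double_sort_oracle(genes):
    """Brute-force nested quintiles: sort, slice into fifths, re-sort, slice."""
    ids = sorted(g.gene_id for g in genes)
    by_gene = {g.gene_id: g for g in genes}
    size_sorted = sorted(ids, key=lambda g: (by_gene[g].length, g))
    assignment = {}
    for i, size_chunk in enumerate(np.array_split(size_sorted, 5), start=1):
        ed_sorted = sorted(size_chunk, key=lambda g: (od.exon_density(by_gene[g]), g))
        for j, cell in enumerate(np.array_split(ed_sorted, 5), start=1):
            for g in cell:
                assignment[g] = (i, j)
    return assignment


def per_cell_sort_oracle(density, strata, q):
    """Independent per-cell full sort for outlier labels."""
    labels = {}
    for _, cell in strata.groupby(["size_bin", "exon_density_bin"]):
        ranked = sorted(cell.index, key=lambda g: (density[g], g))
        k = int(np.ceil(q * len(ranked) - 1e-9))
        for g in ranked:
            labels[g] = "none"
        for g in ranked[:k]:
            labels[g] = "lower"
        for g in ranked[-k:] if k else []:
            labels[g] = "upper"
    return labels


class TestFilter:
    def test_strict_10kb_boundary(self, make_gene):
        at = make_gene(gene_id="at", end=10_000)
        above = make_gene(gene_id="above", end=10_001)
        assert od.filter_genes([at, above]) == [above]

    def test_empty_input(self):
        assert od.filter_genes([]) == []


class TestStratify:
    def test_equal_cells_of_four(self):
        genes = random_genes(np.random.default_rng(0), 100)
        st = od.stratify(genes)
        counts = st.groupby(["size_bin", "exon_density_bin"]).size()
        assert len(counts) == 25 and (counts == 4).all()

    def test_identical_sizes_fall_back_to_id_order(self, make_gene):
        genes = [
            make_gene(gene_id=f"g{i:02d}", start=0, end=20_000, n_exons=1 + i % 3)
            for i in range(25)
        ]
        st = od.stratify(genes)
        # size ties: bins are contiguous blocks of the gene_id sort
        ids = sorted(st.index)
        for b in range(1, 6):
            assert list(st.loc[ids[(b - 1) * 5 : b * 5], "size_bin"]) == [b] * 5

    def test_too_few_genes(self, make_gene):
        with pytest.raises(ValueError, match="at least 25"):
            od.stratify([make_gene(gene_id=f"g{i}") for i in range(24)])

    def test_matches_double_sort_oracle(self):
        genes = random_genes(np.random.default_rng(42), 500)
        st = od.stratify(genes)
        oracle = double_sort_oracle(genes)
        for g in st.index:
            assert (st.loc[g, "size_bin"], st.loc[g, "exon_density_bin"]) == oracle[g]

    def test_exon_density_modes(self, make_gene):
        g = make_gene(end=20_000, exons=((0, 1000), (5000, 6000)))
        assert od.exon_density(g, "count") == pytest.approx(0.1)
        assert od.exon_density(g, "bp") == pytest.approx(0.1)


class TestDetectOutliers:
    @staticmethod
    def _setup(n, seed=0):
        rng = np.random.default_rng(seed)
        genes = random_genes(rng, n)
        st = od.stratify(genes)
        density = {g.gene_id: float(rng.random()) for g in genes}
        return density, st

    def test_counts_per_cell(self):
        density, st = self._setup(500)  # 25 cells of 20
        calls = od.detect_outliers(density, st, q=0.10)
        merged = calls.join(st)
        per_cell = merged.groupby(["size_bin", "exon_density_bin"])["label"]
        for _, labels in per_cell:
            assert (labels == "upper").sum() == 2
            assert (labels == "lower").sum() == 2

    def test_zero_cutoff_degenerate(self):
        density, st = self._setup(100)
        calls = od.detect_outliers(density, st, q=0.0)
        assert (calls["label"] == "none").all()

    def test_cell_too_small_for_both_tails(self):
        density, st = self._setup(25)  # cells of 1
        with pytest.raises(ValueError, match="too small"):
            od.detect_outliers(density, st, q=0.5)

    def test_matches_per_cell_sort_oracle(self):
        for seed in range(5):
            density, st = self._setup(500, seed)
            calls = od.detect_outliers(density, st, q=0.10)
            oracle = per_cell_sort_oracle(density, st, 0.10)
            assert calls["label"].to_dict() == oracle

    def test_deterministic(self):
        density, st = self._setup(200)
        a = od.detect_outliers(density, st)
        b = od.detect_outliers(density, st)
        pd.testing.assert_frame_equal(a, b)

    def test_outlier_fraction_near_q(self):
        density, st = self._setup(1000)
        calls = od.detect_outliers(density, st, q=0.10)
        for side in ("upper", "lower"):
            frac = (calls["label"] == side).mean()
            assert frac == pytest.approx(0.10, abs=0.01)

    def test_normalization_removes_size_and_exon_density_bias(self):
        """Upper and lower outlier sets should not differ in the confounders."""
        rng = np.random.default_rng(7)
        genes = random_genes(rng, 1000)
        st = od.stratify(genes)
        sizes = st["size"]
        # density strongly driven by gene size: unstratified calls would be
        # completely confounded
        density = {
            g: float(np.log(sizes[g]) + rng.normal(0, 0.5)) for g in st.index
        }
        scale = max(density.values())
        density = {g: v / scale for g, v in density.items()}
        calls = od.detect_outliers(density, st, q=0.10)
        upper = calls.index[calls["label"] == "upper"]
        lower = calls.index[calls["label"] == "lower"]
        for col in ("size", "exon_density"):
            p = wilcoxon_rank_sum(st.loc[upper, col], st.loc[lower, col]).p
            assert p > 0.01


class TestOptimizeCutoff:
    @staticmethod
    def _species_data(n, seed, shared_density=None):
        rng = np.random.default_rng(seed)
        densities, strata, homology_members = {}, {}, {}
        species = ["cow", "human", "mouse"]
        for si, sp in enumerate(species):
            # identical gene structure across species when densities are
            # duplicated, so stratification is identical too
            gene_rng = np.random.default_rng(seed) if shared_density is not None else rng
            genes = random_genes(gene_rng, n, species=sp)
            st = od.stratify(genes)
            if shared_density is None:
                dens = {g: float(rng.random()) for g in st.index}
            else:
                ids = sorted(st.index)
                dens = dict(zip(ids, shared_density))
            densities[sp], strata[sp] = dens, st
        groups = []
        ids_by_sp = {sp: sorted(strata[sp].index) for sp in species}
        for i in range(n):
            groups.append(
                HomologyGroup(
                    f"HG{i:05d}", tuple((sp, ids_by_sp[sp][i]) for sp in species)
                )
            )
        return densities, strata, groups

    def test_default_grid_has_ten_rows(self):
        densities, strata, groups = self._species_data(100, 0)
        table = od.optimize_cutoff(densities, strata, groups)
        assert len(table) == 10
        assert table["cutoff"].tolist() == pytest.approx(
            [0.025 * k for k in range(1, 11)]
        )

    def test_independent_labels_near_null(self):
        densities, strata, groups = self._species_data(1000, 1)
        table = od.optimize_cutoff(densities, strata, groups, cutoffs=[0.25])
        row = table.iloc[0]
        # q^3 = 0.0156; Monte-Carlo noise at n=1000 stays well within 4 SD
        se = np.sqrt(0.25**3 * (1 - 0.25**3) / 1000)
        assert abs(row["observed_freq_suo"] - 0.25**3) < 4 * se

    def test_perfectly_correlated_densities_share_at_rate_q(self):
        rng = np.random.default_rng(3)
        shared = list(rng.random(500))
        densities, strata, groups = self._species_data(500, 3, shared_density=shared)
        table = od.optimize_cutoff(densities, strata, groups, cutoffs=[0.10])
        row = table.iloc[0]
        # identical density vectors: outlier status is (nearly) the same gene
        # set in every species, so the shared frequency approaches q itself
        assert row["observed_freq_suo"] == pytest.approx(0.10, abs=0.03)
        assert row["enrichment_suo"] == pytest.approx(0.10 / 0.10**3, rel=0.35)
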