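import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teoutliers import te_metrics as tm
from teoutliers.model import TE_CLASSES, TEFragment


def per_base_oracle(gene, fragments):
    """Base-wise sweep: coverage and class composition by explicit assignment.

    Each base in the gene span is marked covered if any fragment spans it;
    its class comes from the covering fragment with the lowest start, then
    the longest one.
    """
    owner = np.full(gene.length, -1)
    order = sorted(
        (f for f in fragments if f.chromosome == gene.chromosome),
        key=lambda f: (f.start, -(f.end - f.start)),
    )
    for idx, f in enumerate(order):
        s = max(f.start, gene.start) - gene.start
        e = min(f.end, gene.end) - gene.start
        if e > s:
            sl = owner[s:e]
            sl[sl == -1] = idx
    covered = int((owner >= 0).sum())
    class_bp = dict.fromkeys(TE_CLASSES, 0)
    for idx, f in enumerate(order):
        class_bp[f.te_class] += int((owner == idx).sum())
    return covered, class_bp


class TestDensity:
    def test_ratio_definition(self, make_gene, make_frag):
        gene = make_gene(end=20_000)
        frags = [make_frag(0, 2000), make_frag(5000, 8000)]
        m = tm.compute_te_density(gene, frags)
        assert m.coverage == 5000
        assert m.density == pytest.approx(0.25)

    def test_no_overlap_is_zero(self, make_gene, make_frag):
        gene = make_gene(end=20_000)
        m = tm.compute_te_density(gene, [make_frag(50_000, 51_000)])
        assert (m.coverage, m.density) == (0, 0.0)

    def test_union_of_overlapping_fragments(self, make_gene, make_frag):
        gene = make_gene(start=0, end=10_000)
        m = tm.compute_te_density(gene, [make_frag(100, 600), make_frag(400, 900)])
        assert m.coverage == 800
        assert m.density == pytest.approx(0.08)

    def test_clipping_to_gene_span(self, make_gene, make_frag):
        gene = make_gene(start=1000, end=2000)
        m = tm.compute_te_density(gene, [make_frag(0, 5000)])
        assert m.density == 1.0

    def test_invariant_under_fragment_split(self, make_gene, make_frag):
        gene = make_gene(end=10_000)
        whole = tm.compute_te_density(gene, [make_frag(200, 1200)])
        split = tm.compute_te_density(gene, [make_frag(200, 700), make_frag(700, 1200)])
        assert whole.coverage == split.coverage

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_per_base_oracle(self, data):
        from teoutliers.model import GeneModel

        end = data.draw(st.integers(1000, 50_000))
        gene = GeneModel("g", "human", "chr1", 0, end, "+", ((0, 100),))
        n = data.draw(st.integers(0, 25))
        frags = []
        for _ in range(n):
            s = data.draw(st.integers(-500, gene.end + 500))
            length = data.draw(st.integers(1, 3000))
            cls = data.draw(st.sampled_from(TE_CLASSES))
            frags.append(TEFragment("chr1", s, s + length, cls, "fam", 10.0))
        cov, class_bp = per_base_oracle(gene, frags)
        m = tm.compute_te_density(gene, frags)
        assert m.coverage == cov
        comp = tm.compute_composition(gene, frags)
        if cov == 0:
            assert comp is None
        else:
            for cls in TE_CLASSES:
                assert comp[cls] == pytest.approx(class_bp[cls] / cov)


class TestComposition:
    def test_single_class(self, make_gene, make_frag):
        gene = make_gene(end=20_000)
        comp = tm.compute_composition(gene, [make_frag(0, 100), make_frag(500, 900)])
        assert comp == {"SINE": 1.0, "LINE": 0.0, "LTR": 0.0, "DNA": 0.0}

    def test_two_class_arithmetic(self, make_gene, make_frag):
        gene = make_gene(end=20_000)
        comp = tm.compute_composition(
            gene,
            [make_frag(0, 300, "SINE"), make_frag(1000, 1100, "LINE", family="L1")],
        )
        assert comp["SINE"] == pytest.approx(0.75)
        assert comp["LINE"] == pytest.approx(0.25)

    def test_cross_class_overlap_lower_start_wins(self, make_gene, make_frag):
        gene = make_gene(end=10_000)
        frags = [make_frag(100, 600, "LINE"), make_frag(400, 900, "SINE")]
        comp = tm.compute_composition(gene, frags)
        # LINE owns [100,600), SINE only the uncovered [600,900)
        assert comp["LINE"] == pytest.approx(500 / 800)
        assert comp["SINE"] == pytest.approx(300 / 800)

    def test_no_te_undefined(self, make_gene):
        assert tm.compute_composition(make_gene(), []) is None


class TestMeanAge:
    def test_single_fragment_identity(self, make_gene, make_frag):
        gene = make_gene(end=20_000)
        assert tm.compute_mean_te_age(gene, [make_frag(0, 100, divergence=12.5)]) == 12.5

    def test_weighted_mean(self, make_gene, make_frag):
        gene = make_gene(end=20_000)
        frags = [
            make_frag(0, 100, divergence=10.0),
            make_frag(1000, 1300, divergence=20.0),
        ]
        # (10*100 + 20*300) / 400 = 17.5
        assert tm.compute_mean_te_age(gene, frags) == pytest.approx(17.5)

    def test_equal_divergence_invariance(self, make_gene, make_frag):
        gene = make_gene(end=20_000)
        frags = [make_frag(i * 500, i * 500 + 200, divergence=7.7) for i in range(5)]
        assert tm.compute_mean_te_age(gene, frags) == pytest.approx(7.7)

    def test_unmerged_weighting_counts_overlap_twice(self, make_gene, make_frag):
        gene = make_gene(end=10_000)
        frags = [make_frag(0, 1000, divergence=10.0), make_frag(500, 1000, divergence=30.0)]
        # weights 1000 and 500 despite the 500 bp overlap
        assert tm.compute_mean_te_age(gene, frags) == pytest.approx(
            (10 * 1000 + 30 * 500) / 1500
        )

    def test_convex_combination_bounds(self, make_gene, make_frag):
        rng = np.random.default_rng(0)
        gene = make_gene(end=30_000)
        frags = [
            make_frag(int(s), int(s) + int(l), divergence=float(d))
            for s, l, d in zip(
                rng.integers(0, 29_000, 20), rng.integers(50, 900, 20), rng.uniform(1, 40, 20)
            )
        ]
        d_bar = tm.compute_mean_te_age(gene, frags)
        divs = [f.divergence for f in frags]
        assert min(divs) <= d_bar <= max(divs)

    def test_no_fragment_is_error_not_zero(self, make_gene):
        with pytest.raises(ValueError, match="no TE fragments"):
            tm.compute_mean_te_age(make_gene(), [])


class TestGC:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 1.0), ("ATGC", 0.5), ("ANNT", 0.0), ("acgt", 0.5)]
    )
    def test_gc_fraction(self, seq, expected):
        assert tm.gc_fraction(seq) == pytest.approx(expected)

    def test_ambiguity_excluded_from_denominator(self):
        assert tm.gc_fraction("ANNT") == 0.0  # denominator is 2, not 4
        assert tm.gc_fraction("GNNN") == 1.0

    def test_all_ambiguous_errors(self):
        with pytest.raises(ValueError):
            tm.gc_fraction("NNNN")

    def test_compute_gc_from_fasta(self, tmp_path, make_gene):
        from pyfaidx import Fasta

        fa = tmp_path / "toy.fa"
        fa.write_text(">chr1\n" + "ACGT" * 25 + "\n")
        gene = make_gene(start=0, end=100, exons=((0, 50),))
        assert tm.compute_gc(gene, Fasta(str(fa))) == pytest.approx(0.5)

    def test_per_base_gc_oracle(self, tmp_path, make_gene):
        from pyfaidx import Fasta

        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGTN"), size=2000))
        fa = tmp_path / "toy.fa"
        fa.write_text(">chr1\n" + seq + "\n")
        gene = make_gene(start=100, end=1900, exons=((100, 200),))
        sub = seq[100:1900]
        expected = sum(c in "GC" for c in sub) / sum(c in "ACGT" for c in sub)
        assert tm.compute_gc(gene, Fasta(str(fa))) == pytest.approx(expected)
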