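import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from teoutliers import cross_species as cs
from teoutliers.model import GeneTEMetrics, HomologyGroup, SharedOutlierSet


def _calls(labels: dict[str, str]) -> pd.DataFrame:
    df = pd.DataFrame({"label": pd.Series(labels)})
    df.index.name = "gene_id"
    return df


def _group(i, species_genes):
    return HomologyGroup(f"HG{i}", tuple(sorted(species_genes)))


class TestFindShared:
    species = ("human", "mouse", "cow")

    def _three_species(self, labels_by_species):
        calls = {sp: _calls(labels_by_species[sp]) for sp in self.species}
        groups = [
            _group(0, [(sp, f"{sp}_A") for sp in self.species]),
            _group(1, [(sp, f"{sp}_B") for sp in self.species]),
        ]
        return calls, groups

    def test_upper_in_all_species_included(self):
        calls, groups = self._three_species(
            {sp: {f"{sp}_A": "upper", f"{sp}_B": "none"} for sp in self.species}
        )
        s = cs.find_shared_outliers(calls, groups, "upper")
        assert s.group_ids == ["HG0"]

    def test_two_of_three_excluded(self):
        labels = {sp: {f"{sp}_A": "upper", f"{sp}_B": "none"} for sp in self.species}
        labels["cow"]["cow_A"] = "none"
        calls, groups = self._three_species(labels)
        assert cs.find_shared_outliers(calls, groups, "upper").n == 0

    def test_mixed_sides_excluded_from_both(self):
        labels = {sp: {f"{sp}_A": "upper", f"{sp}_B": "none"} for sp in self.species}
        labels["mouse"]["mouse_A"] = "lower"
        calls, groups = self._three_species(labels)
        assert cs.find_shared_outliers(calls, groups, "upper").n == 0
        assert cs.find_shared_outliers(calls, groups, "lower").n == 0

    def test_paralogs_excluded(self):
        calls = {sp: _calls({f"{sp}_A": "upper", f"{sp}_A2": "upper"}) for sp in self.species}
        groups = [
            _group(0, [("human", "human_A"), ("human", "human_A2"),
                       ("mouse", "mouse_A"), ("cow", "cow_A")])
        ]
        assert cs.find_shared_outliers(calls, groups, "upper").n == 0

    def test_species_order_symmetric(self):
        calls, groups = self._three_species(
            {sp: {f"{sp}_A": "upper", f"{sp}_B": "lower"} for sp in self.species}
        )
        reordered = {sp: calls[sp] for sp in reversed(self.species)}
        assert cs.find_shared_outliers(calls, groups, "upper") == cs.find_shared_outliers(
            reordered, groups, "upper"
        )

    def test_suo_slo_disjoint_on_random_labels(self):
        rng = np.random.default_rng(0)
        calls = {}
        for sp in self.species:
            labels = rng.choice(["upper", "lower", "none"], size=200, p=[0.1, 0.1, 0.8])
            calls[sp] = _calls({f"{sp}_g{i}": l for i, l in enumerate(labels)})
        groups = [
            _group(i, [(sp, f"{sp}_g{i}") for sp in self.species]) for i in range(200)
        ]
        suo = set(cs.find_shared_outliers(calls, groups, "upper").group_ids)
        slo = set(cs.find_shared_outliers(calls, groups, "lower").group_ids)
        assert not (suo & slo)

    def test_missing_calls_error(self):
        calls = {"human": pd.DataFrame({"x": []})}
        with pytest.raises(ValueError, match="missing outlier calls"):
            cs.find_shared_outliers(calls, [], "upper")


class TestExcessTest:
    def test_observed_equal_to_null(self):
        # 1 shared in 1000 orthologs at q=0.1, S=3 -> exactly the null rate
        rep = cs.shared_excess_test(1, 1000, 0.1, 3, continuity=False)
        assert rep.p == pytest.approx(1.0, abs=1e-9)

    def test_matches_exact_binomial_oracle(self):
        # strong excess: 84 shared among 16000 vs null 0.001
        rep = cs.shared_excess_test(84, 16000, 0.1, 3)
        oracle = binomtest(84, 16000, 0.001, alternative="greater").pvalue
        assert rep.p < 1e-15 and oracle < 1e-15
        # moderate excess: chi-square p tracks the exact tail
        rep = cs.shared_excess_test(4, 1000, 0.1, 3)
        oracle = binomtest(4, 1000, 0.001).pvalue
        assert rep.p == pytest.approx(oracle, abs=0.05)

    def test_zero_shared_closed_form(self):
        n, q, s = 500, 0.1, 3
        rep = cs.shared_excess_test(0, n, q, s)
        closed = (1 - q**s) ** n  # P(no shared at all under the null)
        # two-sided chi-square p cannot be more extreme than this tail doubled
        assert rep.p > closed


def _metrics(gene_id, comp, gc=None):
    return GeneTEMetrics(
        gene_id=gene_id, coverage=1000, density=0.1, composition=comp, gc=gc
    )


def _shared(n, species=("human", "mouse")):
    return SharedOutlierSet(
        side="upper",
        members=tuple(
            (f"HG{i}", tuple((sp, f"{sp}_g{i}") for sp in species)) for i in range(n)
        ),
    )


class TestCorrelations:
    def _comp(self, sine):
        rest = (1 - sine) / 3
        return {"SINE": sine, "LINE": rest, "LTR": rest, "DNA": rest}

    def test_identical_compositions_r1(self):
        shared = _shared(5)
        ma = {f"human_g{i}": _metrics(f"human_g{i}", self._comp(0.1 * (i + 1))) for i in range(5)}
        mb = {f"mouse_g{i}": _metrics(f"mouse_g{i}", self._comp(0.1 * (i + 1))) for i in range(5)}
        r = cs.composition_correlation(shared, ma, mb, "human", "mouse")
        assert r["SINE"] == pytest.approx(1.0)

    def test_anticorrelated_r_minus1(self):
        shared = _shared(5)
        ma = {f"human_g{i}": _metrics(f"human_g{i}", self._comp(0.1 * (i + 1))) for i in range(5)}
        mb = {f"mouse_g{i}": _metrics(f"mouse_g{i}", self._comp(0.1 * (5 - i))) for i in range(5)}
        r = cs.composition_correlation(shared, ma, mb, "human", "mouse")
        assert r["SINE"] == pytest.approx(-1.0)

    def test_random_matches_covariance_oracle(self):
        rng = np.random.default_rng(1)
        n = 30
        shared = _shared(n)
        sa, sb = rng.uniform(0.05, 0.9, n), rng.uniform(0.05, 0.9, n)
        ma = {f"human_g{i}": _metrics(f"human_g{i}", self._comp(sa[i])) for i in range(n)}
        mb = {f"mouse_g{i}": _metrics(f"mouse_g{i}", self._comp(sb[i])) for i in range(n)}
        r = cs.composition_correlation(shared, ma, mb, "human", "mouse")
        expected = np.corrcoef(sa, sb)[0, 1]
        assert r["SINE"] == pytest.approx(expected, abs=1e-12)

    def test_gc_constant_undefined(self):
        n = 5
        shared = _shared(n)
        m = {
            f"human_g{i}": _metrics(f"human_g{i}", self._comp(0.1 * (i + 1)), gc=0.4)
            for i in range(n)
        }
        r = cs.gc_composition_correlation(shared, m, "human")
        assert np.isnan(r["SINE"])

    def test_gc_monotone_linear(self):
        n = 5
        shared = _shared(n)
        m = {
            f"human_g{i}": _metrics(
                f"human_g{i}", self._comp(0.1 * (i + 1)), gc=0.3 + 0.05 * i
            )
            for i in range(n)
        }
        r = cs.gc_composition_correlation(shared, m, "human")
        assert r["SINE"] == pytest.approx(1.0)
        assert r["LINE"] == pytest.approx(-1.0)


class TestChromosomeCounts:
    def test_tally_matches_groupby_oracle(self, make_gene):
        rng = np.random.default_rng(2)
        n = 40
        shared = _shared(n, species=("human",))
        genes = {}
        chroms = []
        for i in range(n):
            c = f"chr{rng.integers(1, 6)}"
            chroms.append(c)
            genes[f"human_g{i}"] = make_gene(gene_id=f"human_g{i}", chromosome=c)
        df = cs.count_by_chromosome(shared, genes, "human")
        oracle = pd.Series(chroms).value_counts().sort_index()
        assert df["n"].to_dict() == oracle.to_dict()

    def test_empty_set_all_zero(self):
        df = cs.count_by_chromosome(
            _shared(0, ("human",)), {}, "human", chromosome_sizes={"chr1": 100}
        )
        assert df["n"].sum() == 0

    def test_sine_dominated_strict_majority(self):
        m = {
            "a": _metrics("a", {"SINE": 0.5, "LINE": 0.5, "LTR": 0, "DNA": 0}),
            "b": _metrics("b", {"SINE": 0.51, "LINE": 0.49, "LTR": 0, "DNA": 0}),
        }
        assert cs.sine_dominated(m, ["a", "b"]) == ["b"]
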