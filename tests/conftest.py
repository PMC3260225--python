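import numpy as np
import pytest

from teoutliers.model import GeneModel, TEFragment


@pytest.fixture
def make_gene():
    """Factory for small gene models with auto-generated exons."""

    def _make(
        gene_id="g1",
        species="human",
        chromosome="chr1",
        start=0,
        end=20_000,
        exons=None,
        n_exons=2,
        strand="+",
        homology_id=None,
    ):
        if exons is None:
            span = end - start
            step = span // n_exons
            exons = tuple(
                (start + i * step, start + i * step + min(100, step))
                for i in range(n_exons)
            )
        return GeneModel(
            gene_id=gene_id,
            species=species,
            chromosome=chromosome,
            start=start,
            end=end,
            strand=strand,
            exons=tuple(exons),
            homology_id=homology_id,
        )

    return _make


@pytest.fixture
def make_frag():
    def _make(start, end, te_class="SINE", chromosome="chr1", family="Alu", divergence=10.0):
        return TEFragment(
            chromosome=chromosome,
            start=start,
            end=end,
            te_class=te_class,
            family=family,
            divergence=divergence,
        )

    return _make


def random_genes(rng: np.random.Generator, n: int, species="human") -> list[GeneModel]:
    """Random >10 kb genes with varied sizes and exon counts."""
    genes = []
    for i in range(n):
        size = int(rng.integers(10_001, 200_000))
        start = int(rng.integers(0, 1_000_000))
        n_ex = int(rng.integers(1, 30))
        bounds = np.linspace(start, start + size, n_ex + 1).astype(int)
        exons = tuple(
            (int(lo), int(lo) + max(1, min(50, int(hi - lo) - 1)))
            for lo, hi in zip(bounds[:-1], bounds[1:])
        )
        genes.append(
            GeneModel(
                gene_id=f"{species}_g{i:04d}",
                species=species,
                chromosome=f"chr{1 + i % 5}",
                start=start,
                end=start + size,
                strand="+",
                exons=exons,
            )
        )
    return genes
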