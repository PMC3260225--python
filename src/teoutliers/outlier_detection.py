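"""Stratified TE-density outlier detection.

Gene size and exon density both constrain how much TE sequence a gene can
hold, so raw density extremes would simply pick out long, exon-sparse genes.
Outliers are therefore called within a 5x5 lattice: genes are split into
size quintiles, each size quintile into exon-density quintiles, and the
upper/lower density tails are taken per lattice cell before being merged
into genome-wide upper/lower sets.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import GeneModel, HomologyGroup

MIN_GENE_LENGTH = 10_000  # strict lower bound, bp
N_BINS = 5
DEFAULT_CUTOFF = 0.10


def filter_genes(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Keep genes strictly larger than 10 kb.

    Small genes hold few TEs purely for lack of room (their density
    distribution collapses onto zero), so they are excluded up front.
    """
    return [g for g in genes if g.length > MIN_GENE_LENGTH]


def exon_density(gene: GeneModel, mode: str = "count") -> float:
    """Exon density of a gene.

    ``mode="count"`` (default): exons per kb of gene span.
    ``mode="bp"``: exonic bp as a fraction of the gene span.
    """
    if mode == "count":
        return gene.exon_count / (gene.length / 1000.0)
    if mode == "bp":
        return sum(e - s for s, e in gene.exons) / gene.length
    raise ValueError(f"unknown exon-density mode {mode!r}")


def stratify(genes: list[GeneModel], mode: str = "count") -> pd.DataFrame:
    """Assign each gene to one of 25 size x exon-density lattice cells.

    Genes are sorted by (size, gene_id) and cut into five near-equal size
    bins at the order statistics; within each size bin the same is done by
    (exon density, gene_id). Cell occupancies differ by at most the rounding
    remainder, and ties are resolved by the gene_id sort so the assignment is
    deterministic.

    Returns a DataFrame indexed by gene_id with columns ``size``,
    ``exon_density``, ``size_bin``, ``exon_density_bin`` (bins are 1-5).
    """
    if len(genes) < N_BINS * N_BINS:
        raise ValueError(f"need at least {N_BINS * N_BINS} genes, got {len(genes)}")
    rows = {
        g.gene_id: (g.length, exon_density(g, mode)) for g in genes
    }
    if len(rows) != len(genes):
        raise ValueError("duplicate gene_id in input")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["size", "exon_density"])
    df.index.name = "gene_id"
    df["size_bin"] = 0
    df["exon_density_bin"] = 0
    by_size = df.loc[sorted(df.index)].sort_values("size", kind="mergesort")
    for i, chunk in enumerate(np.array_split(by_size.index, N_BINS), start=1):
        df.loc[chunk, "size_bin"] = i
        sub = df.loc[chunk]
        by_ed = sub.loc[sorted(sub.index)].sort_values("exon_density", kind="mergesort")
        for j, cell in enumerate(np.array_split(by_ed.index, N_BINS), start=1):
            df.loc[cell, "exon_density_bin"] = j
    return df.loc[sorted(df.index)]


def _tail_count(q: float, n: int) -> int:
    # ceil with a guard against float noise (0.1 * 20 == 2.0000000000000004)
    return int(math.ceil(q * n - 1e-9))


def detect_outliers(
    density: Mapping[str, float],
    strata: pd.DataFrame,
    q: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Call upper/lower TE-density outliers per lattice cell.

    In each of the 25 cells, the ceil(q*n) genes with the highest densities
    are labelled ``upper`` and the ceil(q*n) lowest ``lower`` (boundary ties
    broken by gene_id); cell-wise calls are merged into the genome-wide sets.

    Returns a DataFrame indexed by gene_id with columns ``label`` (upper /
    lower / none) and ``cutoff``.
    """
    if not 0.0 <= q <= 0.5:
        raise ValueError(f"cutoff {q} outside [0, 0.5]")
    missing = [g for g in strata.index if g not in density]
    if missing:
        raise ValueError(f"no density for {len(missing)} stratified genes, e.g. {missing[0]!r}")
    labels = pd.Series("none", index=strata.index, name="label")
    for _, cell in strata.groupby(["size_bin", "exon_density_bin"], sort=True):
        ids = sorted(cell.index)
        ranked = sorted(ids, key=lambda g: (density[g], g))
        k = _tail_count(q, len(ranked))
        if 2 * k > len(ranked):
            raise ValueError(
                f"cell of {len(ranked)} genes too small for cutoff {q} on both sides"
            )
        if k:
            labels[ranked[:k]] = "lower"
            labels[ranked[-k:]] = "upper"
    out = labels.to_frame()
    out["cutoff"] = q
    return out


DEFAULT_CUTOFF_GRID = tuple(np.round(np.arange(0.025, 0.2501, 0.025), 4))


def optimize_cutoff(
    density_by_species: Mapping[str, Mapping[str, float]],
    strata_by_species: Mapping[str, pd.DataFrame],
    homology: list[HomologyGroup],
    cutoffs: Iterable[float] = DEFAULT_CUTOFF_GRID,
) -> pd.DataFrame:
    """Scan outlier cutoffs and tabulate shared-outlier yield vs. the null.

    For each cutoff q the outlier calls are recomputed in every species and
    intersected over homology groups. The expected null frequency of a
    shared outlier under independence is q**S for S species; the enrichment
    ratio is the observed shared frequency over that null.
    """
    from .cross_species import find_shared_outliers  # local import, avoids cycle

    species = sorted(density_by_species)
    if len(species) < 2:
        raise ValueError("need at least two species")
    if set(species) != set(strata_by_species):
        raise ValueError("species mismatch between densities and strata")
    rows = []
    for q in cutoffs:
        calls = {
            sp: detect_outliers(density_by_species[sp], strata_by_species[sp], q)
            for sp in species
        }
        upper = find_shared_outliers(calls, homology, side="upper")
        lower = find_shared_outliers(calls, homology, side="lower")
        n_orth = _n_informative_groups(calls, homology)
        if n_orth == 0:
            raise ValueError("no homology group with one analyzed gene per species")
        expected = float(q) ** len(species)
        rows.append(
            {
                "cutoff": float(q),
                "n_suo": upper.n,
                "n_slo": lower.n,
                "n_orthologs": n_orth,
                "expected_null_freq": expected,
                "observed_freq_suo": upper.n / n_orth,
                "observed_freq_slo": lower.n / n_orth,
                "enrichment_suo": (upper.n / n_orth) / expected,
                "enrichment_slo": (lower.n / n_orth) / expected,
            }
        )
    return pd.DataFrame(rows)


def _n_informative_groups(
    calls_by_species: Mapping[str, pd.DataFrame], homology: list[HomologyGroup]
) -> int:
    """Homology groups with exactly one analyzed gene in every species."""
    species = sorted(calls_by_species)
    n = 0
    for grp in homology:
        ok = True
        for sp in species:
            genes = [g for g in grp.genes_of(sp) if g in calls_by_species[sp].index]
            if len(genes) != 1:
                ok = False
                break
        n += ok
    return n
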