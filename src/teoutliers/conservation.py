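"""Gene conservation levels and TE-age comparisons.

Conservation is read off the homology table: a gene is *ancient* when its
group also contains a distant outgroup species (zebrafish, fruit fly or
yeast by default), *mammalian-specific* when the group spans at least two of
the focal mammals, and *species-specific* otherwise — including genes with
no homology group at all.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GeneModel, HomologyGroup
from .stats import wilcoxon_rank_sum

LEVELS = ("species_specific", "mammalian_specific", "ancient")
DEFAULT_MAMMALS = frozenset({"human", "mouse", "cow"})
DEFAULT_OUTGROUPS = frozenset({"zebrafish", "fruitfly", "yeast"})


def classify_conservation(
    genes: Iterable[GeneModel],
    homology: list[HomologyGroup],
    mammals: frozenset[str] = DEFAULT_MAMMALS,
    outgroups: frozenset[str] = DEFAULT_OUTGROUPS,
) -> pd.Series:
    """Conservation level per gene, as a Series indexed by gene_id."""
    group_species: dict[tuple[str, str], set[str]] = {}
    for grp in homology:
        for sp, gid in grp.members:
            group_species[(sp, gid)] = grp.species
    labels = {}
    for g in genes:
        species = group_species.get((g.species, g.gene_id), {g.species})
        n_mammals = len(species & mammals)
        if species & outgroups and n_mammals >= 1:
            labels[g.gene_id] = "ancient"
        elif n_mammals >= 2:
            labels[g.gene_id] = "mammalian_specific"
        else:
            labels[g.gene_id] = "species_specific"
    return pd.Series(labels, name="conservation").sort_index()


def conservation_composition(
    gene_sets: Mapping[str, Iterable[str]], labels: pd.Series
) -> pd.DataFrame:
    """Per-set fraction of genes at each conservation level (rows sum to 1)."""
    rows = {}
    for name, ids in gene_sets.items():
        ids = [g for g in ids if g in labels.index]
        if not ids:
            raise ValueError(f"gene set {name!r} is empty or unlabelled")
        counts = labels.loc[ids].value_counts()
        rows[name] = {lvl: counts.get(lvl, 0) / len(ids) for lvl in LEVELS}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(LEVELS))


def compare_te_age(ages_a: Sequence[float], ages_b: Sequence[float]) -> dict:
    """Two-sided rank-sum comparison of mean TE age between two gene sets."""
    a = np.asarray(list(ages_a), dtype=float)
    b = np.asarray(list(ages_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both gene sets need TE ages")
    report = wilcoxon_rank_sum(a, b)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "test": report,
    }


def age_control_experiment(
    labels: pd.Series,
    ages: Mapping[str, float],
    n_per_group: int = 200,
    seed: int = 0,
) -> dict:
    """TE-age comparison between random mammalian-specific and ancient genes.

    Samples ``n_per_group`` genes (without replacement, seeded) from each
    conservation level among genes that have a defined TE age, then runs the
    same rank-sum comparison as :func:`compare_te_age`. This controls for
    the possibility that a TE-age difference between outlier sets merely
    reflects a gene-age difference.
    """
    rng = np.random.default_rng(seed)
    pools = {}
    for level in ("mammalian_specific", "ancient"):
        pool = sorted(
            g for g in labels.index[labels == level] if g in ages and ages[g] is not None
        )
        if len(pool) < n_per_group:
            raise ValueError(
                f"{level}: need {n_per_group} genes with TE age, have {len(pool)}"
            )
        pools[level] = [pool[i] for i in rng.choice(len(pool), n_per_group, replace=False)]
    result = compare_te_age(
        [ages[g] for g in pools["mammalian_specific"]],
        [ages[g] for g in pools["ancient"]],
    )
    result["sampled"] = pools
    return result
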