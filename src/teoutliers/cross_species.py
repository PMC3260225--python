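"""Shared-outlier identification across species and follow-up analyses.

A gene qualifies as a shared upper/lower outlier (SUO/SLO) when its
homology group has exactly one analyzed gene in every species and all of
them are outliers of the same side. Under independent outlier calling at
cutoff q in S species, a group is a shared outlier with probability q**S,
which is the null the excess test works against.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pandas as pd

from .model import TE_CLASSES, GeneModel, GeneTEMetrics, HomologyGroup, SharedOutlierSet
from .stats import TestReport, pearson_r, prop_test_1samp


def find_shared_outliers(
    calls_by_species: Mapping[str, pd.DataFrame],
    homology: list[HomologyGroup],
    side: str,
) -> SharedOutlierSet:
    """Intersect per-species outlier calls over homology groups.

    A group is included only if it has exactly one analyzed gene per species
    (groups with paralogs in any species are excluded to avoid double
    counting) and every such gene carries the requested label.
    """
    if side not in ("upper", "lower"):
        raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")
    if not calls_by_species:
        raise ValueError("no outlier calls supplied")
    species = sorted(calls_by_species)
    for sp in species:
        if "label" not in calls_by_species[sp].columns:
            raise ValueError(f"species {sp!r}: missing outlier calls")
    labels = {sp: calls_by_species[sp]["label"].to_dict() for sp in species}
    members = []
    for grp in sorted(homology, key=lambda g: g.group_id):
        pairs = []
        for sp in species:
            analyzed = [g for g in grp.genes_of(sp) if g in labels[sp]]
            if len(analyzed) != 1:
                pairs = None
                break
            pairs.append((sp, analyzed[0]))
        if pairs is None:
            continue
        if all(labels[sp][g] == side for sp, g in pairs):
            members.append((grp.group_id, tuple(pairs)))
    return SharedOutlierSet(side=side, members=tuple(members))


def shared_excess_test(
    n_shared: int, n_orthologs: int, q: float, n_species: int, continuity: bool = True
) -> TestReport:
    """Test the observed shared-outlier proportion against the q**S null."""
    if n_orthologs <= 0:
        raise ValueError("need a positive number of orthologous groups")
    p0 = float(q) ** n_species
    return prop_test_1samp(n_shared, n_orthologs, p0, continuity=continuity)


def composition_correlation(
    shared: SharedOutlierSet,
    metrics_a: Mapping[str, GeneTEMetrics],
    metrics_b: Mapping[str, GeneTEMetrics],
    species_a: str,
    species_b: str,
) -> dict[str, float]:
    """Pearson r of normalized TE-class fractions between two species.

    One r per TE class, computed over orthologous gene pairs of the shared
    set that have a defined composition in both species. NaN when fewer
    than three informative pairs or a zero-variance vector.
    """
    pairs = []
    for _, genes in shared.members:
        by_sp = dict((sp, gid) for sp, gid in genes)
        ma = metrics_a.get(by_sp.get(species_a, ""))
        mb = metrics_b.get(by_sp.get(species_b, ""))
        if ma is None or mb is None:
            continue
        if ma.composition is None or mb.composition is None:
            continue
        pairs.append((ma.composition, mb.composition))
    out = {}
    for cls in TE_CLASSES:
        if len(pairs) < 3:
            out[cls] = float("nan")
        else:
            out[cls] = pearson_r(
                [a[cls] for a, _ in pairs], [b[cls] for _, b in pairs]
            )
    return out


def gc_composition_correlation(
    shared: SharedOutlierSet,
    metrics: Mapping[str, GeneTEMetrics],
    species: str,
    classes: Iterable[str] = ("LINE", "SINE"),
) -> dict[str, float]:
    """Pearson r of per-gene class fraction vs. gene G+C content."""
    rows = []
    for _, genes in shared.members:
        by_sp = dict((sp, gid) for sp, gid in genes)
        m = metrics.get(by_sp.get(species, ""))
        if m is None or m.composition is None or m.gc is None:
            continue
        rows.append(m)
    out = {}
    for cls in classes:
        if len(rows) < 3:
            out[cls] = float("nan")
        else:
            out[cls] = pearson_r(
                [m.composition[cls] for m in rows], [m.gc for m in rows]
            )
    return out


def count_by_chromosome(
    shared: SharedOutlierSet,
    genes: Mapping[str, GeneModel],
    species: str,
    chromosome_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Tally shared outliers per chromosome of the reference species."""
    counts: dict[str, int] = {}
    if chromosome_sizes:
        counts = dict.fromkeys(chromosome_sizes, 0)
    for gid in shared.genes_of(species):
        gene = genes.get(gid)
        if gene is None:
            continue
        counts[gene.chromosome] = counts.get(gene.chromosome, 0) + 1
    df = pd.DataFrame(
        {"n": pd.Series(counts, dtype=int)}
    ).rename_axis("chromosome").sort_index()
    if chromosome_sizes:
        df["chromosome_size"] = pd.Series(chromosome_sizes)
    return df


def sine_dominated(metrics: Mapping[str, GeneTEMetrics], gene_ids: Iterable[str]) -> list[str]:
    """Genes whose TE content is more than 50% SINE (strict, normalized)."""
    out = []
    for gid in gene_ids:
        m = metrics.get(gid)
        if m is not None and m.composition is not None and m.composition["SINE"] > 0.5:
            out.append(gid)
    return out
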