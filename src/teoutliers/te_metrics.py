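"""Per-gene TE metrics: coverage, density, class composition, age, G+C.

TE density is the fraction of the gene span (longest isoform, introns
included) covered by the union of TE fragments. The mean TE age is the
fragment-length-weighted mean percent divergence from the family consensus,

    d_bar = sum(d_i * l_i) / L,   L = sum(l_i),

with l_i the clipped but *unmerged* fragment length: the sum runs over
fragments, not bases, so a base under two fragments contributes twice to the
age but once to the density.
"""

from __future__ import annotations

from collections.abc import Iterable

from .model import TE_CLASSES, GeneModel, GeneTEMetrics, TEFragment


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    ivs = sorted(iv for iv in intervals if iv[1] > iv[0])
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _clipped(gene: GeneModel, fragments: Iterable[TEFragment]) -> list[TEFragment]:
    """Fragments on the gene's chromosome clipped to its span."""
    out = []
    for f in fragments:
        if f.chromosome != gene.chromosome:
            continue
        s, e = max(f.start, gene.start), min(f.end, gene.end)
        if e > s:
            out.append(
                TEFragment(f.chromosome, s, e, f.te_class, f.family, f.divergence)
            )
    return out


def compute_te_density(gene: GeneModel, fragments: Iterable[TEFragment]) -> GeneTEMetrics:
    """Union TE coverage within the gene span and its density.

    Fragments are clipped to [start, end); overlapping or abutting fragments
    are merged before summing so density never exceeds 1.
    """
    if gene.length <= 0:
        raise ValueError(f"{gene.gene_id}: zero-length gene")
    clipped = _clipped(gene, fragments)
    coverage = sum(e - s for s, e in merge_intervals((f.start, f.end) for f in clipped))
    return GeneTEMetrics(
        gene_id=gene.gene_id, coverage=coverage, density=coverage / gene.length
    )


def compute_composition(
    gene: GeneModel, fragments: Iterable[TEFragment]
) -> dict[str, float] | None:
    """Fraction of TE-covered bp contributed by each of the four classes.

    A base under fragments of different classes is assigned to the fragment
    with the lower start (longer fragment on a start tie); fractions are
    normalized by total TE bp. Returns None when the gene holds no TE bp.
    """
    overlapping = [
        f
        for f in fragments
        if f.chromosome == gene.chromosome and f.end > gene.start and f.start < gene.end
    ]
    if not overlapping:
        return None
    # claim bases in priority order: earliest (unclipped) start, then longest
    # fragment; only the clipped part of each fragment is actually claimed
    order = sorted(overlapping, key=lambda f: (f.start, -(f.end - f.start)))
    covered: list[tuple[int, int]] = []  # disjoint, sorted
    class_bp = dict.fromkeys(TE_CLASSES, 0)
    for f in order:
        lo, hi = max(f.start, gene.start), min(f.end, gene.end)
        # subtract already-claimed intervals from [lo, hi)
        pos = lo
        claimed = 0
        for cs, ce in covered:
            if ce <= pos:
                continue
            if cs >= hi:
                break
            if cs > pos:
                claimed += min(cs, hi) - pos
            pos = max(pos, ce)
            if pos >= hi:
                break
        if pos < hi:
            claimed += hi - pos
        class_bp[f.te_class] += claimed
        covered = merge_intervals(covered + [(lo, hi)])
    total = sum(class_bp.values())
    if total == 0:
        return None
    return {cls: bp / total for cls, bp in class_bp.items()}


def compute_mean_te_age(gene: GeneModel, fragments: Iterable[TEFragment]) -> float:
    """Length-weighted mean percent divergence of TE fragments in the gene.

    Weights are clipped, unmerged fragment lengths. Raises if no fragment
    overlaps the gene (distinct from a density of 0 with no error upstream).
    """
    clipped = _clipped(gene, fragments)
    if not clipped:
        raise ValueError(f"{gene.gene_id}: no TE fragments overlap the gene")
    total = sum(f.length for f in clipped)
    return sum(f.divergence * f.length for f in clipped) / total


def gc_fraction(sequence: str) -> float:
    """G+C over A+C+G+T, case-insensitive; ambiguity codes excluded."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("no unambiguous bases in sequence")
    return gc / acgt


def compute_gc(gene: GeneModel, fasta) -> float:
    """G+C fraction of the gene span from an indexed FASTA (pyfaidx.Fasta)."""
    seq = str(fasta[gene.chromosome][gene.start : gene.end])
    if not seq:
        raise ValueError(f"{gene.gene_id}: no sequence for {gene.chromosome}")
    return gc_fraction(seq)


def compute_metrics(
    gene: GeneModel,
    fragments: Iterable[TEFragment],
    gc: float | None = None,
) -> GeneTEMetrics:
    """All TE metrics for one gene in a single pass."""
    frags = list(fragments)
    m = compute_te_density(gene, frags)
    m.composition = compute_composition(gene, frags)
    if m.coverage > 0:
        m.mean_te_age = compute_mean_te_age(gene, frags)
    m.gc = gc
    return m
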