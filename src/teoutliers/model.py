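"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open throughout the package;
dialect-specific conventions (GTF, RepeatMasker ``.out``) are converted at
parse/write time only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA")


@dataclass(frozen=True)
class GeneModel:
    """A gene represented by its longest isoform.

    ``start``/``end`` span the whole transcription unit; ``exons`` are
    non-overlapping (start, end) intervals within it.
    """

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    homology_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have at least one exon")
        exons = tuple(sorted(self.exons))
        prev_end = None
        for s, e in exons:
            if s < self.start or e > self.end or e <= s:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def exon_density(self) -> float:
        """Exons per kb of gene span."""
        return self.exon_count / (self.length / 1000.0)


@dataclass(frozen=True)
class TEFragment:
    """One RepeatMasker hit, reduced to the fields the analysis needs.

    ``divergence`` is the percent substitution from the family consensus
    (milliDiv / 10 for UCSC rmsk tables), used as a proxy for TE age.
    """

    chromosome: str
    start: int
    end: int
    te_class: str
    family: str
    divergence: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("TE fragment end must exceed start")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")
        if not 0.0 <= self.divergence <= 100.0:
            raise ValueError(f"divergence {self.divergence} outside [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HomologyGroup:
    """A cross-species homology group (HomoloGene-style)."""

    group_id: str
    members: tuple[tuple[str, str], ...]  # (species, gene_id)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_id}: no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"group {self.group_id}: duplicate (species, gene) pair")

    @property
    def species(self) -> set[str]:
        return {sp for sp, _ in self.members}

    def genes_of(self, species: str) -> list[str]:
        return [g for sp, g in self.members if sp == species]


@dataclass
class GeneTEMetrics:
    """Per-gene TE coverage/density/composition/age summary.

    ``coverage`` is union bp of TE annotation clipped to the gene span;
    ``density`` = coverage / gene length. ``composition`` maps each TE class
    to its fraction of covered bp (None when the gene holds no TE bp).
    ``mean_te_age`` is the length-weighted mean percent divergence (None when
    no TE overlaps the gene). ``gc`` is the G+C fraction if available.
    """

    gene_id: str
    coverage: int
    density: float
    composition: dict[str, float] | None = None
    mean_te_age: float | None = None
    gc: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"{self.gene_id}: density {self.density} outside [0, 1]")
        if self.composition is not None:
            total = sum(self.composition.values())
            if any(v < 0 for v in self.composition.values()) or abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.gene_id}: composition does not sum to 1")


@dataclass(frozen=True)
class SharedOutlierSet:
    """Homology groups whose genes are outliers of one side in all species."""

    side: str  # "upper" (SUO) or "lower" (SLO)
    members: tuple[tuple[str, tuple[tuple[str, str], ...]], ...]
    # (group_id, ((species, gene_id), ...))

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def group_ids(self) -> list[str]:
        return [g for g, _ in self.members]

    def genes_of(self, species: str) -> list[str]:
        out = []
        for _, pairs in self.members:
            for sp, gid in pairs:
                if sp == species:
                    out.append(gid)
        return out
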