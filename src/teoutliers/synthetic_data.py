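"""Synthetic multi-species annotation bundles.

The generator emulates the statistical structure the analysis assumes,
without any sequence realism: three mammalian species with orthologous gene
sets; per-gene TE fragments whose abundance is driven by a latent per-group
"openness" state shared across orthologs; Pol-II binding profiles over five
mouse tissues with a controllable ubiquitous/tissue-specific split and an
ES-cell skew tied to openness; promoter mark flags, expression values and
developmental flags all coupled to the same latent state. Every output file
is written in a dialect :mod:`teoutliers.annotations_io` reads back.

The openness state o_g is the ground truth the pipeline should recover:
with te_rate_openness_beta > 0 and ortholog_correlation near 1, orthologs of
open genes are TE-dense in every species, so shared upper outliers should be
enriched for high-openness groups; with beta = 0 and correlation 0, shared
outliers occur at the independence null rate q**S.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations_io import (
    write_gene_models,
    write_homology,
    write_te_annotations,
)
from .model import GeneModel, HomologyGroup, TEFragment

TISSUES = ("ESC", "brain", "heart", "kidney", "liver")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults are the package's study conditions."""

    species: tuple[str, ...] = ("human", "mouse", "cow")
    outgroups: tuple[str, ...] = ("zebrafish", "fruitfly", "yeast")
    binding_species: str = "mouse"
    n_ortholog_groups: int = 2000
    n_private_genes: int = 150  # per species, absent from the homology table
    # gene structure
    gene_size_log_mean: float = np.log(30_000.0)  # median 30 kb
    gene_size_log_sd: float = 0.65
    min_gene_size: int = 2_000
    exon_rate_per_kb: float = 0.25  # Poisson rate on top of 1 guaranteed exon
    exon_size: tuple[int, int] = (80, 250)
    # conservation structure of ortholog groups
    p_all_mammals: float = 0.70
    p_two_mammals: float = 0.15  # remaining groups are single-species
    p_ancient: float = 0.45  # P(outgroup member | >=2 mammals)
    # latent openness and TE model
    ortholog_correlation: float = 0.8  # rho: cross-species corr of openness
    te_rate_log_per_kb: float = 0.0  # alpha: log fragments per kb at o = 0
    te_rate_openness_beta: float = 0.6  # beta: effect of openness on TE rate
    te_dispersion: float = 5.0  # negative-binomial size parameter
    te_length_log_mean: dict[str, float] = field(
        default_factory=lambda: {
            "LINE": np.log(700.0),
            "SINE": np.log(200.0),
            "LTR": np.log(400.0),
            "DNA": np.log(250.0),
        }
    )
    te_length_log_sd: float = 0.5
    te_divergence_mean: dict[str, float] = field(
        default_factory=lambda: {"LINE": 20.0, "SINE": 17.0, "LTR": 14.0, "DNA": 24.0}
    )
    te_divergence_shape: float = 8.0
    te_age_openness_beta: float = 0.10  # open genes carry younger TEs
    gc_mean: float = 0.42
    gc_sd: float = 0.05
    gc_class_slope: float = 25.0  # SINE weight up / LINE weight down with gc
    flank_te_rate: float = 2.0  # Poisson mean of intergenic fragments per gene flank
    # binding model (binding_species only)
    p_ubiquitous: float = 0.54
    dirichlet_ubiquitous: float = 8.0
    dirichlet_specific_top: float = 15.0
    dirichlet_specific_rest: float = 1.0
    esc_openness_beta: float = 1.5  # ES-cell skew of the top tissue with openness
    # marks / expression / function
    k4_base: float = 0.6
    k4_openness_beta: float = 1.0
    k27_base: float = -1.7
    k27_openness_beta: float = -1.0
    expr_log_mean: float = 2.0
    expr_log_sd: float = 1.0
    expr_openness_beta: float = 0.8
    dev_base: float = -0.8
    dev_openness_beta: float = -0.8
    n_chromosomes: int = 19
    intergenic_gap: tuple[int, int] = (5_000, 20_000)
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.species)) != len(self.species) or len(self.species) < 2:
            raise ValueError("need >=2 distinct species")
        if self.binding_species not in self.species:
            raise ValueError("binding_species must be one of the analyzed species")
        for p in (self.p_all_mammals, self.p_two_mammals, self.p_ancient, self.p_ubiquitous):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_all_mammals + self.p_two_mammals > 1.0 + 1e-12:
            raise ValueError("group membership probabilities exceed 1")
        if not -1.0 <= self.ortholog_correlation <= 1.0:
            raise ValueError("ortholog_correlation outside [-1, 1]")


@dataclass
class SimBundle:
    """In-memory result of one simulation."""

    config: SimConfig
    genes: dict[str, list[GeneModel]]  # per species
    fragments: dict[str, list[TEFragment]]  # per species
    homology: list[HomologyGroup]
    binding: pd.DataFrame  # binding_species genes x tissues
    marks: pd.DataFrame  # k4 / k27 flags, binding_species
    expression: pd.Series
    developmental: pd.Series
    gc: dict[str, pd.Series]  # per species
    truth: pd.DataFrame  # per (species, gene): latent values


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _make_gene(
    rng: np.random.Generator, cfg: SimConfig, species: str, gene_id: str,
    chrom: str, start: int, size: int, homology_id: str | None,
) -> GeneModel:
    end = start + size
    n_exons = 1 + rng.poisson(cfg.exon_rate_per_kb * size / 1000.0)
    # one exon per equal-width slot keeps exons sorted and disjoint
    slots = np.linspace(start, end, n_exons + 1).astype(int)
    exons = []
    for lo, hi in zip(slots[:-1], slots[1:]):
        width = int(rng.integers(cfg.exon_size[0], cfg.exon_size[1] + 1))
        width = min(width, hi - lo)
        off = int(rng.integers(0, hi - lo - width + 1)) if hi - lo > width else 0
        exons.append((lo + off, lo + off + width))
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(
        gene_id=gene_id,
        species=species,
        chromosome=chrom,
        start=start,
        end=end,
        strand=strand,
        exons=tuple(exons),
        homology_id=homology_id,
    )


def _te_fragments_for_gene(
    rng: np.random.Generator, cfg: SimConfig, gene: GeneModel, openness: float,
    gc: float,
) -> list[TEFragment]:
    size_kb = gene.length / 1000.0
    mean = size_kb * np.exp(cfg.te_rate_log_per_kb + cfg.te_rate_openness_beta * openness)
    k = cfg.te_dispersion
    n = int(rng.negative_binomial(k, k / (k + mean)))
    classes = list(cfg.te_length_log_mean)
    # class mixture tied to the gene's G+C content
    scores = np.array(
        [
            -cfg.gc_class_slope * (gc - cfg.gc_mean) if cls == "LINE"
            else cfg.gc_class_slope * (gc - cfg.gc_mean) if cls == "SINE"
            else 0.0
            for cls in classes
        ]
    )
    base = np.array([0.30, 0.38, 0.20, 0.12])  # LINE, SINE, LTR, DNA at mean gc
    weights = base * np.exp(scores)
    weights /= weights.sum()
    frags = []
    for _ in range(n):
        cls = classes[int(rng.choice(len(classes), p=weights))]
        length = int(
            np.clip(
                rng.lognormal(cfg.te_length_log_mean[cls], cfg.te_length_log_sd),
                30,
                max(31, gene.length - 1),
            )
        )
        start = int(rng.integers(gene.start, max(gene.start + 1, gene.end - length)))
        mean_div = cfg.te_divergence_mean[cls] * np.exp(-cfg.te_age_openness_beta * openness)
        div = float(
            np.clip(
                rng.gamma(cfg.te_divergence_shape, mean_div / cfg.te_divergence_shape),
                0.0,
                60.0,
            )
        )
        frags.append(
            TEFragment(
                chromosome=gene.chromosome,
                start=start,
                end=start + length,
                te_class=cls,
                family=f"{cls}-sim",
                divergence=div,
            )
        )
    return frags


def simulate(config: SimConfig) -> SimBundle:
    """Draw one fully coupled multi-species bundle from the model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = list(config.species)
    n_sp = len(species)
    rho = config.ortholog_correlation

    # ortholog-group structure
    group_rows = []
    for g in range(config.n_ortholog_groups):
        u = rng.random()
        if u < config.p_all_mammals:
            members = list(species)
        elif u < config.p_all_mammals + config.p_two_mammals:
            members = sorted(rng.choice(species, size=2, replace=False))
        else:
            members = [species[int(rng.integers(n_sp))]]
        ancient = len(members) >= 2 and rng.random() < config.p_ancient
        group_rows.append((f"HG{g:05d}", members, ancient))

    # latent openness: group-level component shared across orthologs
    z_group = rng.normal(size=config.n_ortholog_groups)

    genes: dict[str, list[GeneModel]] = {sp: [] for sp in species}
    gc: dict[str, dict[str, float]] = {sp: {} for sp in species}
    fragments: dict[str, list[TEFragment]] = {sp: [] for sp in species}
    homology: list[HomologyGroup] = []
    truth_rows = []
    cursors: dict[str, dict[str, int]] = {
        sp: {f"chr{i}": 0 for i in range(1, config.n_chromosomes + 1)} for sp in species
    }

    def _place(sp: str, gene_id: str, homology_id: str | None, openness: float):
        chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
        gap = int(rng.integers(*config.intergenic_gap))
        start = cursors[sp][chrom] + gap
        size = int(
            max(
                config.min_gene_size,
                rng.lognormal(config.gene_size_log_mean, config.gene_size_log_sd),
            )
        )
        gene = _make_gene(rng, config, sp, gene_id, chrom, start, size, homology_id)
        cursors[sp][chrom] = gene.end
        g_gc = float(np.clip(rng.normal(config.gc_mean, config.gc_sd), 0.30, 0.60))
        frags = _te_fragments_for_gene(rng, config, gene, openness, g_gc)
        # a few intergenic fragments in the upstream gap exercise clipping
        for _ in range(rng.poisson(config.flank_te_rate)):
            length = int(rng.integers(100, 500))
            s = int(rng.integers(max(0, start - gap), max(1, start - length)))
            frags.append(
                TEFragment(chrom, s, s + length, "SINE", "SINE-sim", float(rng.uniform(5, 30)))
            )
        genes[sp].append(gene)
        gc[sp][gene.gene_id] = g_gc
        fragments[sp].extend(frags)
        truth_rows.append(
            {
                "species": sp,
                "gene_id": gene_id,
                "group_id": homology_id,
                "openness": openness,
                "gc": g_gc,
                "size": gene.length,
            }
        )
        return gene

    for gi, (group_id, members, ancient) in enumerate(group_rows):
        pairs = []
        for sp in species:
            if sp not in members:
                continue
            openness = float(
                np.sqrt(rho) * z_group[gi] + np.sqrt(1.0 - rho) * rng.normal()
            )
            gene_id = f"{sp}_{group_id}"
            _place(sp, gene_id, group_id, openness)
            pairs.append((sp, gene_id))
        if ancient:
            out_sp = config.outgroups[int(rng.integers(len(config.outgroups)))]
            pairs.append((out_sp, f"{out_sp}_{group_id}"))
        homology.append(HomologyGroup(group_id=group_id, members=tuple(sorted(pairs))))

    for sp in species:
        for i in range(config.n_private_genes):
            openness = float(rng.normal())
            _place(sp, f"{sp}_priv{i:04d}", None, openness)

    truth = pd.DataFrame(truth_rows)

    # binding / marks / expression / developmental for the binding species
    bsp = config.binding_species
    b_truth = truth[truth["species"] == bsp].reset_index(drop=True)
    o = b_truth["openness"].to_numpy()
    n_genes = len(b_truth)
    ubiq = rng.random(n_genes) < config.p_ubiquitous
    profiles = np.empty((n_genes, len(TISSUES)))
    top_tissue = np.empty(n_genes, dtype=object)
    for i in range(n_genes):
        if ubiq[i]:
            profiles[i] = rng.dirichlet([config.dirichlet_ubiquitous] * len(TISSUES))
            top_tissue[i] = TISSUES[int(np.argmax(profiles[i]))]
        else:
            w = np.ones(len(TISSUES))
            w[0] = np.exp(config.esc_openness_beta * o[i])  # ESC weight
            w /= w.sum()
            t = int(rng.choice(len(TISSUES), p=w))
            alpha = np.full(len(TISSUES), config.dirichlet_specific_rest)
            alpha[t] = config.dirichlet_specific_top
            profiles[i] = rng.dirichlet(alpha)
            top_tissue[i] = TISSUES[t]
    binding = pd.DataFrame(
        np.round(profiles * 1000.0, 4), index=b_truth["gene_id"], columns=list(TISSUES)
    )
    binding.index.name = "gene_id"
    k4 = rng.random(n_genes) < _sigmoid(config.k4_base + config.k4_openness_beta * o)
    k27 = rng.random(n_genes) < _sigmoid(config.k27_base + config.k27_openness_beta * o)
    marks = pd.DataFrame({"k4": k4, "k27": k27}, index=b_truth["gene_id"])
    expression = pd.Series(
        np.round(
            np.exp(
                rng.normal(
                    config.expr_log_mean + config.expr_openness_beta * o,
                    config.expr_log_sd,
                )
            ),
            6,
        ),
        index=b_truth["gene_id"],
        name="expression",
    )
    developmental = pd.Series(
        rng.random(n_genes) < _sigmoid(config.dev_base + config.dev_openness_beta * o),
        index=b_truth["gene_id"],
        name="developmental",
    )
    truth = truth.assign(
        ubiquitous=np.nan, true_top_tissue=None
    )
    idx = truth["species"] == bsp
    truth.loc[idx, "ubiquitous"] = ubiq.astype(float)
    truth.loc[idx, "true_top_tissue"] = top_tissue

    return SimBundle(
        config=config,
        genes=genes,
        fragments=fragments,
        homology=homology,
        binding=binding,
        marks=marks,
        expression=expression,
        developmental=developmental,
        gc={sp: pd.Series(gc[sp], name="gc").sort_index() for sp in species},
        truth=truth,
    )


def generate_bundle(config: SimConfig, outdir) -> dict[str, Path]:
    """Simulate and write a bundle to disk in the formats the readers accept.

    Returns a mapping of logical names to file paths. Deterministic under
    the config seed: the same config writes byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate(config)
    paths: dict[str, Path] = {}
    for sp in config.species:
        p = outdir / f"genes_{sp}.bed"
        write_gene_models(sorted(bundle.genes[sp], key=lambda g: g.gene_id), p)
        paths[f"genes_{sp}"] = p
        p = outdir / f"te_{sp}.tsv"
        write_te_annotations(
            sorted(bundle.fragments[sp], key=lambda f: (f.chromosome, f.start, f.end)), p
        )
        paths[f"te_{sp}"] = p
        p = outdir / f"gc_{sp}.tsv"
        bundle.gc[sp].to_frame().to_csv(p, sep="\t", index_label="gene_id")
        paths[f"gc_{sp}"] = p
    paths["homology"] = outdir / "homology.tsv"
    write_homology(bundle.homology, paths["homology"])
    paths["binding"] = outdir / "binding.tsv"
    bundle.binding.to_csv(paths["binding"], sep="\t", index_label="gene_id")
    paths["marks"] = outdir / "marks.tsv"
    bundle.marks.astype(int).to_csv(paths["marks"], sep="\t", index_label="gene_id")
    paths["expression"] = outdir / "expression.tsv"
    bundle.expression.to_frame().to_csv(paths["expression"], sep="\t", index_label="gene_id")
    paths["developmental"] = outdir / "developmental.tsv"
    bundle.developmental.astype(int).to_frame().to_csv(
        paths["developmental"], sep="\t", index_label="gene_id"
    )
    paths["truth"] = outdir / "truth.tsv"
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def truth_table(bundle: SimBundle) -> pd.DataFrame:
    """Per-gene latent values for parameter-recovery tests."""
    return bundle.truth.copy()
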