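"""End-to-end orchestration: simulate -> metrics -> outliers -> reports.

Each stage reads the files the previous stage wrote under one output
directory, logs record counts after every filter so pipeline attrition is
auditable, and appends itself to a run manifest with input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import (
    annotations_io as aio,
    chromatin_expression as chrom,
    conservation as cons,
    cross_species as cross,
    outlier_detection as od,
    te_metrics,
    tissue_specificity as ts,
)
from .model import GeneTEMetrics
from .synthetic_data import TISSUES, SimConfig, generate_bundle

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "metrics",
    "outliers",
    "shared",
    "conserve",
    "tissue",
    "chromatin",
    "expression",
    "report",
)


@dataclasses.dataclass
class PipelineConfig:
    """Analysis-side knobs; simulation knobs live in SimConfig."""

    cutoff: float = od.DEFAULT_CUTOFF
    exon_density_mode: str = "count"
    continuity: bool = True
    p_floor: float = ts.DEFAULT_P_FLOOR
    n_age_control: int = 200
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**{**raw.get("sim", {})})
        kwargs = {k: v for k, v in raw.items() if k != "sim"}
        return cls(sim=sim, **kwargs)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _update_manifest(outdir: Path, stage: str, inputs: list[Path], outputs: list[Path], seed: int) -> None:
    manifest_path = outdir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {
        "seed": seed,
        "stages": [],
    }
    manifest["stages"] = [s for s in manifest["stages"] if s["stage"] != stage]
    manifest["stages"].append(
        {
            "stage": stage,
            "inputs": {p.name: _checksum(p) for p in inputs if p.exists()},
            "outputs": {p.name: _checksum(p) for p in outputs if p.exists()},
        }
    )
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path.name}; run the '{stage}' stage first"
        )
    return path


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    paths = generate_bundle(cfg.sim, outdir / "bundle")
    _update_manifest(outdir, "simulate", [], list(paths.values()), cfg.sim.seed)
    return {"files": {k: str(v) for k, v in paths.items()}}


def _load_species(cfg: PipelineConfig, outdir: Path, sp: str):
    bundle = outdir / "bundle"
    genes = aio.read_gene_models(
        _need(bundle / f"genes_{sp}.bed", "simulate"), "bed12", species=sp
    )
    frags = aio.read_te_annotations(_need(bundle / f"te_{sp}.tsv", "simulate"))
    gc = aio.read_gc_table(_need(bundle / f"gc_{sp}.tsv", "simulate"))
    return genes, frags, gc


def stage_metrics(cfg: PipelineConfig, outdir: Path) -> dict:
    """Per-gene TE metrics per species, for genes > 10 kb."""
    summary = {}
    for sp in cfg.sim.species:
        genes, frags, gc = _load_species(cfg, outdir, sp)
        kept = od.filter_genes(genes)
        logger.info("%s: %d genes, %d pass the 10 kb filter", sp, len(genes), len(kept))
        by_chrom: dict[str, list] = {}
        for f in frags:
            by_chrom.setdefault(f.chromosome, []).append(f)
        rows = []
        for g in sorted(kept, key=lambda g: g.gene_id):
            m = te_metrics.compute_metrics(
                g, by_chrom.get(g.chromosome, ()), gc=gc.get(g.gene_id)
            )
            comp = m.composition or dict.fromkeys(("LINE", "SINE", "LTR", "DNA"), float("nan"))
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chromosome": g.chromosome,
                    "length": g.length,
                    "exon_count": g.exon_count,
                    "exon_density": od.exon_density(g, cfg.exon_density_mode),
                    "coverage": m.coverage,
                    "density": m.density,
                    "mean_te_age": m.mean_te_age,
                    "gc": m.gc,
                    **{f"frac_{c}": comp[c] for c in ("LINE", "SINE", "LTR", "DNA")},
                }
            )
        df = pd.DataFrame(rows).set_index("gene_id")
        out = outdir / f"metrics_{sp}.tsv"
        df.to_csv(out, sep="\t")
        summary[sp] = {"n_genes": len(genes), "n_kept": len(kept)}
        _update_manifest(outdir, "metrics", [], [out], cfg.sim.seed)
    return summary


def _load_metrics(outdir: Path, sp: str) -> pd.DataFrame:
    return pd.read_csv(
        _need(outdir / f"metrics_{sp}.tsv", "metrics"), sep="\t", index_col="gene_id"
    )


def metrics_objects(df: pd.DataFrame) -> dict[str, GeneTEMetrics]:
    """Rehydrate GeneTEMetrics objects from a metrics table."""
    out = {}
    for gid, row in df.iterrows():
        comp = {c: row[f"frac_{c}"] for c in ("LINE", "SINE", "LTR", "DNA")}
        has_comp = not any(pd.isna(v) for v in comp.values())
        out[gid] = GeneTEMetrics(
            gene_id=gid,
            coverage=int(row["coverage"]),
            density=float(row["density"]),
            composition=comp if has_comp else None,
            mean_te_age=None if pd.isna(row["mean_te_age"]) else float(row["mean_te_age"]),
            gc=None if pd.isna(row["gc"]) else float(row["gc"]),
        )
    return out


def stage_outliers(cfg: PipelineConfig, outdir: Path) -> dict:
    """Stratify, call outliers at the configured cutoff, and scan the grid."""
    densities, strata = {}, {}
    summary = {}
    for sp in cfg.sim.species:
        df = _load_metrics(outdir, sp)
        genes = aio.read_gene_models(outdir / "bundle" / f"genes_{sp}.bed", "bed12", sp)
        kept = [g for g in od.filter_genes(genes) if g.gene_id in df.index]
        st = od.stratify(kept, mode=cfg.exon_density_mode)
        st.to_csv(outdir / f"strata_{sp}.tsv", sep="\t")
        dens = df["density"].to_dict()
        calls = od.detect_outliers(dens, st, cfg.cutoff)
        calls.to_csv(outdir / f"calls_{sp}.tsv", sep="\t")
        densities[sp], strata[sp] = dens, st
        n_upper = int((calls["label"] == "upper").sum())
        n_lower = int((calls["label"] == "lower").sum())
        logger.info("%s: %d upper, %d lower of %d genes", sp, n_upper, n_lower, len(calls))
        summary[sp] = {"upper": n_upper, "lower": n_lower, "n": len(calls)}
    homology = aio.read_homology(_need(outdir / "bundle" / "homology.tsv", "simulate"))
    table = od.optimize_cutoff(densities, strata, homology)
    table.to_csv(outdir / "cutoff_optimization.tsv", sep="\t", index=False)
    _update_manifest(
        outdir,
        "outliers",
        [outdir / f"metrics_{sp}.tsv" for sp in cfg.sim.species],
        [outdir / "cutoff_optimization.tsv"],
        cfg.sim.seed,
    )
    return summary


def _load_calls(outdir: Path, species) -> dict[str, pd.DataFrame]:
    return {
        sp: pd.read_csv(
            _need(outdir / f"calls_{sp}.tsv", "outliers"), sep="\t", index_col="gene_id"
        )
        for sp in species
    }


def stage_shared(cfg: PipelineConfig, outdir: Path) -> dict:
    """Shared outliers, excess tests, composition and chromosome analyses."""
    calls = _load_calls(outdir, cfg.sim.species)
    homology = aio.read_homology(outdir / "bundle" / "homology.tsv")
    shared = {}
    summary = {}
    for side, tag in (("upper", "SUO"), ("lower", "SLO")):
        s = cross.find_shared_outliers(calls, homology, side)
        shared[side] = s
        rows = [
            {"group_id": gid, **{sp: g for sp, g in pairs}}
            for gid, pairs in s.members
        ]
        pd.DataFrame(rows, columns=["group_id", *cfg.sim.species]).to_csv(
            outdir / f"shared_{side}.tsv", sep="\t", index=False
        )
        n_orth = od._n_informative_groups(calls, homology)
        test = cross.shared_excess_test(
            s.n, n_orth, cfg.cutoff, len(cfg.sim.species), continuity=cfg.continuity
        )
        summary[tag] = {"n": s.n, "n_orthologs": n_orth, "excess_p": test.p}
        logger.info("%s: %d shared among %d ortholog groups (p=%.3g)", tag, s.n, n_orth, test.p)
    sp_a, sp_b = cfg.sim.species[0], cfg.sim.species[1]
    metrics = {sp: metrics_objects(_load_metrics(outdir, sp)) for sp in (sp_a, sp_b)}
    comp_r = cross.composition_correlation(
        shared["upper"], metrics[sp_a], metrics[sp_b], sp_a, sp_b
    )
    gc_r = cross.gc_composition_correlation(shared["upper"], metrics[sp_a], sp_a)
    genes_a = {
        g.gene_id: g
        for g in aio.read_gene_models(outdir / "bundle" / f"genes_{sp_a}.bed", "bed12", sp_a)
    }
    for side in ("upper", "lower"):
        cross.count_by_chromosome(shared[side], genes_a, sp_a).to_csv(
            outdir / f"chromosome_counts_{side}.tsv", sep="\t"
        )
    pd.DataFrame(
        {"composition_r": pd.Series(comp_r), "gc_r": pd.Series(gc_r)}
    ).to_csv(outdir / "correlations.tsv", sep="\t", index_label="te_class")
    summary["composition_r"] = comp_r
    summary["gc_r"] = gc_r
    _update_manifest(
        outdir,
        "shared",
        [outdir / f"calls_{sp}.tsv" for sp in cfg.sim.species],
        [outdir / "shared_upper.tsv", outdir / "shared_lower.tsv"],
        cfg.sim.seed,
    )
    return summary


def stage_conserve(cfg: PipelineConfig, outdir: Path) -> dict:
    """Conservation composition of outlier sets and TE-age comparisons."""
    homology = aio.read_homology(outdir / "bundle" / "homology.tsv")
    mammals = frozenset(cfg.sim.species)
    outgroups = frozenset(cfg.sim.outgroups)
    summary = {}
    sp = cfg.sim.species[0]
    genes = aio.read_gene_models(outdir / "bundle" / f"genes_{sp}.bed", "bed12", sp)
    kept = od.filter_genes(genes)
    labels = cons.classify_conservation(kept, homology, mammals, outgroups)
    labels.to_frame().to_csv(outdir / f"conservation_{sp}.tsv", sep="\t", index_label="gene_id")
    calls = _load_calls(outdir, [sp])[sp]
    sets = {
        "upper": list(calls.index[calls["label"] == "upper"]),
        "lower": list(calls.index[calls["label"] == "lower"]),
        "background": list(calls.index),
    }
    comp = cons.conservation_composition(sets, labels)
    comp.to_csv(outdir / "conservation_composition.tsv", sep="\t", index_label="set")
    summary["composition"] = comp.to_dict("index")

    # TE age: shared upper vs shared lower outliers in the reference species
    metrics = _load_metrics(outdir, sp)
    shared_ids = {}
    for side in ("upper", "lower"):
        shared_df = pd.read_csv(_need(outdir / f"shared_{side}.tsv", "shared"), sep="\t")
        shared_ids[side] = list(shared_df[sp]) if sp in shared_df.columns else []
    ages = metrics["mean_te_age"].dropna()
    if shared_ids["upper"] and shared_ids["lower"]:
        rep = cons.compare_te_age(
            ages.loc[ages.index.intersection(shared_ids["upper"])],
            ages.loc[ages.index.intersection(shared_ids["lower"])],
        )
        summary["te_age"] = {
            "mean_suo": rep["mean_a"],
            "mean_slo": rep["mean_b"],
            "p": rep["test"].p,
        }
    try:
        ctrl = cons.age_control_experiment(
            labels, ages.to_dict(), n_per_group=cfg.n_age_control, seed=cfg.sim.seed
        )
        summary["age_control"] = {
            "mean_mammalian": ctrl["mean_a"],
            "mean_ancient": ctrl["mean_b"],
            "p": ctrl["test"].p,
        }
    except ValueError as exc:
        summary["age_control"] = {"skipped": str(exc)}
    (outdir / "te_age_report.json").write_text(json.dumps(summary, indent=2) + "\n")
    _update_manifest(outdir, "conserve", [], [outdir / "te_age_report.json"], cfg.sim.seed)
    return summary


def _shared_gene_sets(cfg: PipelineConfig, outdir: Path, sp: str) -> dict[str, list[str]]:
    sets = {}
    for side, tag in (("upper", "SUO"), ("lower", "SLO")):
        df = pd.read_csv(_need(outdir / f"shared_{side}.tsv", "shared"), sep="\t")
        sets[tag] = list(df[sp]) if sp in df.columns else []
    return sets


def stage_tissue(cfg: PipelineConfig, outdir: Path) -> dict:
    """Binding entropy profiles and tissue-specificity enrichment."""
    bsp = cfg.sim.binding_species
    binding = aio.read_binding(_need(outdir / "bundle" / "binding.tsv", "simulate"))
    calls = _load_calls(outdir, [bsp])[bsp]
    binding = binding.loc[binding.index.intersection(calls.index)]
    profiles = ts.profile_table(binding)
    profiles.to_csv(outdir / "binding_profiles.tsv", sep="\t", index_label="gene_id")
    sets = _shared_gene_sets(cfg, outdir, bsp)
    background = list(calls.index)
    enrich = ts.ts_enrichment(
        {k: v for k, v in sets.items() if v}, background, profiles, continuity=cfg.continuity
    )
    enrich.to_csv(outdir / "ts_enrichment.tsv", sep="\t", index_label="set")
    comp_sets = {k: v for k, v in sets.items() if v}
    comp_sets["background"] = background
    try:
        comp = ts.single_tissue_composition(comp_sets, profiles, TISSUES, cfg.p_floor)
        comp.to_csv(outdir / "single_tissue_composition.tsv", sep="\t", index_label="set")
        single = comp.to_dict("index")
    except ValueError as exc:
        single = {"skipped": str(exc)}
    _update_manifest(outdir, "tissue", [], [outdir / "ts_enrichment.tsv"], cfg.sim.seed)
    return {"enrichment": enrich.to_dict("index"), "single_tissue": single}


def stage_chromatin(cfg: PipelineConfig, outdir: Path) -> dict:
    """Chromatin-state enrichment and the function x chromatin effect matrix."""
    bsp = cfg.sim.binding_species
    marks = aio.read_marks(_need(outdir / "bundle" / "marks.tsv", "simulate"))
    dev = aio.read_flags(outdir / "bundle" / "developmental.tsv", "developmental")
    calls = _load_calls(outdir, [bsp])[bsp]
    states = chrom.chromatin_states(marks.loc[marks.index.intersection(calls.index)])
    sets = {k: v for k, v in _shared_gene_sets(cfg, outdir, bsp).items() if v}
    background = list(calls.index)
    enrich = chrom.chromatin_enrichment(sets, states, background, continuity=cfg.continuity)
    enrich.to_csv(outdir / "chromatin_enrichment.tsv", sep="\t", index=False)
    bg_states = states.loc[states.index.intersection(background)]
    bg_dev = dev.loc[dev.index.intersection(background)]
    matrix = chrom.effect_matrix(
        states,
        dev,
        sets.get("SLO", []),
        background_dev=(int(bg_dev.sum()), len(bg_dev)),
        background_bivalent=(int((bg_states == "bivalent").sum()), len(bg_states)),
        continuity=cfg.continuity,
    )
    serializable = {
        k: (v if not isinstance(v, dict) else {kk: vv for kk, vv in v.items()})
        for k, v in matrix.items()
    }
    (outdir / "effect_matrix.json").write_text(json.dumps(serializable, indent=2) + "\n")
    _update_manifest(outdir, "chromatin", [], [outdir / "effect_matrix.json"], cfg.sim.seed)
    return {"effect_matrix": serializable}


def stage_expression(cfg: PipelineConfig, outdir: Path) -> dict:
    """Low/high expression split of outlier sets vs. the genomic median."""
    bsp = cfg.sim.binding_species
    expr = aio.read_expression(_need(outdir / "bundle" / "expression.tsv", "simulate"))
    calls = _load_calls(outdir, [bsp])[bsp]
    sets = {k: v for k, v in _shared_gene_sets(cfg, outdir, bsp).items() if v}
    result = chrom.expression_split(sets, expr, list(calls.index), continuity=cfg.continuity)
    out = {
        "median": result["median"],
        "background_high_fraction": result["background_high_fraction"],
        "sets": result["sets"],
    }
    if "between_sets" in result:
        out["suo_vs_slo_p"] = result["between_sets"].p
    (outdir / "expression_split.json").write_text(json.dumps(out, indent=2) + "\n")
    _update_manifest(outdir, "expression", [], [outdir / "expression_split.json"], cfg.sim.seed)
    return out


def stage_report(cfg: PipelineConfig, outdir: Path) -> dict:
    """Assemble the per-stage outputs into one markdown report."""
    lines = ["# TE-density outlier pipeline report", ""]
    opt = outdir / "cutoff_optimization.tsv"
    if opt.exists():
        lines += ["## Cutoff optimization", "", pd.read_csv(opt, sep="\t").to_markdown(index=False), ""]
    for name, fn in (
        ("Shared outliers", "shared_upper.tsv"),
        ("Conservation composition", "conservation_composition.tsv"),
        ("Tissue-specificity enrichment", "ts_enrichment.tsv"),
        ("Chromatin enrichment", "chromatin_enrichment.tsv"),
    ):
        p = outdir / fn
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            if name == "Shared outliers":
                lower = outdir / "shared_lower.tsv"
                n_lower = len(pd.read_csv(lower, sep="\t")) if lower.exists() else 0
                lines += [f"## {name}", "", f"SUO groups: {len(df)}; SLO groups: {n_lower}", ""]
            else:
                lines += [f"## {name}", "", df.to_markdown(index=False), ""]
    for fn in ("te_age_report.json", "effect_matrix.json", "expression_split.json"):
        p = outdir / fn
        if p.exists():
            lines += [f"## {fn.removesuffix('.json').replace('_', ' ').capitalize()}", "",
                      "```json", p.read_text().rstrip(), "```", ""]
    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    _update_manifest(outdir, "report", [], [report], cfg.sim.seed)
    return {"report": str(report)}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "metrics": stage_metrics,
    "outliers": stage_outliers,
    "shared": stage_shared,
    "conserve": stage_conserve,
    "tissue": stage_tissue,
    "chromatin": stage_chromatin,
    "expression": stage_expression,
    "report": stage_report,
}


def run(stage: str, cfg: PipelineConfig, outdir) -> dict:
    """Run one named stage, or every stage in order with ``"all"``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage == "all":
        results = {}
        for s in STAGES:
            results[s] = _STAGE_FUNCS[s](cfg, outdir)
        return results
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    return {stage: _STAGE_FUNCS[stage](cfg, outdir)}
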