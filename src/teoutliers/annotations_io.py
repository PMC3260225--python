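"""Readers and writers for the external annotation formats.

Supported inputs: BED12 and GTF gene models (longest isoform kept per gene),
UCSC rmsk-style tab tables and RepeatMasker ``.out`` files for TE fragments,
and header-bearing TSVs for homology groups, Pol-II binding strengths,
promoter histone-mark flags, expression values and developmental flags.

Internally everything is 0-based half-open; GTF and ``.out`` coordinates
(1-based inclusive) are converted here and nowhere else.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

import pandas as pd

from .model import GeneModel, HomologyGroup, TEFragment

logger = logging.getLogger(__name__)

# repClass prefixes mapped onto the four-class enumeration
_CLASS_MAP = {
    "LINE": "LINE",
    "SINE": "SINE",
    "LTR": "LTR",
    "DNA": "DNA",
}
# non-TE repeat classes silently dropped (with a logged count)
_DROP_CLASSES = {
    "Simple_repeat",
    "Low_complexity",
    "Satellite",
    "rRNA",
    "tRNA",
    "snRNA",
    "scRNA",
    "srpRNA",
    "RNA",
    "Unknown",
}


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# gene models


def _longest_isoform(
    isoforms: dict[str, list[tuple]], species: str
) -> list[GeneModel]:
    """Collapse per-transcript records to one GeneModel per gene.

    Keeps the longest isoform; ties go to the lexicographically smallest
    transcript ID so output is deterministic.
    """
    genes = []
    for gene_id in sorted(isoforms):
        records = isoforms[gene_id]
        chroms = {r[1] for r in records}
        if len(chroms) > 1:
            raise ParseError(
                f"gene {gene_id}: isoforms on conflicting chromosomes {sorted(chroms)}"
            )
        best = min(records, key=lambda r: (-(r[3] - r[2]), r[0]))
        _tx, chrom, start, end, strand, exons = best
        genes.append(
            GeneModel(
                gene_id=gene_id,
                species=species,
                chromosome=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=tuple(exons),
            )
        )
    return genes


def _parse_bed12_line(line: str, lineno: int) -> tuple:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ParseError(f"line {lineno}: BED12 needs 12 fields, got {len(fields)}")
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        name = fields[3]
        strand = fields[5]
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None
    if len(sizes) != block_count or len(starts) != block_count:
        raise ParseError(f"line {lineno}: block count mismatch")
    exons = [(start + off, start + off + sz) for off, sz in zip(starts, sizes)]
    if "|" in name:
        gene_id, tx_id = name.split("|", 1)
    else:
        gene_id = tx_id = name
    return tx_id, gene_id, chrom, start, end, strand, exons


def _parse_gtf(path: Path) -> dict[str, list[tuple]]:
    """Collect exon intervals per transcript from a GTF file."""

    def attr(attrs: str, key: str, lineno: int) -> str:
        for chunk in attrs.split(";"):
            chunk = chunk.strip()
            if chunk.startswith(key + " "):
                return chunk.split(" ", 1)[1].strip('"')
        raise ParseError(f"line {lineno}: missing {key} attribute")

    tx_exons: dict[tuple[str, str], list] = defaultdict(list)
    tx_meta: dict[tuple[str, str], tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"line {lineno}: GTF needs 9 fields, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                s, e = int(start) - 1, int(end)  # 1-based inclusive -> half-open
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            gene_id = attr(attrs, "gene_id", lineno)
            tx_id = attr(attrs, "transcript_id", lineno)
            key = (gene_id, tx_id)
            tx_exons[key].append((s, e))
            if key in tx_meta and tx_meta[key][0] != chrom:
                raise ParseError(
                    f"line {lineno}: transcript {tx_id} on conflicting chromosomes"
                )
            tx_meta[key] = (chrom, strand)
    isoforms: dict[str, list[tuple]] = defaultdict(list)
    for (gene_id, tx_id), exons in tx_exons.items():
        chrom, strand = tx_meta[(gene_id, tx_id)]
        exons = sorted(exons)
        start, end = exons[0][0], max(e for _, e in exons)
        isoforms[gene_id].append((tx_id, chrom, start, end, strand, exons))
    return isoforms


def read_gene_models(path, format: str = "bed12", species: str = "") -> list[GeneModel]:
    """Read gene models, keeping the longest isoform per gene.

    Parameters
    ----------
    path
        Input file.
    format
        ``"bed12"`` (BED name field is ``gene`` or ``gene|transcript``) or
        ``"gtf"`` (``gene_id``/``transcript_id`` attributes on exon rows).
    species
        Species label attached to every record.
    """
    path = Path(path)
    if format == "bed12":
        isoforms: dict[str, list[tuple]] = defaultdict(list)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                tx, gene, chrom, start, end, strand, exons = _parse_bed12_line(
                    line, lineno
                )
                isoforms[gene].append((tx, chrom, start, end, strand, exons))
    elif format == "gtf":
        isoforms = _parse_gtf(path)
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    return _longest_isoform(isoforms, species)


def write_gene_models(genes: list[GeneModel], path) -> None:
    """Write gene models as BED12 (name = gene_id)."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TE annotations


def _map_class(rep_class: str, lineno: int) -> str | None:
    """Map a repClass string to the four-class enumeration.

    Returns None for non-TE repeat classes on the drop list; raises for
    anything else unrecognized so new classes must be mapped explicitly.
    """
    prefix = rep_class.split("/", 1)[0].rstrip("?")
    if prefix in _CLASS_MAP:
        return _CLASS_MAP[prefix]
    if prefix in _DROP_CLASSES:
        return None
    raise ParseError(f"line {lineno}: unmapped repeat class {rep_class!r}")


def read_te_annotations(path, dialect: str = "rmsk_table") -> list[TEFragment]:
    """Read TE fragments from a UCSC rmsk table or RepeatMasker ``.out`` file.

    rmsk tables are 0-based half-open with milliDiv (per-mille divergence);
    ``.out`` files are 1-based inclusive with percent divergence. Both are
    normalized to 0-based half-open percent-divergence fragments. Non-TE
    repeat classes (simple repeats, low complexity, satellites, structural
    RNAs, Unknown) are dropped; their count is logged.
    """
    path = Path(path)
    fragments: list[TEFragment] = []
    dropped = 0
    if dialect == "rmsk_table":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) == 17:  # leading UCSC bin column
                    fields = fields[1:]
                if len(fields) < 12:
                    raise ParseError(
                        f"line {lineno}: rmsk table needs >=16 fields, got {len(fields)}"
                    )
                try:
                    milli_div = float(fields[1])
                    chrom = fields[4]
                    start, end = int(fields[5]), int(fields[6])
                    rep_name, rep_class, rep_family = fields[9], fields[10], fields[11]
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"line {lineno}: {exc}") from None
                te_class = _map_class(rep_class, lineno)
                if te_class is None:
                    dropped += 1
                    continue
                fragments.append(
                    TEFragment(
                        chromosome=chrom,
                        start=start,
                        end=end,
                        te_class=te_class,
                        family=rep_family if rep_family else rep_name,
                        divergence=milli_div / 10.0,
                    )
                )
    elif dialect == "rm_out":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                stripped = line.strip()
                if not stripped or stripped.startswith(("SW", "score", "*")):
                    continue
                fields = stripped.split()
                if len(fields) < 11:
                    raise ParseError(
                        f"line {lineno}: .out row needs >=11 fields, got {len(fields)}"
                    )
                try:
                    div = float(fields[1])
                    chrom = fields[4]
                    start, end = int(fields[5]) - 1, int(fields[6])
                    class_family = fields[10]
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: {exc}") from None
                te_class = _map_class(class_family, lineno)
                if te_class is None:
                    dropped += 1
                    continue
                family = class_family.split("/", 1)[1] if "/" in class_family else fields[9]
                fragments.append(
                    TEFragment(
                        chromosome=chrom,
                        start=start,
                        end=end,
                        te_class=te_class,
                        family=family,
                        divergence=div,
                    )
                )
    else:
        raise ValueError(f"unknown TE dialect {dialect!r}")
    if dropped:
        logger.info("%s: dropped %d non-TE repeat records", path.name, dropped)
    return fragments


def write_te_annotations(fragments: list[TEFragment], path) -> None:
    """Write TE fragments in the (bin-less) UCSC rmsk tab dialect."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(
                "\t".join(
                    [
                        "0",  # swScore, unused
                        str(int(round(f.divergence * 10))),  # milliDiv
                        "0",
                        "0",
                        f.chromosome,
                        str(f.start),
                        str(f.end),
                        "0",
                        "+",
                        f.family,
                        f"{f.te_class}/{f.family}",
                        f.family,
                        "0",
                        "0",
                        "0",
                        "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# plain TSV tables


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def read_homology(path) -> list[HomologyGroup]:
    """Read a homology TSV (columns: group_id, species, gene_id)."""
    df = _read_tsv(path, ["group_id", "species", "gene_id"])
    groups = []
    for gid, sub in df.groupby("group_id", sort=True):
        members = tuple(
            sorted((str(r.species), str(r.gene_id)) for r in sub.itertuples())
        )
        groups.append(HomologyGroup(group_id=str(gid), members=members))
    return groups


def write_homology(groups: list[HomologyGroup], path) -> None:
    rows = [
        {"group_id": g.group_id, "species": sp, "gene_id": gid}
        for g in sorted(groups, key=lambda g: g.group_id)
        for sp, gid in g.members
    ]
    pd.DataFrame(rows, columns=["group_id", "species", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def _check_unique_genes(df: pd.DataFrame, path) -> None:
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")


def read_binding(path) -> pd.DataFrame:
    """Read per-gene per-tissue binding strengths (gene_id + tissue columns).

    Returns a DataFrame indexed by gene_id, one non-negative column per
    tissue.
    """
    df = _read_tsv(path, ["gene_id"])
    _check_unique_genes(df, path)
    df = df.set_index("gene_id")
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no tissue columns")
    if (df.to_numpy(dtype=float) < 0).any():
        raise ParseError(f"{path}: negative binding strength")
    return df.astype(float)


def read_marks(path) -> pd.DataFrame:
    """Read promoter mark flags (columns: gene_id, k4, k27) as booleans."""
    df = _read_tsv(path, ["gene_id", "k4", "k27"])
    _check_unique_genes(df, path)
    out = df.set_index("gene_id")[["k4", "k27"]].astype(int)
    if not out.isin([0, 1]).all().all():
        raise ParseError(f"{path}: mark flags must be 0/1")
    return out.astype(bool)


def read_expression(path) -> pd.Series:
    """Read per-gene expression values (columns: gene_id, expression)."""
    df = _read_tsv(path, ["gene_id", "expression"])
    _check_unique_genes(df, path)
    s = df.set_index("gene_id")["expression"].astype(float)
    if (s < 0).any():
        raise ParseError(f"{path}: negative expression value")
    return s


def read_flags(path, column: str) -> pd.Series:
    """Read a per-gene boolean flag column (e.g. ``developmental``)."""
    df = _read_tsv(path, ["gene_id", column])
    _check_unique_genes(df, path)
    s = df.set_index("gene_id")[column].astype(int)
    if not s.isin([0, 1]).all():
        raise ParseError(f"{path}: {column} flags must be 0/1")
    return s.astype(bool)


def read_gc_table(path) -> pd.Series:
    """Read per-gene G+C fractions (columns: gene_id, gc)."""
    df = _read_tsv(path, ["gene_id", "gc"])
    _check_unique_genes(df, path)
    s = df.set_index("gene_id")["gc"].astype(float)
    if ((s < 0) | (s > 1)).any():
        raise ParseError(f"{path}: gc outside [0, 1]")
    return s


def write_table(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    """Write an indexed table back to TSV (inverse of the readers above)."""
    df.to_csv(path, sep="\t", index_label=index_label)
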