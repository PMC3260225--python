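"""Promoter chromatin states, the function x chromatin effect matrix, and
expression splits.

Promoters are classified from two histone marks measured in ES cells:
H3K4me3 (open chromatin) and H3K27me3 (condensed); carrying both is the
"bivalent" poised state. The effect matrix separates the contributions of
gene function (developmental vs. not) and chromatin state (K4-only vs.
bivalent) to low TE density by conditioning on one while testing the other.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats import prop_test, proportion_se

CHROMATIN_STATES = ("K4_only", "K27_only", "bivalent", "neither")


def categorize_chromatin(k4: bool, k27: bool) -> str:
    """Map the two mark flags onto the four-state classification."""
    if k4 and k27:
        return "bivalent"
    if k4:
        return "K4_only"
    if k27:
        return "K27_only"
    return "neither"


def chromatin_states(marks: pd.DataFrame) -> pd.Series:
    """Chromatin state per gene from a (k4, k27) boolean table."""
    state = np.select(
        [
            marks["k4"] & marks["k27"],
            marks["k4"],
            marks["k27"],
        ],
        ["bivalent", "K4_only", "K27_only"],
        default="neither",
    )
    return pd.Series(state, index=marks.index, name="chromatin_state")


def chromatin_enrichment(
    gene_sets: Mapping[str, Iterable[str]],
    states: pd.Series,
    background_ids: Iterable[str],
    continuity: bool = True,
) -> pd.DataFrame:
    """Per-state fractions for each gene set vs. the genomic background.

    Returns one row per (set, state) with the fraction, its standard error
    and a two-proportion test against the background fraction for that
    state; background rows are included with NaN p.
    """
    bg = states.loc[states.index.intersection(list(background_ids))]
    if len(bg) == 0:
        raise ValueError("empty background")
    rows = []
    bg_counts = bg.value_counts()
    named_sets = dict(gene_sets)
    for name, ids in named_sets.items():
        sub = states.loc[states.index.intersection(list(ids))]
        if len(sub) == 0:
            raise ValueError(f"gene set {name!r} has no annotated genes")
        counts = sub.value_counts()
        for state in CHROMATIN_STATES:
            x, n = int(counts.get(state, 0)), len(sub)
            bx, bn = int(bg_counts.get(state, 0)), len(bg)
            report = prop_test(x, n, bx, bn, continuity=continuity)
            rows.append(
                {
                    "set": name,
                    "state": state,
                    "fraction": x / n,
                    "se": proportion_se(x / n, n),
                    "n": n,
                    "p_vs_background": report.p,
                }
            )
    for state in CHROMATIN_STATES:
        bx, bn = int(bg_counts.get(state, 0)), len(bg)
        rows.append(
            {
                "set": "background",
                "state": state,
                "fraction": bx / bn,
                "se": proportion_se(bx / bn, bn),
                "n": bn,
                "p_vs_background": float("nan"),
            }
        )
    return pd.DataFrame(rows)


def effect_matrix(
    states: pd.Series,
    developmental: pd.Series,
    slo_ids: Iterable[str],
    background_dev: tuple[int, int],
    background_bivalent: tuple[int, int],
    continuity: bool = True,
) -> dict:
    """2x2 function x chromatin matrix for shared lower outliers.

    SLOs are restricted to the K4-only and bivalent chromatin states (the
    K27-only class is too small to analyze) and cross-classified by the
    developmental flag:

        A = K4_only & developmental      B = bivalent & developmental
        C = K4_only & non-developmental  D = bivalent & non-developmental

    with margins T1 = A+C (K4-only column), T2 = B+D (bivalent column),
    T3 = A+B (developmental row), T4 = C+D (non-developmental row). The four
    conditional proportions A/T1, B/T2, B/T3, D/T4 are each tested against
    the supplied genomic background counts (developmental rate for the
    column-wise proportions, bivalent rate for the row-wise ones).
    """
    ids = [g for g in slo_ids if g in states.index and g in developmental.index]
    sub = pd.DataFrame({"state": states.loc[ids], "dev": developmental.loc[ids]})
    sub = sub[sub["state"].isin(["K4_only", "bivalent"])]
    a = int(((sub["state"] == "K4_only") & sub["dev"]).sum())
    b = int(((sub["state"] == "bivalent") & sub["dev"]).sum())
    c = int(((sub["state"] == "K4_only") & ~sub["dev"]).sum())
    d = int(((sub["state"] == "bivalent") & ~sub["dev"]).sum())
    t1, t2, t3, t4 = a + c, b + d, a + b, c + d
    bg_dev_x, bg_dev_n = background_dev
    bg_biv_x, bg_biv_n = background_bivalent

    def _cell(x: int, margin: int, bg: tuple[int, int]) -> dict:
        if margin == 0:
            return {"proportion": float("nan"), "n": 0, "p": float("nan"), "defined": False}
        report = prop_test(x, margin, bg[0], bg[1], continuity=continuity)
        return {
            "proportion": x / margin,
            "se": proportion_se(x / margin, margin),
            "n": margin,
            "p": report.p,
            "defined": True,
        }

    return {
        "A": a,
        "B": b,
        "C": c,
        "D": d,
        "T1": t1,
        "T2": t2,
        "T3": t3,
        "T4": t4,
        # developmental share within each chromatin column
        "A/T1": _cell(a, t1, background_dev),
        "B/T2": _cell(b, t2, background_dev),
        # bivalent share within each function row
        "B/T3": _cell(b, t3, background_bivalent),
        "D/T4": _cell(d, t4, background_bivalent),
        "background_dev_rate": bg_dev_x / bg_dev_n,
        "background_bivalent_rate": bg_biv_x / bg_biv_n,
    }


def expression_split(
    gene_sets: Mapping[str, Iterable[str]],
    expression: pd.Series,
    background_ids: Iterable[str],
    continuity: bool = True,
) -> dict:
    """Low/high expression proportions per set against the genome-wide median.

    The median is computed over all background genes (every gene > 10 kb),
    so the background itself splits 50/50 by construction; values strictly
    greater than the median count as "high". Returns per-set fractions and
    a two-proportion test between the first two sets (SUO vs. SLO in the
    standard pipeline).
    """
    bg = expression.loc[expression.index.intersection(list(background_ids))]
    if len(bg) == 0:
        raise ValueError("empty background")
    median = float(bg.median())
    rows = {}
    counts = {}
    for name, ids in gene_sets.items():
        sub = expression.loc[expression.index.intersection(list(ids))]
        if len(sub) == 0:
            raise ValueError(f"gene set {name!r} has no expression values")
        x, n = int((sub > median).sum()), len(sub)
        counts[name] = (x, n)
        rows[name] = {
            "high_fraction": x / n,
            "se": proportion_se(x / n, n),
            "n": n,
        }
    result = {
        "median": median,
        "background_high_fraction": float((bg > median).mean()),
        "sets": rows,
    }
    names = list(gene_sets)
    if len(names) >= 2:
        (x1, n1), (x2, n2) = counts[names[0]], counts[names[1]]
        result["between_sets"] = prop_test(x1, n1, x2, n2, continuity=continuity)
    return result
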